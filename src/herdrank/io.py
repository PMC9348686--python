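"""Reading, validating and writing bin-event logs and interaction tables.

Electronic feed/water bins record one row per visit: which bin
(``equip_id``), which animal (``animal_id``), and the entry/exit timestamps
(``IN``/``OUT``, second resolution, default dialect ``dd/mm/yyyy HH:MM:SS``).
Raw exports from some systems carry entry time plus a duration instead of an
exit time; :func:`derive_out_from_duration` converts those.

Observational data (live or video scoring of agonistic interactions) arrive
as an ordered two-column table ``actor,reactor``; order is preserved because
sequential indices (Elo) depend on it.

Identifiers are opaque strings throughout: ids that look numeric (``227``)
are never coerced, so leading zeros survive a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("herdrank")

#: Default timestamp dialect of the supported bin exports.
DEFAULT_DATETIME_FORMAT = "%d/%m/%Y %H:%M:%S"

_EVENT_COLUMNS = ("equip_id", "animal_id", "IN", "OUT")
_INTERACTION_COLUMNS = ("actor", "reactor")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """One directed agonistic event: ``actor`` displaced/beat ``reactor``."""

    actor: str
    reactor: str
    equip_id: str | None = None
    t: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.actor == self.reactor:
            raise ValidationError(
                f"actor and reactor are identical ({self.actor!r})"
            )


@dataclass(eq=False)
class InteractionList:
    """Ordered collection of :class:`Interaction`.

    Backed by a DataFrame with columns ``actor``, ``reactor`` and (optional,
    possibly null) ``equip_id``, ``t``. Input order is preserved.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            {"actor": pd.Series(dtype=str), "reactor": pd.Series(dtype=str)}
        )
    )

    def __post_init__(self) -> None:
        missing = [c for c in _INTERACTION_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"interaction table lacks column(s) {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interaction]:
        has_bin = "equip_id" in self.df.columns
        has_t = "t" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield Interaction(
                actor=row.actor,
                reactor=row.reactor,
                equip_id=getattr(row, "equip_id", None) if has_bin else None,
                t=getattr(row, "t", None) if has_t else None,
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionList):
            return NotImplemented
        a = self.df[["actor", "reactor"]].reset_index(drop=True)
        b = other.df[["actor", "reactor"]].reset_index(drop=True)
        return a.equals(b)

    @property
    def animals(self) -> set[str]:
        return set(self.df["actor"]) | set(self.df["reactor"])

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "InteractionList":
        rows = list(pairs)
        df = pd.DataFrame(rows, columns=["actor", "reactor"], dtype=str)
        return cls(df)


@dataclass(eq=False)
class EventLog:
    """Visits of animals to electronic bins.

    ``df`` columns: ``equip_id`` (str), ``animal_id`` (str), ``t_in`` and
    ``t_out`` (naive datetimes, second resolution). ``roster`` and ``bins``
    are always derived from the rows, never stored separately.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["equip_id", "animal_id", "t_in", "t_out"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"event log lacks column(s) {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        cols = ["equip_id", "animal_id", "t_in", "t_out"]
        return self.df[cols].reset_index(drop=True).equals(
            other.df[cols].reset_index(drop=True)
        )

    @property
    def roster(self) -> set[str]:
        return set(self.df["animal_id"])

    @property
    def bins(self) -> set[str]:
        return set(self.df["equip_id"])

    def canonical(self) -> pd.DataFrame:
        """Rows sorted by (equip_id, t_in, input order) — a stable sort."""
        return self.df.sort_values(
            ["equip_id", "t_in"], kind="mergesort"
        ).reset_index(drop=False)


# ---------------------------------------------------------------------------
# header handling
# ---------------------------------------------------------------------------

def _normalise(name: str) -> str:
    return name.strip().lower()


def _resolve_columns(
    df: pd.DataFrame,
    required: Sequence[str],
    column_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    """Rename user columns to canonical names.

    ``column_map`` maps *source* column names to canonical ones and is
    applied first; remaining columns match canonical names
    case-insensitively after trimming.
    """
    df = df.rename(columns=dict(column_map or {}))
    lookup = {_normalise(c): c for c in df.columns}
    renames: dict[str, str] = {}
    for canon in required:
        key = _normalise(canon)
        if canon in df.columns:
            continue
        if key in lookup:
            renames[lookup[key]] = canon
    return df.rename(columns=renames)


def _require(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} is missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )


def _parse_timestamps(
    raw: pd.Series, fmt: str, column: str, lenient: bool
) -> tuple[pd.Series, pd.Series]:
    """Parse to datetime; return (values, bad-row mask)."""
    parsed = pd.to_datetime(raw.str.strip(), format=fmt, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any() and not lenient:
        rows = (bad[bad].index + 2).tolist()  # 1-based incl. header
        raise ParseError(
            f"column {column!r}: unparseable timestamp(s) with format "
            f"{fmt!r} at file line(s) {rows[:10]}"
            + ("..." if len(rows) > 10 else "")
        )
    return parsed, bad


def _combine_split_datetime(df: pd.DataFrame, stem: str) -> pd.DataFrame:
    """Fold a split export (``IN date`` + ``IN time``) into one column."""
    if stem in df.columns:
        return df
    date_col = time_col = None
    for c in df.columns:
        n = _normalise(str(c)).replace("_", " ")
        if n in (f"{stem.lower()} date", f"date {stem.lower()}"):
            date_col = c
        elif n in (f"{stem.lower()} time", f"time {stem.lower()}"):
            time_col = c
    if date_col is not None and time_col is not None:
        df = df.copy()
        df[stem] = (
            df[date_col].astype(str).str.strip()
            + " "
            + df[time_col].astype(str).str.strip()
        )
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bin_events(
    path: str | Path,
    datetime_format: str = DEFAULT_DATETIME_FORMAT,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    lenient: bool = False,
) -> EventLog:
    """Read a bin-event CSV into an :class:`EventLog`.

    Parameters
    ----------
    path
        CSV with header containing ``equip_id``, ``animal_id``, ``IN``,
        ``OUT`` (case-insensitive; date and time may be split into
        ``IN date``/``IN time`` pairs).
    datetime_format
        strftime pattern for the timestamp columns.
    column_map
        Optional source-name → canonical-name renames applied before
        matching.
    lenient
        Drop offending rows (bad timestamps, ``t_out < t_in``) with a
        logged count instead of raising.
    """
    df = pd.read_csv(path, dtype=str, sep=delimiter, skipinitialspace=True)
    df = _resolve_columns(df, _EVENT_COLUMNS, column_map)
    for stem in ("IN", "OUT"):
        df = _combine_split_datetime(df, stem)
    _require(df, _EVENT_COLUMNS, f"event log {path}")

    t_in, bad_in = _parse_timestamps(df["IN"], datetime_format, "IN", lenient)
    t_out, bad_out = _parse_timestamps(
        df["OUT"], datetime_format, "OUT", lenient
    )
    out = pd.DataFrame(
        {
            "equip_id": df["equip_id"].astype(str).str.strip(),
            "animal_id": df["animal_id"].astype(str).str.strip(),
            "t_in": t_in,
            "t_out": t_out,
        }
    )
    bad = bad_in | bad_out
    if bad.any():
        logger.warning("dropping %d row(s) with unparseable timestamps",
                       int(bad.sum()))
        out = out[~bad]

    reversed_rows = out["t_out"] < out["t_in"]
    if reversed_rows.any():
        if lenient:
            logger.warning("dropping %d row(s) with t_out < t_in",
                           int(reversed_rows.sum()))
            out = out[~reversed_rows]
        else:
            rows = (reversed_rows[reversed_rows].index + 2).tolist()
            raise ValidationError(
                f"t_out < t_in at file line(s) {rows[:10]}"
                + ("..." if len(rows) > 10 else "")
            )
    if (out["equip_id"] == "").any() or (out["animal_id"] == "").any():
        raise ValidationError("empty equip_id or animal_id encountered")
    return EventLog(out.reset_index(drop=True))


def derive_out_from_duration(
    raw: pd.DataFrame | str | Path,
    datetime_format: str = DEFAULT_DATETIME_FORMAT,
    *,
    duration_column: str = "duration_s",
    column_map: Mapping[str, str] | None = None,
) -> EventLog:
    """Build an :class:`EventLog` from a duration-style export.

    Exit time is the entry time plus the visit duration in seconds; a visit
    crossing midnight rolls the date forward, which datetime arithmetic
    gives for free. Zero duration yields ``t_out == t_in``.
    """
    if not isinstance(raw, pd.DataFrame):
        raw = pd.read_csv(raw, dtype=str, skipinitialspace=True)
    df = _resolve_columns(
        raw, ("equip_id", "animal_id", "IN", duration_column), column_map
    )
    _require(df, ("equip_id", "animal_id", "IN", duration_column),
             "duration-style export")

    t_in, _ = _parse_timestamps(
        df["IN"].astype(str), datetime_format, "IN", lenient=False
    )
    dur = pd.to_numeric(df[duration_column], errors="coerce")
    if dur.isna().any():
        rows = (dur[dur.isna()].index + 2).tolist()
        raise ParseError(
            f"non-numeric duration at file line(s) {rows[:10]}")
    if (dur < 0).any():
        rows = (dur[dur < 0].index + 2).tolist()
        raise ValidationError(
            f"negative duration at file line(s) {rows[:10]}")
    out = pd.DataFrame(
        {
            "equip_id": df["equip_id"].astype(str).str.strip(),
            "animal_id": df["animal_id"].astype(str).str.strip(),
            "t_in": t_in,
            "t_out": t_in + pd.to_timedelta(dur, unit="s"),
        }
    )
    return EventLog(out)


def read_interactions(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    lenient: bool = False,
    datetime_format: str = DEFAULT_DATETIME_FORMAT,
) -> InteractionList:
    """Read an observational actor/reactor table, preserving row order."""
    df = pd.read_csv(path, dtype=str, sep=delimiter, skipinitialspace=True)
    df = _resolve_columns(
        df, _INTERACTION_COLUMNS + ("equip_id", "t"), column_map
    )
    _require(df, _INTERACTION_COLUMNS, f"interaction table {path}")

    keep = [c for c in ("actor", "reactor", "equip_id", "t") if c in df.columns]
    df = df[keep].copy()
    for c in ("actor", "reactor"):
        df[c] = df[c].astype(str).str.strip()
    if "t" in df.columns:
        df["t"], _ = _parse_timestamps(df["t"], datetime_format, "t", lenient)

    selfpairs = df["actor"] == df["reactor"]
    if selfpairs.any():
        if lenient:
            logger.warning("dropping %d self-pair row(s) (actor == reactor)",
                           int(selfpairs.sum()))
            df = df[~selfpairs]
        else:
            rows = (selfpairs[selfpairs].index + 2).tolist()
            raise ValidationError(
                f"actor equals reactor at file line(s) {rows[:10]}")
    return InteractionList(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# writers + round-trip readers
# ---------------------------------------------------------------------------

def write_table(obj, path: str | Path) -> None:
    """Serialize any of the package's result types to CSV.

    Matrices are written in display orientation — reactor labels down the
    first column, actor labels across the header — so the file matches how
    sociomatrices are conventionally printed. Everything else is a plain
    header + rows table. ``write_table`` then the matching ``read_*``
    reproduces the object exactly.
    """
    from .dominance import DominanceTable, DyadicMatrix, SocioMatrix
    from .detection import BinFrequencyTable, FrequencyTable
    from .indices import ScoreTable

    path = Path(path)
    if isinstance(obj, (SocioMatrix, DyadicMatrix)):
        frame = pd.DataFrame(
            np.asarray(obj.values).T, index=obj.labels, columns=obj.labels
        )
        frame.index.name = "reactor"
        frame.to_csv(path)
    elif isinstance(obj, (DominanceTable, FrequencyTable, BinFrequencyTable)):
        obj.df.to_csv(path, index=False)
    elif isinstance(obj, ScoreTable):
        obj.df.to_csv(path, index=False)
    elif isinstance(obj, InteractionList):
        df = obj.df.copy()
        if "t" in df.columns:
            df["t"] = df["t"].dt.strftime(DEFAULT_DATETIME_FORMAT)
        df.to_csv(path, index=False)
    elif isinstance(obj, EventLog):
        df = obj.df.copy()
        df["IN"] = df.pop("t_in").dt.strftime(DEFAULT_DATETIME_FORMAT)
        df["OUT"] = df.pop("t_out").dt.strftime(DEFAULT_DATETIME_FORMAT)
        df[["equip_id", "animal_id", "IN", "OUT"]].to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def _read_matrix_frame(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, index_col=0, dtype=str)
    labels = [str(x) for x in frame.columns]
    values = frame.to_numpy(dtype=float).T  # file is reactor×actor
    return labels, values


def read_sociomatrix(path: str | Path):
    from .dominance import SocioMatrix

    labels, values = _read_matrix_frame(path)
    return SocioMatrix(labels, values.astype(np.int64))


def read_dyadic_matrix(path: str | Path):
    from .dominance import DyadicMatrix

    labels, values = _read_matrix_frame(path)
    return DyadicMatrix(labels, values.astype(np.int8))


def read_dominance_table(path: str | Path):
    from .dominance import DominanceTable

    df = pd.read_csv(path, dtype={"animal_id": str})
    df["dominance_value"] = df["dominance_value"].astype(np.int64)
    return DominanceTable(df)


def read_frequency_table(path: str | Path):
    from .detection import FrequencyTable

    df = pd.read_csv(path, dtype={"animal_id": str})
    return FrequencyTable(df)


def read_bin_frequency_table(path: str | Path):
    from .detection import BinFrequencyTable

    df = pd.read_csv(path, dtype={"equip_id": str})
    return BinFrequencyTable(df)


def read_score_table(path: str | Path, method: str = ""):
    from .indices import ScoreTable

    df = pd.read_csv(path, dtype={"animal_id": str})
    return ScoreTable(method=method or "scores", df=df)
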