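"""Competitive-replacement detection and frequency summaries.

A replacement is the elementary competitive event at an electronic bin: the
animal occupying the bin (the *reactor*) withdraws and a *different* animal
(the *actor*) enters the same bin within a short time interval. Detection is
a single linear scan of the log sorted by ``(equip_id, t_in)``: each visit
is compared only with its immediate predecessor at the same bin, and the
gap is the next entry time minus the previous exit time, in whole seconds
(the hardware records at second resolution).

The threshold ``sec`` is species- and context-dependent — published values
for cattle range from ~10 s to ~30 s — and is always supplied by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import EventLog, InteractionList

logger = logging.getLogger("herdrank")


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the replacement detector.

    Parameters
    ----------
    sec
        Time-interval threshold in seconds (non-negative).
    gap_comparison
        ``"lt"`` accepts gaps strictly below ``sec`` (default, the stated
        rule); ``"le"`` accepts gaps up to and including ``sec``.
    allow_negative_gap
        Entries recorded before the previous exit (overlapping reads) are
        not replacements by default — the previous animal must have fully
        withdrawn. When true they are treated as gap 0.
    """

    sec: float = 10.0
    gap_comparison: str = "lt"
    allow_negative_gap: bool = False

    def __post_init__(self) -> None:
        if self.sec < 0:
            raise ParameterError(f"sec must be >= 0, got {self.sec}")
        if self.gap_comparison not in ("lt", "le"):
            raise ParameterError(
                f"gap_comparison must be 'lt' or 'le', got "
                f"{self.gap_comparison!r}")


@dataclass(eq=False)
class FrequencyTable:
    """Per-animal interaction counts with percentages of the total."""

    df: pd.DataFrame  # columns: animal_id, count, percent

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True))


@dataclass(eq=False)
class BinFrequencyTable:
    """Per-bin replacement counts with percentages of the total."""

    df: pd.DataFrame  # columns: equip_id, replacements, percent

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinFrequencyTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True))


def detect_replacements(
    log: EventLog, cfg: DetectionConfig | None = None
) -> InteractionList:
    """Scan an event log for competitive replacements.

    Returns one interaction per qualifying consecutive same-bin pair, in
    ``(equip_id, t_in)`` order: the later animal is the actor, the earlier
    the reactor. Consecutive visits by the same animal never qualify.
    """
    cfg = cfg or DetectionConfig()
    if len(log) == 0:
        return InteractionList()

    df = log.canonical()
    same_bin = df["equip_id"].eq(df["equip_id"].shift())
    prev_animal = df["animal_id"].shift()
    prev_out = df["t_out"].shift()
    gap = (df["t_in"] - prev_out).dt.total_seconds()

    if same_bin.any():
        ties = same_bin & df["t_in"].eq(df["t_in"].shift())
        if ties.any():
            logger.warning(
                "%d tied entry time(s) within a bin; actor/reactor "
                "assignment follows input order", int(ties.sum()))

    if cfg.allow_negative_gap:
        gap = gap.clip(lower=0.0)
    upper = gap < cfg.sec if cfg.gap_comparison == "lt" else gap <= cfg.sec
    hit = (
        same_bin
        & df["animal_id"].ne(prev_animal)
        & (gap >= 0)
        & upper
    )

    out = pd.DataFrame(
        {
            "actor": df.loc[hit, "animal_id"].to_numpy(),
            "reactor": prev_animal[hit].to_numpy(),
            "equip_id": df.loc[hit, "equip_id"].to_numpy(),
            "t": df.loc[hit, "t_in"].to_numpy(),
        }
    )
    return InteractionList(out)


def replacements_by_bin(
    log: EventLog, cfg: DetectionConfig | None = None
) -> BinFrequencyTable:
    """Replacement counts per bin; bins with no replacements appear as 0."""
    interactions = detect_replacements(log, cfg)
    counts = interactions.df.groupby("equip_id").size() if len(interactions) \
        else pd.Series(dtype=np.int64)
    rows = pd.DataFrame(
        {
            "equip_id": sorted(log.bins),
            "replacements": [int(counts.get(b, 0)) for b in sorted(log.bins)],
        }
    )
    total = rows["replacements"].sum()
    rows["percent"] = (
        100.0 * rows["replacements"] / total if total else 0.0
    )
    return BinFrequencyTable(rows)


def _frequency(interactions: InteractionList, column: str) -> FrequencyTable:
    if len(interactions) == 0:
        return FrequencyTable(
            pd.DataFrame(columns=["animal_id", "count", "percent"]))
    counts = interactions.df[column].value_counts()
    df = pd.DataFrame(
        {
            "animal_id": counts.index.astype(str),
            "count": counts.to_numpy(dtype=np.int64),
            "percent": 100.0 * counts.to_numpy() / len(interactions),
        }
    ).sort_values("animal_id", kind="mergesort", key=_freq_sort_key)
    return FrequencyTable(df.reset_index(drop=True))


def _freq_sort_key(s: pd.Series) -> pd.Series:
    from .dominance import natural_sort_key

    return s.map(natural_sort_key)


def actor_frequency(interactions: InteractionList) -> FrequencyTable:
    """How often each animal won (appeared as actor).

    Animals that never acted are absent; percentages are of all
    interactions, so the ``percent`` column sums to 100 together with the
    reactor table's complement of animals.
    """
    return _frequency(interactions, "actor")


def reactor_frequency(interactions: InteractionList) -> FrequencyTable:
    """How often each animal was displaced (appeared as reactor)."""
    return _frequency(interactions, "reactor")
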