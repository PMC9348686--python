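"""Sociomatrix, dyadic dominance matrix and Kondo–Hurnik dominance values.

The Kondo–Hurnik index scores every animal by the *sign* of its dyadic
relationships rather than by weighted win proportions: dyad (i, j) counts
+1 for i if i beat j more often than the reverse, −1 if less often, and 0
when tied or never observed. The per-animal dominance value ``S_i`` is the
sum of those signs over all herd mates, so values range over
``[-(n-1), n-1]`` and sum to zero across the herd.

Social rank (2 classes) and social hierarchy (3 classes) cut the occupied
value range ``[min, max]`` into equal-width bins of size
``(max - min + 1) / k``; the lowest bin is "low"/"subordinate".

Internally matrices are actor-rows × reactor-columns; serialization via
:func:`herdrank.io.write_table` transposes to the conventional printed
orientation (reactors down the rows, actors across the columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import InteractionList

logger = logging.getLogger("herdrank")

RANK_LABELS = ("low", "high")
HIERARCHY_LABELS = ("subordinate", "intermediate", "dominant")


def natural_sort_key(label: str) -> tuple:
    """Numeric-aware ordering key: all-digit ids sort as integers."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), s)
    return (1, 0, s)


def canonical_labels(ids) -> list[str]:
    """Distinct ids in canonical order (numeric when all ids are numeric)."""
    distinct = {str(x) for x in ids}
    if all(s.isdigit() for s in distinct):
        return sorted(distinct, key=int)
    return sorted(distinct)


@dataclass(eq=False)
class SocioMatrix:
    """Square count matrix: ``values[i, j]`` = wins of i (actor) over j."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=np.int64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels")
        if (self.values < 0).any():
            raise ValidationError("sociomatrix counts must be non-negative")
        if np.diag(self.values).any():
            raise ValidationError("sociomatrix diagonal must be zero")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SocioMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def total(self) -> int:
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


@dataclass(eq=False)
class DyadicMatrix:
    """Antisymmetric sign matrix with entries in {−1, 0, +1}."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=np.int8)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValidationError("dyadic entries must be in {-1, 0, +1}")
        if not np.array_equal(self.values, -self.values.T):
            raise ValidationError("dyadic matrix must be antisymmetric")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DyadicMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


@dataclass(eq=False)
class DominanceTable:
    """Per-animal dominance value with optional rank/hierarchy classes."""

    df: pd.DataFrame  # animal_id, dominance_value [, social_rank,
    #                   social_hierarchy]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DominanceTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True))

    def scores(self) -> pd.Series:
        return pd.Series(
            self.df["dominance_value"].to_numpy(),
            index=self.df["animal_id"].to_numpy(),
        )


def sociomatrix(
    interactions: InteractionList, roster: Sequence[str] | None = None
) -> SocioMatrix:
    """Tally actor-over-reactor counts into a square matrix.

    Labels are the union of ids seen in the interactions and the optional
    roster, in canonical (numeric-aware) order; roster-only animals get
    all-zero rows and columns.
    """
    ids = set(interactions.animals)
    if roster is not None:
        ids |= {str(x) for x in roster}
    labels = canonical_labels(ids)
    index = {lab: k for k, lab in enumerate(labels)}
    X = np.zeros((len(labels), len(labels)), dtype=np.int64)
    if len(interactions):
        a = interactions.df["actor"].map(index).to_numpy()
        r = interactions.df["reactor"].map(index).to_numpy()
        np.add.at(X, (a, r), 1)
    return SocioMatrix(labels, X)


def dyadic_matrix(m: SocioMatrix) -> DyadicMatrix:
    """Sign of the win-count difference per ordered pair.

    Ties — equal nonzero counts as well as never-observed dyads — map to 0,
    which also guards the 0/0 case of the sign quotient.
    """
    diff = m.values - m.values.T
    return DyadicMatrix(m.labels, np.sign(diff).astype(np.int8))


def categorize(
    values: Sequence[int] | np.ndarray,
    k: int,
    labels: Sequence[str] | None = None,
) -> list[str]:
    """Equal-width binning of dominance values into k ordered classes.

    The occupied range has ``max - min + 1`` integer points; each class
    spans ``(max - min + 1) / k`` of them (real-valued, no rounding), and a
    value lands in class ``floor((v - min) / size)``, clipped to the top
    class. With k=2 the classes are low/high, with k=3
    subordinate/intermediate/dominant.

    A degenerate range (all values equal, e.g. a single animal) cannot be
    split: everyone is assigned the middle class for k=3 and the low class
    for k=2, with a warning.
    """
    if k not in (2, 3):
        raise ParameterError(f"k must be 2 or 3, got {k}")
    values = np.asarray(values)
    if values.size == 0:
        raise ParameterError("cannot categorize an empty value vector")
    if labels is None:
        labels = RANK_LABELS if k == 2 else HIERARCHY_LABELS
    if len(labels) != k:
        raise ParameterError(f"need {k} labels, got {len(labels)}")

    lo, hi = int(values.min()), int(values.max())
    if lo == hi:
        logger.warning(
            "degenerate dominance range (all values %d); assigning every "
            "animal the %s class", lo, labels[0 if k == 2 else 1])
        fill = labels[0] if k == 2 else labels[1]
        return [fill] * values.size
    size = (hi - lo + 1) / k
    bins = np.floor((values - lo) / size).astype(int)
    bins = np.clip(bins, 0, k - 1)
    return [labels[b] for b in bins]


def dominance_values(
    d: DyadicMatrix,
    with_rank: bool = True,
    with_hierarchy: bool = True,
    rank_labels: Sequence[str] = RANK_LABELS,
    hierarchy_labels: Sequence[str] = HIERARCHY_LABELS,
) -> DominanceTable:
    """Kondo–Hurnik dominance value S_i per animal, sorted ascending.

    ``S_i`` sums animal i's dyadic signs over all herd mates; rank and
    hierarchy classes come from :func:`categorize` with k=2 and k=3.
    """
    if d.n == 0:
        return DominanceTable(
            pd.DataFrame(columns=["animal_id", "dominance_value"]))
    s = d.values.sum(axis=1).astype(np.int64)
    df = pd.DataFrame({"animal_id": d.labels, "dominance_value": s})
    if with_hierarchy:
        df["social_hierarchy"] = categorize(s, 3, hierarchy_labels)
    if with_rank:
        df["social_rank"] = categorize(s, 2, rank_labels)
    df = df.sort_values(
        ["dominance_value", "animal_id"],
        kind="mergesort",
        key=lambda col: col.map(natural_sort_key)
        if col.name == "animal_id" else col,
    )
    return DominanceTable(df.reset_index(drop=True))
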