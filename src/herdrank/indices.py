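"""Comparison dominance indices: David's score, Elo rating, correlations.

These serve as cross-checks on the sign-based Kondo–Hurnik values. David's
score weights each dyadic win proportion by the opponents' overall success
and is zero-sum over the herd; Elo is a sequential rating updated per
interaction, order-dependent, and conserves the total rating. Method
agreement is summarised by pairwise Pearson correlation over the shared
roster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dominance import DominanceTable, SocioMatrix, canonical_labels
from .errors import ParameterError, ValidationError
from .io import InteractionList


@dataclass(eq=False)
class ScoreTable:
    """One dominance score per animal, for one method."""

    method: str
    df: pd.DataFrame  # columns: animal_id, score

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self.method == other.method and self.df.reset_index(
            drop=True).equals(other.df.reset_index(drop=True))

    def series(self) -> pd.Series:
        return pd.Series(self.df["score"].to_numpy(),
                         index=self.df["animal_id"].to_numpy())


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between two methods' scores."""

    method_a: str
    method_b: str
    r: float
    p: float
    n: int


def davids_score(m: SocioMatrix, variant: str = "Pij") -> ScoreTable:
    """David's score DS = w + w₂ − l − l₂ over dyadic win proportions.

    ``Pij`` uses the raw proportion X_ij/(X_ij+X_ji); ``Dij`` applies the
    sample-size correction P_ij − (P_ij − 0.5)/(n_ij + 1), which shrinks
    proportions from sparsely observed dyads toward 0.5. Dyads with no
    interactions contribute 0 either way.
    """
    if m.n < 2:
        raise ParameterError("David's score needs at least 2 animals")
    if variant not in ("Pij", "Dij"):
        raise ParameterError(f"variant must be 'Pij' or 'Dij', got {variant!r}")

    X = m.values.astype(float)
    nij = X + X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(nij > 0, X / np.where(nij > 0, nij, 1), 0.0)
    if variant == "Dij":
        P = np.where(nij > 0, P - (P - 0.5) / (nij + 1), 0.0)
    np.fill_diagonal(P, 0.0)

    w = P.sum(axis=1)
    w2 = P @ w
    L = P.T  # losses: l_i = sum_j P_ji
    l = L.sum(axis=1)
    l2 = L @ l
    ds = w + w2 - l - l2
    return ScoreTable(
        method=f"davids_score_{variant}",
        df=pd.DataFrame({"animal_id": m.labels, "score": ds}),
    )


def elo_rating(
    interactions: InteractionList,
    k: float = 100.0,
    start: float = 1000.0,
    roster: Sequence[str] | None = None,
) -> ScoreTable:
    """Sequential Elo ratings over the interaction list, in input order.

    The winner (actor) gains ``k·(1−E)`` where ``E`` is its expected win
    probability ``1/(1+10^((R_loser−R_winner)/400))``; the loser loses the
    same amount, so the total rating stays at ``n·start``.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    ratings: dict[str, float] = {}
    if roster is not None:
        ratings.update({str(a): float(start) for a in roster})
    for row in interactions.df.itertuples(index=False):
        ra = ratings.setdefault(row.actor, float(start))
        rr = ratings.setdefault(row.reactor, float(start))
        expected = 1.0 / (1.0 + 10.0 ** ((rr - ra) / 400.0))
        delta = k * (1.0 - expected)
        ratings[row.actor] = ra + delta
        ratings[row.reactor] = rr - delta
    labels = canonical_labels(ratings)
    return ScoreTable(
        method="elo",
        df=pd.DataFrame(
            {"animal_id": labels, "score": [ratings[a] for a in labels]}),
    )


def kondo_hurnik_scores(t: DominanceTable) -> ScoreTable:
    """Repackage Kondo–Hurnik dominance values as a ScoreTable."""
    return ScoreTable(
        method="kondo_hurnik",
        df=pd.DataFrame(
            {
                "animal_id": t.df["animal_id"].to_numpy(),
                "score": t.df["dominance_value"].to_numpy(dtype=float),
            }
        ),
    )


def method_correlations(
    tables: Iterable[ScoreTable],
) -> list[CorrelationReport]:
    """Pairwise Pearson r (two-sided p) between methods on shared animals."""
    tables = list(tables)
    if len(tables) < 2:
        raise ParameterError("need at least two score tables to correlate")
    reports = []
    for ta, tb in combinations(tables, 2):
        joined = pd.merge(
            ta.df, tb.df, on="animal_id", suffixes=("_a", "_b"))
        if len(joined) < 3:
            raise ValidationError(
                f"methods {ta.method!r} and {tb.method!r} share only "
                f"{len(joined)} animals; need at least 3")
        r, p = stats.pearsonr(joined["score_a"], joined["score_b"])
        reports.append(
            CorrelationReport(ta.method, tb.method, float(r), float(p),
                              len(joined)))
    return reports
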