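"""Landau's linearity index h and de Vries's improved index h′.

Landau's h measures how close a set of dominance relationships is to a
strict linear order. With ``V_a`` the number of herd mates animal *a*
dominates (count of +1 entries in its dyadic row),

    h = 12 / (n³ − n) · Σ_a (V_a − (n − 1)/2)²

h = 1 for every strict linear hierarchy and 0 when every animal dominates
the same number of others (e.g. a circular triad). Unknown dyads (no
interaction in either direction) depress V uniformly, so de Vries proposed
the additive correction

    h′ = h + 6 u / (n³ − n)

with ``u`` the number of unknown dyads. Ties (equal nonzero win counts)
are not unknown and do not enter ``u``, which is why the improved index
needs the sociomatrix as well as the dyadic matrix — the sign matrix alone
cannot distinguish tied from never-observed.

Both formulas are applied exactly as stated; with sparse data h can exceed
1 and no renormalisation is attempted. A value of h above ~0.9 is
conventionally read as a strongly linear hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dominance import DyadicMatrix, SocioMatrix
from .errors import ParameterError, ValidationError

#: Conventional threshold above which a hierarchy is called strongly linear.
STRONG_LINEARITY = 0.9


@dataclass(frozen=True)
class LinearityResult:
    """Linearity summary for one herd."""

    n: int
    V: tuple[int, ...]
    u: int
    h: float
    h_prime: float | None = None

    def annotation(self) -> str:
        best = self.h_prime if self.h_prime is not None else self.h
        if best > STRONG_LINEARITY:
            return "strongly linear hierarchy (index > 0.9)"
        return "not strongly linear (index <= 0.9)"


def dominated_counts(d: DyadicMatrix) -> np.ndarray:
    """V_a = number of animals each animal dominates (+1 entries as actor)."""
    return (d.values == 1).sum(axis=1).astype(np.int64)


def landau_index(d: DyadicMatrix) -> float:
    """Landau's h from a dyadic dominance matrix (needs n ≥ 2)."""
    n = d.n
    if n < 2:
        raise ParameterError(
            f"linearity is undefined for n={n}; need at least 2 animals")
    V = dominated_counts(d)
    dev = V - (n - 1) / 2.0
    return float(12.0 / (n**3 - n) * np.sum(dev**2))


def count_unknown(m: SocioMatrix) -> int:
    """Number of unordered dyads with no interaction in either direction."""
    both_zero = (m.values == 0) & (m.values.T == 0)
    np.fill_diagonal(both_zero, False)
    return int(both_zero.sum() // 2)


def improved_index(d: DyadicMatrix, m: SocioMatrix) -> float:
    """de Vries's h′ = h + 6u/(n³−n); equals h when no dyad is unknown."""
    if d.labels != m.labels:
        raise ValidationError(
            "dyadic and sociomatrix label sets differ; build both from the "
            "same interactions")
    n = d.n
    h = landau_index(d)
    return float(h + 6.0 / (n**3 - n) * count_unknown(m))


def linearity(d: DyadicMatrix, m: SocioMatrix | None = None) -> LinearityResult:
    """Full linearity summary (h, and h′ when a sociomatrix is given)."""
    h = landau_index(d)
    V = tuple(int(v) for v in dominated_counts(d))
    if m is None:
        return LinearityResult(n=d.n, V=V, u=0, h=h, h_prime=None)
    u = count_unknown(m)
    return LinearityResult(n=d.n, V=V, u=u, h=h, h_prime=improved_index(d, m))
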