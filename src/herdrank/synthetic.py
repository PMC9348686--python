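"""Synthetic interaction lists and bin-event logs with a known hierarchy.

Every stage of the pipeline is testable without real barn data: the
generator plants a latent strict linear dominance order over the herd and
emits either (a) bare actor/reactor interactions, where each staged contest
is won by the higher-ranked animal with probability ``1 − p_upset``, or
(b) a full multi-bin event log in which competitive replacements are
inserted as consecutive visit pairs with a configurable entry/exit gap,
embedded in background visits whose gaps are too large to ever trigger the
detector.

Background visit structure is deliberately simple — bin choice uniform,
visit durations exponential (default mean 120 s), visit counts Poisson —
just enough to exercise the detector's per-bin sorting, gap arithmetic and
same-animal rule. No diurnal feeding pattern or intake model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import EventLog, InteractionList

#: All synthetic timestamps count forward from this instant.
EPOCH = pd.Timestamp("2021-01-01 06:00:00")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``latent_order`` lists animal ids from most to least dominant;
    ``inserted_replacements`` holds the staged (actor, reactor, equip_id,
    gap-seconds) tuples for bin logs (empty for bare interaction lists).
    """

    latent_order: tuple[str, ...]
    p_upset: float
    seed: int
    inserted_replacements: tuple[tuple[str, str, str, int], ...] = field(
        default_factory=tuple)

    def rank(self, animal: str) -> int:
        """0 = most dominant."""
        return self.latent_order.index(animal)


def _make_ids(n: int, start: int = 101) -> list[str]:
    return [str(start + i) for i in range(n)]


def _staged_pair(
    rng: np.random.Generator,
    latent_order: tuple[str, ...],
    p_upset: float,
) -> tuple[str, str]:
    """Pick a dyad uniformly; the higher-ranked wins w.p. 1 − p_upset."""
    n = len(latent_order)
    i, j = rng.choice(n, size=2, replace=False)
    hi, lo = (i, j) if i < j else (j, i)  # hi = better (smaller) rank
    if rng.random() < p_upset:
        hi, lo = lo, hi
    return latent_order[hi], latent_order[lo]


def simulate_interactions(
    n_animals: int,
    n_events: int,
    p_upset: float = 0.1,
    seed: int = 0,
) -> tuple[InteractionList, SyntheticTruth]:
    """Draw actor/reactor interactions from a latent linear hierarchy."""
    if n_animals < 2:
        raise ParameterError(f"need at least 2 animals, got {n_animals}")
    if n_events < 0:
        raise ParameterError(f"n_events must be >= 0, got {n_events}")
    if not 0.0 <= p_upset <= 0.5:
        raise ParameterError(
            f"p_upset must be in [0, 0.5], got {p_upset}")
    rng = np.random.default_rng(seed)
    ids = _make_ids(n_animals)
    latent = tuple(rng.permutation(ids))
    pairs = [_staged_pair(rng, latent, p_upset) for _ in range(n_events)]
    truth = SyntheticTruth(latent_order=latent, p_upset=p_upset, seed=seed)
    return InteractionList.from_pairs(pairs), truth


def simulate_bin_log(
    n_animals: int,
    n_bins: int = 5,
    n_days: int = 3,
    visit_rate: float = 10.0,
    gap_range: tuple[int, int] = (0, 9),
    background_events: int | None = None,
    n_replacements: int = 50,
    p_upset: float = 0.1,
    seed: int = 0,
    visit_mean_s: float = 120.0,
    min_background_gap: int = 61,
) -> tuple[EventLog, SyntheticTruth]:
    """Generate a multi-bin event log with planted replacements.

    Parameters
    ----------
    visit_rate
        Expected background visits per animal per day; the realised total
        is Poisson unless ``background_events`` pins it exactly.
    gap_range
        Inclusive integer bounds (seconds) for the entry/exit gap of every
        staged replacement pair.
    n_replacements
        Number of staged replacement pairs inserted across all bins.
    min_background_gap
        Smallest gap (seconds) preceding any non-staged visit; detection at
        any threshold ``sec <= min_background_gap`` therefore recovers
        exactly the staged pairs — background visits cannot collide.

    Notes
    -----
    Each staged pair occupies one bin timeline slot: the reactor's visit,
    then the actor's entry ``gap`` seconds after the reactor's exit. All
    other inter-visit gaps are at least ``min_background_gap``. Timestamps
    have second resolution and start at 06:00 on day one; ``n_days`` only
    scales the expected background count.
    """
    if n_animals < 2 or n_bins < 1:
        raise ParameterError("need n_animals >= 2 and n_bins >= 1")
    if not 0.0 <= p_upset <= 0.5:
        raise ParameterError(f"p_upset must be in [0, 0.5], got {p_upset}")
    lo, hi = int(gap_range[0]), int(gap_range[1])
    if lo < 0 or hi < lo:
        raise ParameterError(f"bad gap_range {gap_range}")
    if hi >= min_background_gap:
        raise ParameterError(
            "gap_range must stay below min_background_gap, otherwise "
            "staged and background gaps are not separable")
    if visit_rate <= 0 or visit_mean_s <= 0 or n_days < 1:
        raise ParameterError("rates and durations must be positive")
    if n_replacements < 0 or (background_events or 0) < 0:
        raise ParameterError("event counts must be non-negative")

    rng = np.random.default_rng(seed)
    ids = _make_ids(n_animals)
    latent = tuple(rng.permutation(ids))

    n_background = (
        int(background_events)
        if background_events is not None
        else int(rng.poisson(visit_rate * n_animals * n_days))
    )
    bins = [f"F{b + 1}" for b in range(n_bins)]
    # one slot per background visit (0) or staged pair (1), spread over bins
    slot_bins = rng.integers(0, n_bins, size=n_background + n_replacements)
    slot_kind = np.zeros(n_background + n_replacements, dtype=int)
    slot_kind[n_background:] = 1
    rng.shuffle(slot_kind)

    rows: list[tuple[str, str, pd.Timestamp, pd.Timestamp]] = []
    inserted: list[tuple[str, str, str, int]] = []
    cursors = {b: EPOCH for b in bins}

    def _duration() -> pd.Timedelta:
        return pd.Timedelta(
            seconds=max(1, int(round(rng.exponential(visit_mean_s)))))

    for kind, b_idx in zip(slot_kind, slot_bins):
        b = bins[b_idx]
        lead = pd.Timedelta(
            seconds=int(min_background_gap + rng.integers(0, 300)))
        if kind == 0:
            animal = ids[rng.integers(0, n_animals)]
            t_in = cursors[b] + lead
            t_out = t_in + _duration()
            rows.append((b, animal, t_in, t_out))
            cursors[b] = t_out
        else:
            actor, reactor = _staged_pair(rng, latent, p_upset)
            r_in = cursors[b] + lead
            r_out = r_in + _duration()
            gap = int(rng.integers(lo, hi + 1))
            a_in = r_out + pd.Timedelta(seconds=gap)
            a_out = a_in + _duration()
            rows.append((b, reactor, r_in, r_out))
            rows.append((b, actor, a_in, a_out))
            inserted.append((actor, reactor, b, gap))
            cursors[b] = a_out

    df = pd.DataFrame(
        rows, columns=["equip_id", "animal_id", "t_in", "t_out"]
    ).sort_values("t_in", kind="mergesort").reset_index(drop=True)
    truth = SyntheticTruth(
        latent_order=latent,
        p_upset=p_upset,
        seed=seed,
        inserted_replacements=tuple(inserted),
    )
    return EventLog(df), truth


def recovery_metrics(
    detected: InteractionList, truth: SyntheticTruth
) -> dict[str, float]:
    """Precision/recall of detected pairs against the staged insertions.

    Pairs are compared as (actor, reactor, equip_id) multisets, so a
    staged pair detected twice or with swapped roles counts against both
    metrics.
    """
    from collections import Counter

    got = Counter(
        (r.actor, r.reactor, r.equip_id) for r in detected)
    want = Counter((a, r, b) for a, r, b, _ in truth.inserted_replacements)
    tp = sum((got & want).values())
    precision = tp / sum(got.values()) if got else 1.0
    recall = tp / sum(want.values()) if want else 1.0
    return {"precision": precision, "recall": recall,
            "true_positives": float(tp)}
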