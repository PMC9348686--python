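"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import pandas as pd
import pytest
from hypothesis import settings

import herdrank as hr

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

BASE = datetime(2021, 1, 1, 8, 0, 0)


def make_log(rows) -> hr.EventLog:
    """EventLog from (equip_id, animal_id, in_offset_s, out_offset_s) rows."""
    df = pd.DataFrame(
        [
            {
                "equip_id": b,
                "animal_id": a,
                "t_in": pd.Timestamp(BASE + timedelta(seconds=s_in)),
                "t_out": pd.Timestamp(BASE + timedelta(seconds=s_out)),
            }
            for b, a, s_in, s_out in rows
        ]
    )
    return hr.EventLog(df)


def brute_force_replacements(rows, sec, cmp="lt"):
    """Independent replacement oracle on (bin, animal, in_s, out_s) tuples.

    Enumerates consecutive same-bin pairs directly from the tuples with a
    stable per-bin sort on entry offset, never touching the package's
    sorting or scanning code.
    """
    by_bin: dict[str, list[tuple[int, str, int, int]]] = {}
    for idx, (b, a, s_in, s_out) in enumerate(rows):
        by_bin.setdefault(b, []).append((idx, a, s_in, s_out))
    hits = []
    for b in sorted(by_bin):
        ordered = sorted(by_bin[b], key=lambda r: (r[2], r[0]))
        for (_, pa, _, p_out), (q_idx, qa, q_in, _) in zip(
            ordered, ordered[1:]
        ):
            gap = q_in - p_out
            ok_upper = gap < sec if cmp == "lt" else gap <= sec
            if qa != pa and gap >= 0 and ok_upper:
                hits.append((qa, pa, b, q_in))
    return hits


def random_log_rows(rng, n_events=60, n_bins=3, n_animals=5, span=600):
    """Dense random rows designed to create collisions, overlaps, ties."""
    rows = []
    for _ in range(n_events):
        b = f"B{rng.integers(1, n_bins + 1)}"
        a = f"A{rng.integers(1, n_animals + 1)}"
        s_in = int(rng.integers(0, span))
        s_out = s_in + int(rng.integers(0, 90))
        rows.append((b, a, s_in, s_out))
    return rows


@pytest.fixture
def tiny_interactions() -> hr.InteractionList:
    return hr.InteractionList.from_pairs(
        [("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def linear_dyadic() -> hr.DyadicMatrix:
    """Strict linear order A > B > C."""
    socio = hr.sociomatrix(
        hr.InteractionList.from_pairs([("A", "B"), ("A", "C"), ("B", "C")]))
    return hr.dyadic_matrix(socio)
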