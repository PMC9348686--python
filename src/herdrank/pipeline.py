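"""End-to-end analysis: detection → matrices → dominance → linearity →
comparison indices, as one call.

This is the library counterpart of the ``herdrank run`` CLI command; both
produce identical artifacts from the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detection import (
    BinFrequencyTable,
    DetectionConfig,
    FrequencyTable,
    actor_frequency,
    reactor_frequency,
    replacements_by_bin,
)
from .dominance import (
    DominanceTable,
    DyadicMatrix,
    SocioMatrix,
    dominance_values,
    dyadic_matrix,
    sociomatrix,
)
from .indices import (
    CorrelationReport,
    ScoreTable,
    davids_score,
    elo_rating,
    kondo_hurnik_scores,
    method_correlations,
)
from .io import EventLog, InteractionList
from .linearity import LinearityResult, linearity


@dataclass
class RunResult:
    """All artifacts of one analysis run."""

    interactions: InteractionList
    socio: SocioMatrix
    dyadic: DyadicMatrix
    dominance: DominanceTable
    linearity: LinearityResult
    freq_actor: FrequencyTable
    freq_reactor: FrequencyTable
    freq_bin: BinFrequencyTable | None
    scores: list[ScoreTable] = field(default_factory=list)
    correlations: list[CorrelationReport] = field(default_factory=list)
    config: DetectionConfig | None = None
    n_events: int | None = None

    def summary(self) -> dict:
        """JSON-ready run summary (parameters and headline quantities)."""
        out = {
            "n_events": self.n_events,
            "n_animals": self.socio.n,
            "n_interactions": len(self.interactions),
            "unknown_dyads": self.linearity.u,
            "landau_h": self.linearity.h,
            "improved_h_prime": self.linearity.h_prime,
            "linearity_note": self.linearity.annotation(),
            "correlations": [
                {"methods": [c.method_a, c.method_b], "r": c.r, "p": c.p,
                 "n": c.n}
                for c in self.correlations
            ],
        }
        if self.config is not None:
            out["parameters"] = {
                "sec": self.config.sec,
                "gap_comparison": self.config.gap_comparison,
                "allow_negative_gap": self.config.allow_negative_gap,
            }
        return out


def analyze_interactions(
    interactions: InteractionList,
    roster=None,
    elo_k: float = 100.0,
    elo_start: float = 1000.0,
) -> RunResult:
    """Run everything downstream of detection on an interaction list."""
    socio = sociomatrix(interactions, roster)
    dyadic = dyadic_matrix(socio)
    dom = dominance_values(dyadic)
    lin = linearity(dyadic, socio)
    scores = [
        kondo_hurnik_scores(dom),
        davids_score(socio),
        elo_rating(interactions, k=elo_k, start=elo_start,
                   roster=socio.labels),
    ]
    corr = method_correlations(scores) if socio.n >= 3 else []
    return RunResult(
        interactions=interactions,
        socio=socio,
        dyadic=dyadic,
        dominance=dom,
        linearity=lin,
        freq_actor=actor_frequency(interactions),
        freq_reactor=reactor_frequency(interactions),
        freq_bin=None,
        scores=scores,
        correlations=corr,
    )


def analyze(log: EventLog, cfg: DetectionConfig | None = None) -> RunResult:
    """Full pipeline from a raw bin-event log."""
    from .detection import detect_replacements

    cfg = cfg or DetectionConfig()
    interactions = detect_replacements(log, cfg)
    result = analyze_interactions(interactions)
    result.freq_bin = replacements_by_bin(log, cfg)
    result.config = cfg
    result.n_events = len(log)
    return result
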