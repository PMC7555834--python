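"""In-memory end-to-end helpers: scenario -> QC -> WSS -> timeline.

These glue functions run the same steps as the CLI without touching the
filesystem; they back the simulation studies (cutoff calibration on
labeled pairs, scenario-recovery rates) and are convenient for
programmatic use.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from . import qc_filters, timeline, wss_core
from .calibration import CalibrationResult, calibrate_cutoff
from .datatypes import (
    LabeledScoreSet,
    Pattern,
    RelatednessCall,
    StabilityPattern,
    WssScore,
)
from .synthetic_data import SCENARIOS, ScenarioData, ScenarioSpec, simulate_scenario

__all__ = [
    "score_scenario",
    "recover_pattern",
    "generate_labeled_scores",
    "calibrate_on_scenarios",
]


def score_scenario(data: ScenarioData, min_windows: int = 1) -> List[WssScore]:
    """Sample QC, window masking and all-pairs WSS for one realized scenario."""
    qcs = {t.sample_id: qc_filters.sample_qc(t, data.species) for t in data.tracks}
    mask = qc_filters.build_window_mask(
        data.tracks, data.species, window_size=data.spec.window_size
    )
    return wss_core.score_all_pairs(data.profiles, mask, qcs, min_windows=min_windows)


def recover_pattern(data: ScenarioData, cutoff: float) -> Optional[Pattern]:
    """Run the full pipeline on a realized scenario and classify its
    stability pattern; None when the series is unscorable."""
    scores = score_scenario(data)
    cutoffs = {data.species.species_id: cutoff}
    calls = []
    for s in scores:
        if s.valid:
            call = wss_core.call_relatedness(s, cutoffs)
            if call is not None:
                calls.append(call)
    try:
        tl = timeline.build_anchor_mosaic(
            calls, data.meta, data.spec.subject_id, data.species.species_id
        )
        return timeline.classify_pattern(tl).pattern
    except (timeline.TimelineSkip, ValueError):
        return None


def generate_labeled_scores(
    n_per_class: int,
    seed: int,
    **spec_kwargs,
) -> LabeledScoreSet:
    """Score synthetic pairs with known strain identity until both label
    classes hold ``n_per_class`` scores.

    Replicates cycle through all four scenarios so both classes arise in
    the same joint-genotyping contexts the pipeline sees: same-strain pairs
    are labeled related, cross-strain pairs unrelated.
    """
    related: List[float] = []
    unrelated: List[float] = []
    rep = 0
    while len(related) < n_per_class or len(unrelated) < n_per_class:
        scenario = SCENARIOS[rep % len(SCENARIOS)]
        spec = ScenarioSpec(scenario=scenario, seed=seed + rep, **spec_kwargs)
        data = simulate_scenario(spec)
        for s in score_scenario(data):
            if not s.valid:
                continue
            same = data.strain_of[s.sample_a] == data.strain_of[s.sample_b]
            if same and len(related) < n_per_class:
                related.append(s.wss)
            elif not same and len(unrelated) < n_per_class:
                unrelated.append(s.wss)
        rep += 1
        if rep > 100 * max(1, n_per_class):
            raise RuntimeError("labeled score generation did not converge")
    return LabeledScoreSet(
        species_id=spec_kwargs.get("species_id", "synth_species"),
        related_scores=related,
        unrelated_scores=unrelated,
    )


def calibrate_on_scenarios(
    n_per_class: int = 100, seed: int = 0, method: str = "midpoint", **spec_kwargs
) -> CalibrationResult:
    """Calibrate a relatedness cutoff on synthetic labeled pairs."""
    labeled = generate_labeled_scores(n_per_class, seed, **spec_kwargs)
    return calibrate_cutoff(labeled, method=method)
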