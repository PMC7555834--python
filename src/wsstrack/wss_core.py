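"""The window-based SNV similarity (WSS) score and cutoff-based relatedness.

For a sample pair on one species reference, every fixed-size genome window
usable in *both* samples contributes a per-window concordance: over the
positions genotyped in both samples within the window, the fraction at
which their consensus alleles agree.  A sample genotyped as reference at a
joint record counts as carrying allele 0; a ``./.`` no-call removes the
position from that pair's comparison.  The genome-wide WSS is 100 x the
mean of the defined per-window concordances (unweighted by default; a
variant weights each window by its position count).

A pair is *related* when its WSS strictly exceeds the species cutoff and
*unrelated* otherwise; species without a cutoff are excluded from calling.
"""
from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .datatypes import (
    CutoffTable,
    RelatednessCall,
    SampleQc,
    SpeciesRef,
    StrainProfile,
    WindowMask,
    WssScore,
    pair_key,
)

__all__ = [
    "window_similarity",
    "compute_wss",
    "call_relatedness",
    "score_all_pairs",
]


def window_similarity(
    a: StrainProfile,
    b: StrainProfile,
    window: Tuple[int, int],
) -> Optional[float]:
    """Concordance of two profiles within one 0-based half-open window.

    Returns ``|{p: allele_a(p) == allele_b(p)}| / |P|`` where ``P`` is the
    set of window positions genotyped in both samples, or ``None`` when
    ``P`` is empty (the window is skipped).
    """
    start0, end0 = window
    lo, hi = start0 + 1, end0  # 1-based inclusive bounds
    shared = [p for p in a.calls if lo <= p <= hi and p in b.calls]
    if not shared:
        return None
    matches = sum(1 for p in shared if a.calls[p] == b.calls[p])
    return matches / len(shared)


def compute_wss(
    a: StrainProfile,
    b: StrainProfile,
    mask: WindowMask,
    qc_a: SampleQc,
    qc_b: SampleQc,
    min_windows: int = 1,
    weight_by_positions: bool = False,
) -> WssScore:
    """Genome-wide WSS (0-100) for one sample pair on one species.

    The score is valid only when both samples pass sample QC and at least
    ``min_windows`` windows are usable in both samples *and* contain jointly
    genotyped positions.  Symmetric in (a, b) by construction.
    """
    for obj in (b, mask, qc_a, qc_b):
        if obj.species_id != a.species_id:
            raise ValueError(
                f"species mismatch: {obj.species_id!r} vs {a.species_id!r}"
            )
    n_total = mask.n_windows
    qc_ok = qc_a.passed and qc_b.passed
    usable_a = mask.usable.get(a.sample_id)
    usable_b = mask.usable.get(b.sample_id)
    if usable_a is None or usable_b is None:
        raise ValueError("window mask missing a sample of the pair")

    sims: List[float] = []
    weights: List[int] = []
    w = mask.window_size
    for widx in range(n_total):
        if not (usable_a[widx] and usable_b[widx]):
            continue
        start0 = widx * w
        end0 = min(start0 + w, mask.reference_length)
        lo, hi = start0 + 1, end0
        shared = [p for p in a.calls if lo <= p <= hi and p in b.calls]
        if not shared:
            continue
        sims.append(sum(1 for p in shared if a.calls[p] == b.calls[p]) / len(shared))
        weights.append(len(shared))

    n_used = len(sims)
    valid = qc_ok and n_used >= max(1, min_windows)
    if valid:
        if weight_by_positions:
            wss = 100.0 * sum(s * w_ for s, w_ in zip(sims, weights)) / sum(weights)
        else:
            wss = 100.0 * sum(sims) / n_used
    else:
        wss = math.nan
    sa, sb = pair_key(a.sample_id, b.sample_id)
    return WssScore(
        species_id=a.species_id,
        sample_a=sa,
        sample_b=sb,
        wss=wss,
        n_windows_used=n_used,
        n_windows_total=n_total,
        valid=valid,
    )


def call_relatedness(score: WssScore, cutoffs: CutoffTable) -> Optional[RelatednessCall]:
    """Call a valid score against the species cutoff (related iff wss >
    cutoff, strictly).

    Returns ``None`` when the species has no cutoff — such species are
    excluded from the analysis rather than raising.
    """
    if not score.valid:
        raise ValueError(
            f"cannot call relatedness on invalid score "
            f"({score.sample_a}, {score.sample_b}) on {score.species_id}"
        )
    cutoff = cutoffs.get(score.species_id)
    if cutoff is None:
        return None
    return RelatednessCall(score=score, cutoff=cutoff, related=score.wss > cutoff)


def score_all_pairs(
    profiles: Sequence[StrainProfile],
    mask: WindowMask,
    qcs: Mapping[str, SampleQc],
    min_windows: int = 1,
    weight_by_positions: bool = False,
) -> List[WssScore]:
    """WSS for every unordered pair of profiles, in deterministic
    (sample_a, sample_b) lexicographic order."""
    by_id = {p.sample_id: p for p in profiles}
    scores = []
    for sa, sb in itertools.combinations(sorted(by_id), 2):
        scores.append(
            compute_wss(
                by_id[sa],
                by_id[sb],
                mask,
                qcs[sa],
                qcs[sb],
                min_windows=min_windows,
                weight_by_positions=weight_by_positions,
            )
        )
    return scores
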