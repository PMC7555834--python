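"""Derivation of species-specific WSS relatedness cutoffs from labeled pairs.

The real study imports cutoffs established on Human Microbiome Project
longitudinal samples; this module derives the analogous threshold from any
set of scored pairs with known labels (related = same-subject longitudinal
pair, unrelated = different-subject pair) so the pipeline is self-contained
on synthetic data.  Supplied cutoff tables are never overwritten silently.

Two methods, both documented interpretations rather than a published rule:

* ``midpoint`` — halfway between the lowest related score and the highest
  unrelated score, applicable only when the two distributions separate;
  falls back to ``max_youden`` on overlap.
* ``max_youden`` — the observed score maximizing Youden's J
  (sensitivity + specificity - 1), ties broken toward the larger threshold.

Relatedness downstream is strict (wss > cutoff), and the same convention is
used here: sensitivity counts related scores strictly above the cutoff,
specificity counts unrelated scores at or below it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .datatypes import LabeledScoreSet

__all__ = ["CalibrationResult", "calibrate_cutoff", "evaluate_cutoff"]


@dataclass(frozen=True)
class CalibrationResult:
    species_id: str
    cutoff: float
    method: str          # method actually used ("midpoint" or "max_youden")
    separable: bool      # True when related/unrelated score ranges do not overlap
    youden: float        # Youden's J at the chosen cutoff on the calibration data


def _check(labeled: LabeledScoreSet) -> None:
    if not labeled.related_scores or not labeled.unrelated_scores:
        raise ValueError(
            f"calibration for {labeled.species_id!r} requires non-empty related "
            "and unrelated score lists"
        )


def evaluate_cutoff(labeled: LabeledScoreSet, cutoff: float) -> Tuple[float, float]:
    """(sensitivity, specificity) of a cutoff on labeled scores.

    Sensitivity = fraction of related scores > cutoff; specificity =
    fraction of unrelated scores <= cutoff.
    """
    _check(labeled)
    sens = sum(1 for s in labeled.related_scores if s > cutoff) / len(labeled.related_scores)
    spec = sum(1 for s in labeled.unrelated_scores if s <= cutoff) / len(labeled.unrelated_scores)
    return sens, spec


def calibrate_cutoff(labeled: LabeledScoreSet, method: str = "midpoint") -> CalibrationResult:
    """Derive a relatedness cutoff (in [0, 100]) from labeled pair scores."""
    _check(labeled)
    if method not in ("midpoint", "max_youden"):
        raise ValueError(f"unknown calibration method {method!r}")

    lo_rel = min(labeled.related_scores)
    hi_unrel = max(labeled.unrelated_scores)
    separable = lo_rel > hi_unrel

    if method == "midpoint" and separable:
        cutoff = (lo_rel + hi_unrel) / 2.0
        sens, spec = evaluate_cutoff(labeled, cutoff)
        return CalibrationResult(labeled.species_id, cutoff, "midpoint", True, sens + spec - 1.0)

    # max_youden over observed scores (midpoint falls back here on overlap)
    best_cut, best_j = 0.0, -1.0
    for cand in sorted(set(labeled.related_scores) | set(labeled.unrelated_scores)):
        sens, spec = evaluate_cutoff(labeled, cand)
        j = sens + spec - 1.0
        if j >= best_j:  # ties broken toward the larger threshold
            best_cut, best_j = cand, j
    return CalibrationResult(labeled.species_id, best_cut, "max_youden", separable, best_j)
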