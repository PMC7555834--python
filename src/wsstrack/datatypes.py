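"""Shared domain containers for the WSS strain-tracking pipeline.

Coordinate convention: external files (VCF, depth TSV) are 1-based
inclusive; all internal window arithmetic is 0-based half-open.  The
single conversion point is the readers/writers in :mod:`wsstrack.io_formats`.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SampleMeta",
    "SpeciesRef",
    "StrainProfile",
    "DepthTrack",
    "SampleQc",
    "WindowMask",
    "WssScore",
    "RelatednessCall",
    "CutoffTable",
    "LabeledScoreSet",
    "Pattern",
    "StabilityPattern",
    "SubjectTimeline",
    "ANCHOR_GROUP",
    "ORPHAN",
    "NO_SCORE",
    "n_windows",
    "pair_key",
]


DELIVERY_MODES = ("vaginal", "cesarean", "unknown")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: who it came from and when it was collected."""

    sample_id: str
    subject_id: str
    collection_month: float
    antibiotic_exposed: bool = False
    delivery_mode: str = "unknown"

    def __post_init__(self) -> None:
        if not math.isfinite(self.collection_month) or self.collection_month < 0:
            raise ValueError(
                f"collection_month must be finite and non-negative, got "
                f"{self.collection_month!r} for sample {self.sample_id!r}"
            )
        if self.delivery_mode not in DELIVERY_MODES:
            raise ValueError(f"unknown delivery_mode {self.delivery_mode!r}")


@dataclass(frozen=True)
class SpeciesRef:
    """A species reference sequence; the cutoff may be absent (species is
    then excluded from relatedness calling downstream)."""

    species_id: str
    reference_length: int
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValueError("reference_length must be >= 1")
        if self.cutoff is not None and not (0.0 <= self.cutoff <= 100.0):
            raise ValueError(f"cutoff must lie in [0, 100], got {self.cutoff}")


@dataclass
class StrainProfile:
    """One sample's consensus genotype calls on one species reference.

    ``calls`` maps 1-based position -> allele index (0 = reference allele,
    >= 1 = alternate).  Positions with no genotype call (``./.``) are simply
    absent from the map.
    """

    sample_id: str
    species_id: str
    calls: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, allele in self.calls.items():
            if pos < 1:
                raise ValueError(f"positions are 1-based; got {pos}")
            if allele < 0:
                raise ValueError(f"allele index must be >= 0; got {allele}")

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass
class DepthTrack:
    """Dense per-base read depth for one sample on one reference."""

    sample_id: str
    species_id: str
    depths: np.ndarray  # shape (reference_length,), non-negative ints

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be a 1-D array")
        if len(self.depths) and self.depths.min() < 0:
            raise ValueError("negative depth encountered")


@dataclass(frozen=True)
class SampleQc:
    """Sample-level coverage QC verdict for one sample x species."""

    sample_id: str
    species_id: str
    breadth: float
    mean_depth: float
    passed: bool


@dataclass
class WindowMask:
    """Per-sample usability of fixed-size windows over one reference.

    ``usable[sample_id]`` is a boolean vector of length
    ``ceil(reference_length / window_size)``.
    """

    species_id: str
    window_size: int
    reference_length: int
    usable: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return n_windows(self.reference_length, self.window_size)


def n_windows(reference_length: int, window_size: int) -> int:
    """Number of fixed-size windows tiling a reference (terminal window may
    be partial); a window larger than the reference yields one window."""
    return max(1, math.ceil(reference_length / window_size))


def pair_key(sample_a: str, sample_b: str) -> Tuple[str, str]:
    """Canonical (lexicographic) ordering for an unordered sample pair."""
    return (sample_a, sample_b) if sample_a <= sample_b else (sample_b, sample_a)


@dataclass
class WssScore:
    """Genome-wide window-based SNV similarity for one sample pair.

    ``wss`` lies in [0, 100] and is only meaningful when ``valid``; an
    invalid score (QC failure or too few usable windows) carries
    ``wss = nan``.  The pair is unordered: sample_a <= sample_b.
    """

    species_id: str
    sample_a: str
    sample_b: str
    wss: float
    n_windows_used: int
    n_windows_total: int
    valid: bool

    def __post_init__(self) -> None:
        self.sample_a, self.sample_b = pair_key(self.sample_a, self.sample_b)
        if self.valid and not (0.0 <= self.wss <= 100.0):
            raise ValueError(f"wss out of [0, 100]: {self.wss}")


@dataclass(frozen=True)
class RelatednessCall:
    """A cutoff-based relatedness verdict: related iff wss > cutoff (strict)."""

    score: WssScore
    cutoff: float
    related: bool


CutoffTable = Dict[str, float]
"""Mapping species_id -> WSS relatedness cutoff (percent)."""


@dataclass
class LabeledScoreSet:
    """WSS scores with known related/unrelated labels, for cutoff calibration."""

    species_id: str
    related_scores: List[float]
    unrelated_scores: List[float]


class Pattern(str, enum.Enum):
    """Longitudinal strain-stability classes for a subject x species."""

    STABLE = "STABLE"
    NO_DOMINANT = "NO_DOMINANT"
    REPLACEMENT = "REPLACEMENT"
    TRANSIENT = "TRANSIENT"


@dataclass(frozen=True)
class StabilityPattern:
    subject_id: str
    species_id: str
    pattern: Pattern


ANCHOR_GROUP = "ANCHOR_GROUP"
ORPHAN = "ORPHAN"
NO_SCORE = "NO_SCORE"


@dataclass
class SubjectTimeline:
    """Chronology of one subject x species: anchor-relatedness mosaic and,
    once grouped, the strain-group coloring of every sample.

    ``anchor_calls[sample_id]`` is True/False (related/unrelated to the
    anchor) or None when no valid score exists for that pair.  Group labels
    are one of ANCHOR_GROUP, "GROUP_<k>", ORPHAN, NO_SCORE.
    """

    subject_id: str
    species_id: str
    samples: List[Tuple[str, float]]  # (sample_id, collection_month), chronological
    anchor: str
    anchor_calls: Dict[str, Optional[bool]]
    group_labels: Optional[Dict[str, str]] = None

    @property
    def sample_ids(self) -> List[str]:
        return [s for s, _ in self.samples]

    def months(self) -> Mapping[str, float]:
        return dict(self.samples)
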