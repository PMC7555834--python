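"""Coverage-based exclusion rules applied before any similarity is computed.

Two levels of filtering:

* sample level — a sample is excluded from all pairwise comparisons for a
  species when its breadth of coverage is below 30% or its mean read depth
  is below 3.5 (both strict);
* window level — a fixed-size genome window is ignored for a sample when
  more than 50% of its bases have read depth below 5 (strict "more than").

"Breadth" is the fraction of reference bases covered by at least one read;
"mean depth" averages over the full reference, zeros included, with a
switch to average over covered bases only.
"""
from __future__ import annotations

from typing import Dict, Iterable, Mapping

import numpy as np

from .datatypes import DepthTrack, SampleQc, SpeciesRef, WindowMask, n_windows

__all__ = [
    "BREADTH_MIN",
    "DEPTH_MIN",
    "WINDOW_LOW_DEPTH",
    "WINDOW_LOW_FRAC",
    "DEFAULT_WINDOW_SIZE",
    "sample_qc",
    "window_mask",
    "build_window_mask",
]

BREADTH_MIN = 0.30
DEPTH_MIN = 3.5
WINDOW_LOW_DEPTH = 5
WINDOW_LOW_FRAC = 0.5
DEFAULT_WINDOW_SIZE = 1000


def sample_qc(
    track: DepthTrack,
    species: SpeciesRef,
    breadth_min: float = BREADTH_MIN,
    depth_min: float = DEPTH_MIN,
    covered_only_depth: bool = False,
) -> SampleQc:
    """Evaluate sample-level coverage QC for one sample on one reference.

    A sample passes iff breadth >= ``breadth_min`` and mean depth >=
    ``depth_min``.  ``covered_only_depth`` averages depth over covered bases
    instead of the whole reference.
    """
    if len(track.depths) != species.reference_length:
        raise ValueError(
            f"depth track length {len(track.depths)} != reference length "
            f"{species.reference_length} for {species.species_id}"
        )
    covered = int(np.count_nonzero(track.depths >= 1))
    breadth = covered / species.reference_length
    if covered_only_depth:
        mean_depth = float(track.depths[track.depths >= 1].mean()) if covered else 0.0
    else:
        mean_depth = float(track.depths.mean())
    passed = breadth >= breadth_min and mean_depth >= depth_min
    return SampleQc(
        sample_id=track.sample_id,
        species_id=species.species_id,
        breadth=breadth,
        mean_depth=mean_depth,
        passed=passed,
    )


def window_mask(
    track: DepthTrack,
    species: SpeciesRef,
    window_size: int = DEFAULT_WINDOW_SIZE,
    low_depth: int = WINDOW_LOW_DEPTH,
    low_frac: float = WINDOW_LOW_FRAC,
) -> np.ndarray:
    """Per-window usability vector for one sample.

    Window ``w`` is usable iff the fraction of its bases with depth <
    ``low_depth`` is <= ``low_frac`` ("more than 50% low" is excluded,
    strictly).  The terminal partial window is evaluated over its actual
    bases; a window size exceeding the reference yields one whole-reference
    window.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    L = species.reference_length
    if len(track.depths) != L:
        raise ValueError("depth track length does not match reference length")
    nw = n_windows(L, window_size)
    low = track.depths < low_depth
    usable = np.empty(nw, dtype=bool)
    for w in range(nw):
        start = w * window_size
        end = min(start + window_size, L)
        frac_low = low[start:end].mean() if end > start else 1.0
        usable[w] = frac_low <= low_frac
    return usable


def build_window_mask(
    tracks: Iterable[DepthTrack],
    species: SpeciesRef,
    window_size: int = DEFAULT_WINDOW_SIZE,
    low_depth: int = WINDOW_LOW_DEPTH,
    low_frac: float = WINDOW_LOW_FRAC,
) -> WindowMask:
    """Assemble the per-sample window usability mask for a set of samples."""
    mask = WindowMask(
        species_id=species.species_id,
        window_size=window_size,
        reference_length=species.reference_length,
    )
    for track in tracks:
        mask.usable[track.sample_id] = window_mask(
            track, species, window_size=window_size, low_depth=low_depth, low_frac=low_frac
        )
    return mask
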