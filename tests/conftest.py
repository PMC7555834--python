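import math

import numpy as np
import pytest

from wsstrack.datatypes import DepthTrack, SampleQc, SpeciesRef, StrainProfile
from wsstrack.qc_filters import build_window_mask


@pytest.fixture
def species():
    return SpeciesRef(species_id="sp1", reference_length=4000, cutoff=87.5)


def make_profile(sample_id, calls, species_id="sp1"):
    return StrainProfile(sample_id=sample_id, species_id=species_id, calls=dict(calls))


def make_track(sample_id, depths, species_id="sp1"):
    return DepthTrack(sample_id=sample_id, species_id=species_id, depths=np.asarray(depths))


def uniform_track(sample_id, length, depth, species_id="sp1"):
    return make_track(sample_id, np.full(length, depth), species_id=species_id)


def passing_qc(sample_id, species_id="sp1"):
    return SampleQc(sample_id=sample_id, species_id=species_id, breadth=1.0, mean_depth=20.0, passed=True)


def full_mask(species, sample_ids, window_size=1000):
    """Window mask with every window usable (uniform depth 20)."""
    tracks = [uniform_track(s, species.reference_length, 20, species.species_id) for s in sample_ids]
    return build_window_mask(tracks, species, window_size=window_size)


def brute_force_groups(nodes, edges):
    """Transitive closure by repeated merging; independent of networkx."""
    groups = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                groups.remove(gb)
                ga |= gb
                changed = True
    return {frozenset(g) for g in groups}


def grouped_timeline(months, anchor_related, other_edges, subject="subj1"):
    """Build a grouped SubjectTimeline from explicit relatedness structure.

    The anchor is the sample at max(months); ``other_edges`` are the
    related pairs among non-anchor samples, every other non-anchor pair
    gets an explicit unrelated call.  Returns (timeline, calls).
    """
    import itertools

    from wsstrack.datatypes import RelatednessCall, SampleMeta, WssScore
    from wsstrack.timeline import build_anchor_mosaic, group_strains

    def call(a, b, related):
        score = WssScore(species_id="sp1", sample_a=a, sample_b=b,
                         wss=95.0 if related else 10.0,
                         n_windows_used=5, n_windows_total=5, valid=True)
        return RelatednessCall(score=score, cutoff=87.5, related=related)

    meta = [SampleMeta(sample_id=f"m{m:g}", subject_id=subject, collection_month=float(m))
            for m in months]
    anchor = f"m{max(months):g}"
    calls = []
    for m in months:
        s = f"m{m:g}"
        if s != anchor:
            calls.append(call(s, anchor, s in anchor_related))
    pairs_present = {frozenset((a, b)) for a, b in other_edges}
    for a, b in other_edges:
        calls.append(call(a, b, True))
    non_anchor = [f"m{m:g}" for m in months if f"m{m:g}" != anchor]
    for a, b in itertools.combinations(non_anchor, 2):
        if frozenset((a, b)) not in pairs_present:
            calls.append(call(a, b, False))
    tl = build_anchor_mosaic(calls, meta, subject, "sp1")
    return group_strains(calls, tl), calls


def naive_wss(calls_a, calls_b, depths_a, depths_b, ref_len, window_size,
              low_depth=5, low_frac=0.5):
    """Independent brute-force recomputation of the genome-wide WSS.

    Single position-by-position loop over the whole reference, no shared
    code with the implementation.  Returns None when no window contributes.
    """
    n_win = max(1, math.ceil(ref_len / window_size))
    sims = []
    for w in range(n_win):
        lo = w * window_size + 1
        hi = min((w + 1) * window_size, ref_len)
        n_bases = hi - lo + 1
        low_a = low_b = 0
        shared = matched = 0
        for p in range(lo, hi + 1):
            if depths_a[p - 1] < low_depth:
                low_a += 1
            if depths_b[p - 1] < low_depth:
                low_b += 1
            if p in calls_a and p in calls_b:
                shared += 1
                if calls_a[p] == calls_b[p]:
                    matched += 1
        if low_a / n_bases > low_frac or low_b / n_bases > low_frac:
            continue
        if shared:
            sims.append(matched / shared)
    if not sims:
        return None
    return 100.0 * sum(sims) / len(sims)
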