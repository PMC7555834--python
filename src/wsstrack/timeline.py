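"""Per-subject, per-species longitudinal strain reconstruction.

From the pairwise relatedness calls of one subject's samples on one
species, three successive views are built:

1. the *anchor mosaic* — each earlier sample called related/unrelated to
   the anchor (the last sample with valid scores; a green/purple row);
2. the *stability pattern* — STABLE (dominant strain throughout),
   NO_DOMINANT (no sample shares the anchor strain), REPLACEMENT (an early
   strain displaced by the strain that then persists to the anchor), or
   TRANSIENT (the dominant strain interrupted and later recovered);
3. the *strain groups* — anchor-related samples form the anchor group;
   the remaining samples are partitioned by connected components of the
   relatedness graph (mutually related samples share a color), singletons
   are orphans, unscorable samples carry no label but NO_SCORE.

Relatedness observed in real data is not transitive, so grouping uses
connected components rather than cliques; a strict-clique variant is
available via ``require_clique``.
"""
from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .datatypes import (
    ANCHOR_GROUP,
    NO_SCORE,
    ORPHAN,
    Pattern,
    RelatednessCall,
    SampleMeta,
    StabilityPattern,
    SubjectTimeline,
    pair_key,
)

__all__ = [
    "TimelineSkip",
    "build_anchor_mosaic",
    "classify_pattern",
    "group_strains",
    "build_timelines",
]


class TimelineSkip(Exception):
    """A subject x species cannot be reconstructed (too few scorable
    samples); carries the logged reason."""


def _call_map(calls: Iterable[RelatednessCall]) -> Dict[Tuple[str, str], bool]:
    cmap: Dict[Tuple[str, str], bool] = {}
    for c in calls:
        cmap[pair_key(c.score.sample_a, c.score.sample_b)] = c.related
    return cmap


def build_anchor_mosaic(
    calls: Sequence[RelatednessCall],
    meta: Sequence[SampleMeta],
    subject_id: str,
    species_id: str,
) -> SubjectTimeline:
    """Build the anchor-relatedness mosaic for one subject x species.

    The anchor is the chronologically last sample participating in any
    valid relatedness call (a last sample failing QC therefore falls back
    to the latest scorable one).  ``anchor_calls`` holds True/False per
    earlier sample, or None when the pair has no valid score.
    """
    calls = [c for c in calls if c.score.species_id == species_id]
    subject_meta = sorted(
        (m for m in meta if m.subject_id == subject_id),
        key=lambda m: (m.collection_month, m.sample_id),
    )
    if not subject_meta:
        raise TimelineSkip(f"subject {subject_id!r}: no samples in metadata")
    sample_order = [(m.sample_id, m.collection_month) for m in subject_meta]
    known = {s for s, _ in sample_order}
    cmap = _call_map(calls)
    scorable = {s for pair in cmap for s in pair if s in known}
    if len(scorable) < 2:
        raise TimelineSkip(
            f"subject {subject_id!r} x {species_id!r}: fewer than 2 scorable samples"
        )
    anchor = max(scorable, key=lambda s: dict(sample_order)[s])
    anchor_calls: Dict[str, Optional[bool]] = {}
    for s, _ in sample_order:
        if s == anchor:
            continue
        anchor_calls[s] = cmap.get(pair_key(s, anchor))
    if not any(v is not None for v in anchor_calls.values()):
        raise TimelineSkip(
            f"subject {subject_id!r} x {species_id!r}: no valid anchor comparisons"
        )
    return SubjectTimeline(
        subject_id=subject_id,
        species_id=species_id,
        samples=sample_order,
        anchor=anchor,
        anchor_calls=anchor_calls,
    )


def classify_pattern(tl: SubjectTimeline) -> StabilityPattern:
    """Classify the subject x species stability pattern from the mosaic.

    Operates on the chronologically ordered *present* calls (missing
    entries are skipped, so inserting unscorable timepoints never changes
    the class).  The anchor relates to itself, so it acts as an implicit
    final related call: a mixed sequence where some related call precedes a
    later unrelated one is TRANSIENT (interruption then recovery at the
    anchor); the only other mixed shape — unrelated prefix then related to
    the end — is REPLACEMENT.
    """
    months = tl.months()
    seq = [
        tl.anchor_calls[s]
        for s, _ in sorted(tl.samples, key=lambda x: (x[1], x[0]))
        if s != tl.anchor and tl.anchor_calls.get(s) is not None
    ]
    if len(seq) < 2:
        raise ValueError(
            f"pattern undecidable with {len(seq)} anchor call(s) for "
            f"{tl.subject_id!r} x {tl.species_id!r}"
        )
    if all(seq):
        pattern = Pattern.STABLE
    elif not any(seq):
        pattern = Pattern.NO_DOMINANT
    else:
        # mixed: related call followed (in time) by an unrelated call means
        # the dominant strain was interrupted and recovered by the anchor
        first_true = seq.index(True)
        interrupted = any(not v for v in seq[first_true + 1 :])
        pattern = Pattern.TRANSIENT if interrupted else Pattern.REPLACEMENT
    return StabilityPattern(tl.subject_id, tl.species_id, pattern)


def group_strains(
    calls: Sequence[RelatednessCall],
    tl: SubjectTimeline,
    require_clique: bool = False,
) -> SubjectTimeline:
    """Fill ``tl.group_labels``: the strain-group coloring of every sample.

    Samples related to the anchor (plus the anchor itself) get
    ANCHOR_GROUP.  The rest are partitioned by connected components of the
    relatedness graph restricted to non-anchor-related scorable samples;
    components of size >= 2 become GROUP_1..k numbered by their earliest
    member's collection month, singletons become ORPHAN, and samples
    without any valid score get NO_SCORE.  With ``require_clique`` a
    component must be mutually related throughout or it dissolves into
    orphans.
    """
    cmap = _call_map(c for c in calls if c.score.species_id == tl.species_id)
    months = tl.months()
    known = set(months)
    scorable = {s for pair in cmap for s in pair if s in known}

    labels: Dict[str, str] = {}
    anchor_set = {tl.anchor}
    for s in scorable:
        if s != tl.anchor and cmap.get(pair_key(s, tl.anchor)):
            anchor_set.add(s)
    for s in anchor_set:
        labels[s] = ANCHOR_GROUP

    rest = sorted(scorable - anchor_set)
    g = nx.Graph()
    g.add_nodes_from(rest)
    for sa, sb in itertools.combinations(rest, 2):
        if cmap.get(pair_key(sa, sb)):
            g.add_edge(sa, sb)

    components = [sorted(c) for c in nx.connected_components(g)]
    if require_clique:
        kept = []
        for comp in components:
            if len(comp) >= 2 and not all(
                cmap.get(pair_key(a, b)) for a, b in itertools.combinations(comp, 2)
            ):
                kept.extend([x] for x in comp)
            else:
                kept.append(comp)
        components = kept
    multi = sorted(
        (c for c in components if len(c) >= 2),
        key=lambda c: min((months[s], s) for s in c),
    )
    for k, comp in enumerate(multi, start=1):
        for s in comp:
            labels[s] = f"GROUP_{k}"
    for comp in components:
        if len(comp) == 1:
            labels[comp[0]] = ORPHAN
    for s in known - scorable:
        labels[s] = NO_SCORE

    tl.group_labels = labels
    return tl


def build_timelines(
    calls: Sequence[RelatednessCall],
    meta: Sequence[SampleMeta],
) -> Tuple[List[SubjectTimeline], List[StabilityPattern], List[str]]:
    """Run the full reconstruction for every subject x species present in
    the calls; returns (timelines-with-groups, patterns, skip reasons)."""
    by_sample = {m.sample_id: m for m in meta}
    combos = sorted(
        {
            (by_sample[s].subject_id, c.score.species_id)
            for c in calls
            for s in (c.score.sample_a, c.score.sample_b)
            if s in by_sample
        }
    )
    timelines: List[SubjectTimeline] = []
    patterns: List[StabilityPattern] = []
    skipped: List[str] = []
    for subject_id, species_id in combos:
        subject_samples = {m.sample_id for m in meta if m.subject_id == subject_id}
        subject_calls = [
            c
            for c in calls
            if c.score.species_id == species_id
            and c.score.sample_a in subject_samples
            and c.score.sample_b in subject_samples
        ]
        try:
            tl = build_anchor_mosaic(subject_calls, meta, subject_id, species_id)
        except TimelineSkip as exc:
            skipped.append(str(exc))
            continue
        group_strains(subject_calls, tl)
        timelines.append(tl)
        try:
            patterns.append(classify_pattern(tl))
        except ValueError as exc:
            skipped.append(str(exc))
    return timelines, patterns, skipped
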