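"""Synthetic longitudinal metagenomes with known strain dynamics.

Everything downstream of variant calling is exercised without any real
reads: the generator draws strain *templates* (SNV positions with
alternate bases on a virtual reference), resamples them per timepoint with
a small per-call flip probability (consensus-calling noise), assembles the
joint genotype matrix a multi-sample caller would emit, and writes the
exact dialects :mod:`wsstrack.io_formats` reads — a multi-sample VCF,
per-sample depth TSVs, sample metadata and a truth table.

Four scenarios mirror the longitudinal dynamics seen in infant cohorts:

* STABLE       — one dominant strain at every timepoint;
* REPLACEMENT  — an early strain displaced partway by an independent
                 strain that persists through the final (anchor) sample;
* TRANSIENT    — the dominant strain interrupted by an internal run of an
                 independent strain, then recovered through the anchor;
* NO_DOMINANT  — an independent strain at every timepoint.

Coverage is a constant high depth with per-window dropout to depth 2
(below the read-depth-5 window filter), exercising the QC path.  All
output is bit-identical under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .datatypes import DepthTrack, SampleMeta, SpeciesRef, StrainProfile, n_windows

__all__ = [
    "BASES",
    "ScenarioSpec",
    "ScenarioData",
    "ReferenceBases",
    "generate_strain",
    "sample_from_strain",
    "simulate_scenario",
    "generate_scenario",
]

BASES = ("A", "C", "G", "T")

SCENARIOS = ("STABLE", "REPLACEMENT", "TRANSIENT", "NO_DOMINANT")


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one simulated subject x species series."""

    scenario: str
    n_timepoints: int = 5
    months: Optional[Tuple[float, ...]] = None  # default: 6-monthly from month 6
    reference_length: int = 10_000
    snv_density: float = 5.0  # SNVs per kb per strain
    within_strain_noise: float = 0.02  # per-call flip probability on resampling
    dropout: float = 0.1  # per-window low-coverage probability
    depth: int = 20
    dropout_depth: int = 2
    window_size: int = 1000
    species_id: str = "synth_species"
    subject_id: str = "subject1"
    antibiotic_exposed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 timepoints")
        for p in (self.within_strain_noise, self.dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.months is not None:
            if len(self.months) != self.n_timepoints:
                raise ValueError("months must match n_timepoints")
            if any(b <= a for a, b in zip(self.months, self.months[1:])):
                raise ValueError("months must be strictly increasing")

    def timepoints(self) -> Tuple[float, ...]:
        if self.months is not None:
            return self.months
        return tuple(6.0 * (i + 1) for i in range(self.n_timepoints))


class ReferenceBases:
    """Lazily drawn reference bases for a virtual reference sequence.

    Only positions touched by some strain ever materialize; draws are
    deterministic under the scenario RNG."""

    def __init__(self, length: int, rng: np.random.Generator) -> None:
        self.length = length
        self._rng = rng
        self._bases: Dict[int, str] = {}

    def __getitem__(self, pos: int) -> str:
        if pos not in self._bases:
            self._bases[pos] = BASES[self._rng.integers(4)]
        return self._bases[pos]


StrainTemplate = Dict[int, str]
"""A strain's SNV profile: 1-based position -> alternate base (!= ref)."""


def generate_strain(
    ref_len: int, snv_density: float, rng: np.random.Generator, ref: ReferenceBases
) -> StrainTemplate:
    """Draw a strain template: SNV positions uniform without replacement,
    alternate bases uniform over the three non-reference bases."""
    if snv_density < 0:
        raise ValueError("snv_density must be >= 0")
    n_snv = round(snv_density * ref_len / 1000.0)
    if n_snv > ref_len:
        raise ValueError(f"density implies {n_snv} SNVs on a {ref_len} bp reference")
    positions = rng.choice(ref_len, size=n_snv, replace=False) + 1  # 1-based
    template: StrainTemplate = {}
    for pos in sorted(int(p) for p in positions):
        alts = [b for b in BASES if b != ref[pos]]
        template[pos] = alts[rng.integers(3)]
    return template


def sample_from_strain(
    template: StrainTemplate, noise: float, rng: np.random.Generator
) -> StrainTemplate:
    """Resample a strain: each call independently flipped to one of the
    three other bases with probability ``noise`` (possibly back to the
    reference base, which then reads as a reference genotype)."""
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    out: StrainTemplate = {}
    for pos, base in template.items():
        if noise > 0 and rng.random() < noise:
            others = [b for b in BASES if b != base]
            out[pos] = others[rng.integers(3)]
        else:
            out[pos] = base
    return out


@dataclass
class ScenarioData:
    """In-memory realization of one scenario (what the files would hold)."""

    spec: ScenarioSpec
    species: SpeciesRef
    profiles: List[StrainProfile]
    tracks: List[DepthTrack]
    meta: List[SampleMeta]
    strain_of: Dict[str, str]  # sample_id -> generating strain id
    records: List[io_formats.VcfRecord] = field(default_factory=list)

    @property
    def sample_ids(self) -> List[str]:
        return [m.sample_id for m in self.meta]


def _strain_assignment(spec: ScenarioSpec, rng: np.random.Generator) -> List[str]:
    """Per-timepoint strain identity ('A', 'B', or per-timepoint S<i>)."""
    n = spec.n_timepoints
    if spec.scenario == "STABLE":
        return ["A"] * n
    if spec.scenario == "NO_DOMINANT":
        return [f"S{i}" for i in range(n)]
    if spec.scenario == "REPLACEMENT":
        # switch point strictly inside the series so both strains are seen
        switch = int(rng.integers(1, n - 1)) if n > 2 else 1
        return ["A"] * switch + ["B"] * (n - switch)
    # TRANSIENT: internal run of B, A recovered through the anchor
    start = int(rng.integers(1, n - 1))
    max_len = n - 1 - start
    run = int(rng.integers(1, max_len + 1))
    ids = ["A"] * n
    for i in range(start, start + run):
        ids[i] = "B"
    return ids


def simulate_scenario(spec: ScenarioSpec) -> ScenarioData:
    """Realize a scenario fully in memory (profiles, depth tracks,
    metadata, truth and the joint VCF records)."""
    rng = np.random.default_rng(spec.seed)
    ref = ReferenceBases(spec.reference_length, rng)
    assignment = _strain_assignment(spec, rng)
    templates: Dict[str, StrainTemplate] = {}
    for sid in assignment:
        if sid not in templates:
            templates[sid] = generate_strain(spec.reference_length, spec.snv_density, rng, ref)

    months = spec.timepoints()
    sample_ids = [f"{spec.subject_id}_t{i:02d}" for i in range(spec.n_timepoints)]
    observed: List[StrainTemplate] = [
        sample_from_strain(templates[assignment[i]], spec.within_strain_noise, rng)
        for i in range(spec.n_timepoints)
    ]

    # joint genotype matrix over the union of segregating sites
    all_pos = sorted({p for t in templates.values() for p in t} | {p for o in observed for p in o})
    records: List[io_formats.VcfRecord] = []
    calls: List[Dict[int, int]] = [{} for _ in sample_ids]
    for pos in all_pos:
        ref_base = ref[pos]
        bases = [o.get(pos, ref_base) for o in observed]
        alts: List[str] = []
        for b in bases:
            if b != ref_base and b not in alts:
                alts.append(b)
        if not alts:
            continue  # noise reverted every carrier to reference: monomorphic
        gts = [0 if b == ref_base else 1 + alts.index(b) for b in bases]
        records.append((pos, ref_base, tuple(alts), gts))
        for i, g in enumerate(gts):
            calls[i][pos] = g

    species = SpeciesRef(species_id=spec.species_id, reference_length=spec.reference_length)
    profiles = [
        StrainProfile(sample_id=s, species_id=spec.species_id, calls=calls[i])
        for i, s in enumerate(sample_ids)
    ]

    nw = n_windows(spec.reference_length, spec.window_size)
    tracks = []
    for s in sample_ids:
        depths = np.full(spec.reference_length, spec.depth, dtype=np.int64)
        for w in range(nw):
            if spec.dropout > 0 and rng.random() < spec.dropout:
                lo = w * spec.window_size
                hi = min(lo + spec.window_size, spec.reference_length)
                depths[lo:hi] = spec.dropout_depth
        tracks.append(DepthTrack(sample_id=s, species_id=spec.species_id, depths=depths))

    meta = [
        SampleMeta(
            sample_id=s,
            subject_id=spec.subject_id,
            collection_month=months[i],
            antibiotic_exposed=spec.antibiotic_exposed,
        )
        for i, s in enumerate(sample_ids)
    ]
    strain_of = {s: assignment[i] for i, s in enumerate(sample_ids)}
    return ScenarioData(
        spec=spec,
        species=species,
        profiles=profiles,
        tracks=tracks,
        meta=meta,
        strain_of=strain_of,
        records=records,
    )


def generate_scenario(spec: ScenarioSpec, out_dir: Path) -> ScenarioData:
    """Realize a scenario and write the full fixture directory:
    ``samples.vcf``, ``depth_<sample>.tsv``, ``metadata.tsv``,
    ``truth.tsv``.  Bit-identical for identical seeds."""
    data = simulate_scenario(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.write_multisample_vcf(
        out_dir / "samples.vcf", data.species, data.sample_ids, data.records
    )
    for track in data.tracks:
        io_formats.write_depth_track(track, out_dir / f"depth_{track.sample_id}.tsv")
    io_formats.write_metadata(data.meta, out_dir / "metadata.tsv")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("sample_id\tstrain_id\tscenario\n")
        for s in data.sample_ids:
            fh.write(f"{s}\t{data.strain_of[s]}\t{spec.scenario}\n")
    return data
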