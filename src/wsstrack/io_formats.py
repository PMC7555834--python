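"""Readers and writers for every external artifact of the pipeline.

Dialects
--------
* multi-sample VCF v4.x (one genotype column per sample; read via pysam)
* depth TSV: ``contig  pos(1-based)  depth``, samtools-depth style; absent
  positions mean depth 0
* cutoff TSV: ``species_id  cutoff``
* metadata TSV: ``sample_id  subject_id  collection_month
  antibiotic_exposed  delivery_mode``
* score matrix TSV (long format, deterministic row order)
* labeled score TSV: ``species_id  label  wss`` with label in
  {related, unrelated}

All files may carry ``#``-prefixed comment header lines (run configuration
is embedded there by the CLI); readers skip them.  No scientific logic
lives here.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .datatypes import (
    CutoffTable,
    DepthTrack,
    LabeledScoreSet,
    SampleMeta,
    SpeciesRef,
    StrainProfile,
    WssScore,
)

__all__ = [
    "InputError",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "species_from_vcf",
    "read_depth_track",
    "write_depth_track",
    "read_cutoff_table",
    "write_cutoff_table",
    "read_metadata",
    "write_metadata",
    "read_score_matrix",
    "write_score_matrix",
    "read_labeled_scores",
    "write_labeled_scores",
]

PathLike = Union[str, Path]


class InputError(ValueError):
    """Raised when an input file violates its dialect contract."""


# ---------------------------------------------------------------------------
# VCF


def _resolve_genotype(gt: Tuple[Optional[int], ...], ad: Optional[Sequence[int]]) -> Optional[int]:
    """Collapse a (possibly diploid) GT tuple to a single consensus allele.

    Missing (all None) -> None.  Homozygous -> that allele.  Heterozygous
    calls are resolved by majority allele depth when AD is present,
    otherwise by the first allele; ties go to the first allele.
    """
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    first = alleles[0]
    if all(a == first for a in alleles):
        return first
    if ad is not None:
        best = first
        best_depth = -1
        for a in alleles:
            if a < len(ad) and ad[a] is not None and ad[a] > best_depth:
                best, best_depth = a, ad[a]
        return best
    return first


def read_multisample_vcf(
    path: PathLike,
    species: SpeciesRef,
    include_indels: bool = False,
) -> List[StrainProfile]:
    """Read a multi-sample VCF into one :class:`StrainProfile` per sample.

    Positions are 1-based as in the VCF.  ``./.`` genotypes are recorded as
    no-call (position absent from that sample's map).  Multiallelic records
    are kept as the called allele index.  Non-SNV records are skipped unless
    ``include_indels`` is set.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise InputError(f"malformed VCF {path!r}: {exc}") from exc
    samples = list(vf.header.samples)
    calls: Dict[str, Dict[int, int]] = {s: {} for s in samples}
    try:
        for rec in vf:
            if rec.chrom != species.species_id:
                raise InputError(
                    f"{path}: contig {rec.chrom!r} at position {rec.pos} does not "
                    f"match species {species.species_id!r}"
                )
            if rec.pos < 1 or rec.pos > species.reference_length:
                raise InputError(
                    f"{path}: position {rec.pos} outside reference "
                    f"[1, {species.reference_length}]"
                )
            if not include_indels:
                alts = rec.alts or ()
                if len(rec.ref) != 1 or any(len(a) != 1 or not a.isalpha() for a in alts):
                    continue
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT", (None,))
                ad = sample.get("AD", None)
                allele = _resolve_genotype(tuple(gt), ad)
                if allele is not None:
                    calls[s][rec.pos] = allele
    except InputError:
        raise
    except Exception as exc:  # pysam parse failure mid-file
        raise InputError(f"malformed VCF {path!r}: {exc}") from exc
    finally:
        vf.close()
    return [StrainProfile(sample_id=s, species_id=species.species_id, calls=calls[s]) for s in samples]


VcfRecord = Tuple[int, str, Tuple[str, ...], Sequence[Optional[int]]]
"""(pos_1based, ref_base, alt_bases, per-sample allele index or None)."""


def write_multisample_vcf(
    path: PathLike,
    species: SpeciesRef,
    sample_ids: Sequence[str],
    records: Iterable[VcfRecord],
    header_comments: Sequence[str] = (),
) -> None:
    """Write a minimal deterministic multi-sample VCF v4.2.

    Genotypes are emitted diploid-homozygous (``1/1``) in the GATK
    consensus style; missing calls as ``./.``.
    """
    lines = ["##fileformat=VCFv4.2"]
    for c in header_comments:
        lines.append(f"##wsstrack_{c}")
    lines.append(
        f"##contig=<ID={species.species_id},length={species.reference_length}>"
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for pos, ref, alts, gts in sorted(records, key=lambda r: r[0]):
        gt_fields = ["./." if g is None else f"{g}/{g}" for g in gts]
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{species.species_id}\t{pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
            + "\t".join(gt_fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def species_from_vcf(path: PathLike, cutoff: Optional[float] = None) -> SpeciesRef:
    """Recover the (single) contig id and length from a VCF header."""
    with pysam.VariantFile(str(path)) as vf:
        contigs = list(vf.header.contigs.values())
    if len(contigs) != 1:
        raise InputError(
            f"{path}: expected exactly one contig in header, found {len(contigs)}"
        )
    c = contigs[0]
    return SpeciesRef(species_id=c.name, reference_length=c.length, cutoff=cutoff)


# ---------------------------------------------------------------------------
# depth tracks


def read_depth_track(path: PathLike, species: SpeciesRef, sample_id: str = "") -> DepthTrack:
    """Read a samtools-depth-style TSV into a dense depth array.

    Rows are ``contig  pos(1-based)  depth``; unlisted positions get depth 0.
    """
    depths = np.zeros(species.reference_length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            contig, pos_s, depth_s = parts
            if contig != species.species_id:
                raise InputError(
                    f"{path}:{lineno}: contig {contig!r} != species {species.species_id!r}"
                )
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if pos < 1 or pos > species.reference_length:
                raise InputError(
                    f"{path}:{lineno}: position {pos} outside [1, {species.reference_length}]"
                )
            if depth < 0:
                raise InputError(f"{path}:{lineno}: negative depth {depth}")
            depths[pos - 1] = depth
    return DepthTrack(sample_id=sample_id, species_id=species.species_id, depths=depths)


def write_depth_track(track: DepthTrack, path: PathLike, include_zeros: bool = False) -> None:
    """Write a depth track as samtools-depth-style TSV (zero rows omitted
    by default, matching the sparse-file convention)."""
    with open(path, "w") as fh:
        for i, d in enumerate(track.depths):
            if d or include_zeros:
                fh.write(f"{track.species_id}\t{i + 1}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# cutoff tables


def read_cutoff_table(path: PathLike) -> CutoffTable:
    """Read a 2-column ``species_id  cutoff`` TSV into a mapping."""
    table: CutoffTable = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            species, cutoff_s = parts
            if first_data_line and species == "species_id":
                first_data_line = False
                continue  # optional header row
            first_data_line = False
            try:
                cutoff = float(cutoff_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-numeric cutoff: {cutoff_s!r}") from exc
            if not (0.0 <= cutoff <= 100.0) or math.isnan(cutoff):
                raise InputError(f"{path}:{lineno}: cutoff {cutoff} outside [0, 100]")
            if species in table:
                raise InputError(f"{path}:{lineno}: duplicate species {species!r}")
            table[species] = cutoff
    return table


def write_cutoff_table(table: CutoffTable, path: PathLike, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("species_id\tcutoff\n")
        for species in sorted(table):
            fh.write(f"{species}\t{table[species]:.10g}\n")


# ---------------------------------------------------------------------------
# sample metadata


_META_COLS = ["sample_id", "subject_id", "collection_month", "antibiotic_exposed", "delivery_mode"]


def read_metadata(path: PathLike) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise InputError(f"{path}: duplicate sample_id {dup!r}")
    metas = []
    for row in df.itertuples(index=False):
        exposed = row.antibiotic_exposed
        if isinstance(exposed, str):
            exposed = exposed.strip().lower() in ("1", "true", "yes")
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                collection_month=float(row.collection_month),
                antibiotic_exposed=bool(exposed),
                delivery_mode=str(row.delivery_mode),
            )
        )
    return metas


def write_metadata(metas: Sequence[SampleMeta], path: PathLike, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_META_COLS) + "\n")
        for m in metas:
            fh.write(
                f"{m.sample_id}\t{m.subject_id}\t{m.collection_month:.10g}\t"
                f"{str(m.antibiotic_exposed).lower()}\t{m.delivery_mode}\n"
            )


# ---------------------------------------------------------------------------
# score matrices


_SCORE_COLS = [
    "species",
    "sample_a",
    "sample_b",
    "wss",
    "n_windows_used",
    "n_windows_total",
    "qc_pass",
]


def write_score_matrix(scores: Iterable[WssScore], path: PathLike, header_comments: Sequence[str] = ()) -> None:
    """Write WSS scores as long-format TSV, ordered by (species, sample_a,
    sample_b); invalid scores carry ``NA`` in the wss column."""
    rows = sorted(scores, key=lambda s: (s.species_id, s.sample_a, s.sample_b))
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_SCORE_COLS) + "\n")
        for s in rows:
            wss = "NA" if not s.valid else f"{s.wss:.10g}"
            fh.write(
                f"{s.species_id}\t{s.sample_a}\t{s.sample_b}\t{wss}\t"
                f"{s.n_windows_used}\t{s.n_windows_total}\t{str(s.valid).lower()}\n"
            )


def read_score_matrix(path: PathLike) -> List[WssScore]:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"sample_a": str, "sample_b": str, "species": str},
        na_values=["NA"],
    )
    missing = [c for c in _SCORE_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing score columns {missing}")
    scores = []
    for row in df.itertuples(index=False):
        valid = bool(row.qc_pass) if not isinstance(row.qc_pass, str) else row.qc_pass.lower() == "true"
        scores.append(
            WssScore(
                species_id=row.species,
                sample_a=row.sample_a,
                sample_b=row.sample_b,
                wss=float(row.wss) if valid and not pd.isna(row.wss) else float("nan"),
                n_windows_used=int(row.n_windows_used),
                n_windows_total=int(row.n_windows_total),
                valid=valid,
            )
        )
    return scores


# ---------------------------------------------------------------------------
# labeled scores (calibration input)


def read_labeled_scores(path: PathLike) -> Dict[str, LabeledScoreSet]:
    """Read ``species_id  label  wss`` rows into per-species labeled sets."""
    sets: Dict[str, LabeledScoreSet] = {}
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species_id": str, "label": str})
    for col in ("species_id", "label", "wss"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    for row in df.itertuples(index=False):
        ls = sets.setdefault(row.species_id, LabeledScoreSet(row.species_id, [], []))
        if row.label == "related":
            ls.related_scores.append(float(row.wss))
        elif row.label == "unrelated":
            ls.unrelated_scores.append(float(row.wss))
        else:
            raise InputError(f"{path}: label must be related/unrelated, got {row.label!r}")
    return sets


def write_labeled_scores(sets: Iterable[LabeledScoreSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tlabel\twss\n")
        for ls in sets:
            for w in ls.related_scores:
                fh.write(f"{ls.species_id}\trelated\t{w:.10g}\n")
            for w in ls.unrelated_scores:
                fh.write(f"{ls.species_id}\tunrelated\t{w:.10g}\n")
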