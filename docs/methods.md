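# Methods

## The similarity model

`wsstrack` treats each metagenomic sample mapped to one species reference
as a haploid-style consensus genotype: at every variant record of the
joint multi-sample VCF, a sample carries one allele index (0 = reference,
≥ 1 = alternate) or no call (`./.`). Diploid-style genotypes are collapsed
deterministically — homozygous calls keep their allele, heterozygous calls
resolve by majority allele depth when the `AD` field is present and by the
first allele otherwise. Indel records are skipped by default
(`include_indels=True` keeps them); the score is designed for SNVs.

The window-based SNV similarity between samples *i* and *j* tiles the
reference with fixed windows and averages per-window concordance:

* the position set *P_w* of a window is every position genotyped in
  **both** samples. Because a joint caller genotypes all samples at every
  record, a sample without the variant normally appears with allele 0 and
  counts as a (mis)match; a `./.` no-call removes the position from that
  pair only. This is the central missing-data rule: *missing ≠ reference*.
* windows unusable in either sample (coverage masking, below) or with
  empty *P_w* are skipped; the rest contribute equally to the mean
  (`weight_by_positions=True` switches to weighting each window by
  |*P_w*|, which estimates the pooled per-position concordance instead).
* the score is reported on a 0–100 scale; cutoff comparisons always use
  full precision.

The per-window formula and the window length are interpretations — the
approach descends from an earlier strain-tracking method whose exact
constants are not restated here — so both are first-class parameters
(`window_size`, default 1000 bp) and are recorded in every output header.

Properties guaranteed by construction and enforced by tests: symmetry,
0 ≤ WSS ≤ 100, WSS = 100 for identical call sets at full coverage, and
monotonicity (turning a mismatching position into a match never lowers
the score).

An important consequence of the joint-genotyping convention is that the
score between two *unrelated* strains depends on cohort composition: in a
cohort containing further strains, positions variant only in those other
samples are reference-genotyped in both members of the pair and count as
matches. In a five-strain cohort an unrelated pair scores near 60 rather
than near 0. Cutoffs must therefore be calibrated on pairs scored in
comparable joint contexts, which is what `pipeline.generate_labeled_scores`
does (below).

## Coverage filtering

Two rules, both strict inequalities, run before any scoring:

* **sample level** — exclude a sample from all comparisons for a species
  when breadth (fraction of reference bases with depth ≥ 1) is < 0.30 or
  mean depth is < 3.5. Mean depth averages over the full reference with
  zeros included; `covered_only_depth=True` averages over covered bases
  only, for pipelines that define depth that way.
* **window level** — ignore a window for a sample when *more than* 50% of
  its bases have depth < 5; exactly 50% is retained. The terminal partial
  window is judged over its actual bases. A pair uses a window only when
  it is usable in both samples, keeping the score symmetric.

A score is `valid` only when both samples pass sample QC and at least
`min_windows` (default 1) windows contribute; `n_windows_used` is always
reported so stricter validity can be imposed post hoc.

## Relatedness and cutoff calibration

A valid pair is related iff WSS > cutoff, strictly; a score exactly at the
cutoff is unrelated. Species without a cutoff are excluded from calling
(with a logged warning), never defaulted. Supplied cutoff tables are never
overwritten by calibration.

`calibration.calibrate_cutoff` derives a cutoff from labeled pairs
(related = same-strain, unrelated = different-strain). `midpoint` places
the threshold halfway between the lowest related and highest unrelated
score when the distributions separate; otherwise, and always under
`max_youden`, the observed score maximizing sensitivity + specificity − 1
is chosen, ties toward the larger threshold. Sensitivity/specificity use
the same strict `>` convention as calling. Both rules are stated as
interpretations in the output metadata; neither claims to reproduce any
previously published threshold table.

## Timeline reconstruction

Per subject × species, the **anchor** is the chronologically last sample
participating in any valid score — so a final sample lost to low coverage
falls back to the latest scorable one. The anchor mosaic records, per
earlier sample, related/unrelated to the anchor or *absent* when the pair
has no valid score (missing is never rendered as unrelated).

Pattern classification reads the present calls in time order. All related
→ `STABLE`; none related → `NO_DOMINANT`. For mixed sequences the anchor
acts as an implicit final related observation (it trivially shares its own
strain): if any related call precedes a later unrelated call the dominant
strain was interrupted and recovered — `TRANSIENT`; the only remaining
mixed shape, an unrelated prefix followed by related calls through the
anchor, is `REPLACEMENT`. This rule is total over all boolean sequences,
and inserting unscorable timepoints never changes the class. With fewer
than two present calls the series is reported as undecidable rather than
guessed.

Strain grouping colors each sample: anchor-related samples (plus the
anchor) form `ANCHOR_GROUP`; the remaining scorable samples are
partitioned by connected components of the relatedness graph restricted to
them — observed relatedness is not transitive, so components, not cliques,
match the "related samples share a color" reading; a strict-clique variant
(`require_clique=True`) dissolves non-clique components into orphans.
Components of size ≥ 2 are numbered `GROUP_k` by their earliest member's
collection month; singletons are `ORPHAN`; samples with no valid score are
`NO_SCORE`. The labels partition the sample set.

## Group statistics

Pattern frequencies are compared between exposure groups (antibiotics vs
none) by one-way ANOVA followed by Tukey's HSD (`scipy.stats.f_oneway`,
`statsmodels` `pairwise_tukeyhsd`). The response is a per-subject binary
indicator of pattern presence — the default `subject` unit avoids
pseudo-replication when one subject contributes several species; the
`species` unit (one indicator per subject × species occurrence) is the
config alternative, since the choice of unit is genuinely open. When every
group has zero within-group variance the F statistic is undefined and the
result is flagged degenerate instead of carrying a p-value. For two groups
the ANOVA is identical to the equal-variance t-test (F = t²), which the
tests verify to 1e-10.

## The synthetic generator

`synthetic_data` emulates what a joint variant caller would emit for one
subject's longitudinal series, without simulating reads:

* a **strain template** is a set of SNV positions (uniform without
  replacement; default 5 SNVs/kb on a 10 kb reference) with alternate
  bases uniform over the three non-reference bases;
* a **sample** resamples its timepoint's template, flipping each call to
  another base with probability `within_strain_noise` (default 0.02,
  emulating consensus-calling error; a flip may restore the reference
  base and then reads as genotype 0);
* the four scenarios assign templates to the default five 6-monthly
  timepoints: `STABLE` (one template), `REPLACEMENT` (template A then an
  independent B from a random internal switch point through the anchor),
  `TRANSIENT` (A, an internal run of B, recovery to A including the
  anchor), `NO_DOMINANT` (an independent template per timepoint);
* coverage is uniform depth 20 with per-window dropout (default
  probability 0.1) to depth 2 — below the window filter's depth-5 bound —
  so masking is exercised while sample-level QC still passes;
* emitted artifacts are exactly the dialects the readers accept
  (multi-sample VCF with contig header, samtools-depth TSVs, metadata and
  truth tables), byte-identical under a fixed seed.

What the generator does **not** model: read-level error and alignment
artifacts, within-sample strain mixtures, abundance variation between
species, uneven (non-window) coverage structure, and real cutoff tables.
Passing tests therefore demonstrate the correctness of scoring, filtering,
calibration and reconstruction logic on idealized consensus calls — not
performance on real metagenomes, where reference bias and mixed strains
blur the score distributions.

## Simulation studies and sizes

Cutoff calibration and the scenario-recovery study run on the generator's
default conditions (10 kb reference, 5 SNVs/kb, 5 timepoints, noise 0.02,
dropout 0.1, 1 kb windows). Labeled score sets cycle replicates through
all four scenarios and label pairs by true strain identity, so related and
unrelated scores arise in the same joint-genotyping contexts the pipeline
later sees; calibration uses 100–200 pairs per class with held-out
evaluation on independently seeded batches. Scenario recovery is measured
over 200 seeded replicates per scenario against the calibrated cutoff.
These sizes give stable rates while keeping the whole suite fast on a
single CPU.

## Numerical and degenerate-input choices

* Window arithmetic is 0-based half-open internally; files are 1-based
  (VCF/samtools convention), converted once at the I/O boundary.
* Scores are written at 10 significant digits (`%.10g`), enough to make
  rereads exact for the ratios the score produces; invalid scores carry
  `NA` and `wss = nan` in memory.
* Pair ordering is canonical (lexicographic), all output rows are sorted,
  and no timestamps are written, so reruns are byte-identical — the
  determinism the tests assert.
* Degenerate inputs: an all-zero depth track yields breadth 0 and fails
  QC rather than erroring; an empty VCF produces header-only outputs and
  exit 0; a window larger than the reference becomes a single window; an
  empty cutoff table simply excludes every species.

## Known limitations

* Consensus collapsing discards within-sample strain mixtures; a 60/40
  mixture is scored as its majority strain.
* The score's dependence on cohort composition (joint-genotyping matches
  at others' variant sites) means cutoffs are only portable between
  comparable cohort structures.
* `REPLACEMENT` requires only persistence of the new strain through the
  anchor, not a minimum number of timepoints; with sparse sampling a
  transient excursion adjacent to the anchor is indistinguishable from a
  replacement by construction.
* Causal attribution (antibiotics, diet, maternal origin) is out of
  scope; the statistics module only tests frequency differences.
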