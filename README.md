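# wsstrack

Window-based SNV similarity (WSS) strain tracking for longitudinal
metagenomic samples.

Shotgun metagenomes of the same body site taken months apart can carry the
*same* strain of a species or a *different* one, and telling the two apart
is the basis for studying strain persistence, replacement and transient
excursions — for example in the developing infant gut, where dominant
strains may be stable for years, be displaced for good, or disappear and
return. `wsstrack` implements that analysis for anyone with per-species
multi-sample VCFs and per-sample depth tracks: it scores every pair of
samples by genome-wide genotype concordance, calls pairs related or
unrelated against a species-specific cutoff, and reconstructs each
subject's longitudinal strain history.

## The score

For samples *i*, *j* mapped to one species reference, partition the
reference into fixed windows (default 1 kb). In window *w*, let
*P<sub>w</sub>* be the positions genotyped in both samples; the window
concordance is

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>w</sub>* = |{p ∈ P<sub>w</sub> : a<sub>i</sub>(p) = a<sub>j</sub>(p)}| / |P<sub>w</sub>|

where *a<sub>i</sub>(p)* is the consensus allele index (0 = reference).
The genome-wide score is

&nbsp;&nbsp;&nbsp;&nbsp;WSS(i, j) = 100 · mean{ *s<sub>w</sub>* : *w* usable in both samples, |P<sub>w</sub>| > 0 }

Coverage filtering happens first: a sample is excluded when its breadth of
coverage is < 30% or its mean depth is < 3.5, and a window is ignored for
a sample when more than 50% of its bases have depth < 5. The pair is
**related** (same strain) when WSS strictly exceeds the species cutoff.

From all pairwise calls of one subject × species, the package builds the
anchor mosaic (each sample vs. the last scorable sample), classifies the
stability pattern — `STABLE`, `REPLACEMENT`, `TRANSIENT`, `NO_DOMINANT` —
partitions non-anchor samples into mutually-related strain groups
(connected components; singletons are orphans), and compares pattern
frequencies between exposure groups with one-way ANOVA + Tukey HSD.

## Worked example

Simulate a subject whose dominant strain is transiently displaced at one
timepoint, then run the whole pipeline:

```sh
wsstrack simulate --scenario TRANSIENT --seed 11 --out-dir fix
printf 'synth_species\t75.0\n' > cutoffs.tsv
wsstrack all --vcf fix/samples.vcf --depth-dir fix \
    --cutoffs cutoffs.tsv --meta fix/metadata.tsv --out-dir out
```

`out/relatedness.tsv` holds the scored pairs:

```
species	sample_a	sample_b	wss	cutoff	related
synth_species	subject1_t00	subject1_t01	0	75	false
synth_species	subject1_t00	subject1_t02	97.39583333	75	true
synth_species	subject1_t00	subject1_t03	100	75	true
synth_species	subject1_t01	subject1_t02	2.604166667	75	false
...
```

Sample `t01` scores ~0 against every other timepoint (a different strain),
while the remaining samples score 97–100 against each other (the same
strain resampled with consensus-calling noise). The timeline tables follow:

```
# out/patterns.tsv
subject_id	species_id	pattern
subject1	synth_species	TRANSIENT

# out/groups.tsv
subject1	synth_species	subject1_t00	ANCHOR_GROUP
subject1	synth_species	subject1_t01	ORPHAN
subject1	synth_species	subject1_t02	ANCHOR_GROUP
...
```

The classification matches the generating truth in `fix/truth.tsv`: strain
A is dominant, strain B appears once and vanishes (`TRANSIENT`), and the
intruding sample is related to nothing (`ORPHAN`).

The same steps are available as library calls (`simulate_scenario`,
`score_scenario`, `build_timelines`, …); see `docs/methods.md` for the
model, parameter and design details.

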