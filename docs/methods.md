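# Methods

This note documents the models and procedures implemented in `ladomics`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer should
know about. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All intervals are 0-based half-open (`[start, end)`, the BED
convention). One-based CpG coordinates from array manifests become
`[pos−1, pos)` on ingest. Overlap requires at least one shared base;
`[0,100)` and `[100,200)` abut and do not overlap, and their gap
distance is 0 (gap = start of next − end of previous). Strand is carried
but ignored by every overlap and distance query. Chromosome names match
exactly; `normalize_chrom`/`AnnotationTrack.normalized` map the bare
dialect (`1`) onto `chr1` for mixed public tracks. Queries on
chromosomes absent from a track have *undefined* distance (NaN) and are
excluded from medians rather than treated as infinitely far.

## Probe filtering

A probe is removed when its detection p-value exceeds 0.01 in **any**
sample, or when flagged sex-chromosomal, SNP-affected or cross-reactive.
"Fail in any sample" is the strictest per-sample rule; the per-rule
removal counts are logged so the choice is auditable and relaxable.
Array normalisation is out of scope: the pipeline consumes normalised
beta values.

## Moderated differential methylation

Per probe, the two-group OLS residual variance `s²_g` (df `n−2`) is
shrunk toward an empirical-Bayes prior `(d0, s0²)` estimated from the
ensemble of log variances: with
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, the excess of `Var(e)` over
`ψ′(d_g/2)` is inverted through the trigamma function to give `d0`, and
`s0²` follows from the mean of `e`. The trigamma inversion is a monotone
bisection to tolerance 1e−8; `d0` is capped at 1e6 and treated as
infinite beyond (all variances then equal `s0²`). If the excess is
non-positive the prior is infinite; if fewer than two probes have
positive variance the fit falls back to unmoderated F with a warning.
The moderated statistic is `F = Δβ²/(s̃²(1/n₁+1/n₂))` against
`F(1, d0+d_g)` (a chi-squared reference when `d0` is effectively
infinite). All-constant probes give `F = 0, p = 1` by definition;
zero-variance probes with a non-zero effect give `p = 0` with a warning
rather than NaN. A test cross-checks the whole path against R limma's
`lmFit`+`eBayes` on the same matrix.

Tests run on the beta scale by default; `use_mvalues` applies
`log2(β/(1−β))` after clipping at 1e−6. The original scale is not
asserted — both are supported. Significance defaults to BH q < 0.05.

## Bounded probe clustering

A greedy left-to-right scan per chromosome opens a new cluster when the
gap to the previous probe exceeds 500 bp or the span (last member
position − first member position) would exceed 1500 bp. Span is measured
position-to-position; singletons are allowed; output is invariant to
input order (sorting is internal) and equals an exhaustive reference
implementation on random inputs. The cluster summary fed downstream is
the unweighted mean beta of member probes per sample (median by flag);
variability is the across-sample standard deviation (n−1) of that
summary. Ranking ties are broken by (chrom, start) so top-k selection is
deterministic.

## Consensus subtyping

Per repetition, `ceil(p_item·n)` samples (and `ceil(p_feature·m)`
features) are drawn without replacement, the subsample is clustered by
average-linkage agglomeration, and one linkage tree is cut at every
K = 2..max_k. Consensus(i,j) is co-clustered reps over co-sampled reps;
the final per-K assignment is average-linkage clustering of
1 − consensus. Defaults: max_k 6, reps 1000, p_item 0.8, p_feature 1.

*Distance.* The inner metric defaults to Euclidean. Correlation distance
(1 − Pearson) is available but degenerates under a global compression of
the beta scale: a sample drifting toward partial methylation (β → 0.6)
shrinks its feature variance, and its correlation distance to its own
subgroup can exceed its distance to other groups, destroying the
planted three-group structure. Euclidean distance on cluster summaries
has no such pathology.

*K selection.* The consensus CDF area `A(K)` always grows with K — even
on clean K\*-group data, forcing K\*+1 clusters splits a true cluster
arbitrarily per subsample and keeps adding a few percent of area per
extra K — so thresholding the relative delta area alone selects max_k.
The implemented rule takes the largest K whose relative area increase
exceeds 0.05 **and** whose consensus is near-binary (proportion of
ambiguous clustering, PAC over (0.1, 0.9), at most 0.01). A flat,
ambiguous K=2 consensus (PAC > 0.1) is reported as "no structure" with
chosen_k = 2. Both curves are emitted for audit.

*Reproducibility.* Per-rep generators derive from `(seed, rep_counter)`,
so the loop is deterministic and parallelisable without changing the
stream.

PCA of the cluster matrix centres columns, decomposes by full SVD, and
fixes each component's sign so its largest-magnitude loading is
positive, making embeddings identical across runs and BLAS builds.

## Enrichment statistics

For a feature selection within a track membership over one universe,
`expected = n_selected × (n_in_track / n_universe)`; the signed fold is
`observed/expected` when enriched and `−expected/observed` when depleted
(exactly +1 at independence, −∞ if nothing selected overlaps the track).
The chi-squared test subtracts `min(0.5, |O−E|)` from each cell's |O−E|
(Yates correction capped so independence gives exactly 0). Fisher's
exact test reports the sample odds ratio `ad/bc` (infinite/zero for a
zero cell, with a finite p) and the two-sided p summing hypergeometric
probabilities at or below the observed table's. Peak distributions over
feature classes are counted non-exclusively (≥1 bp overlap per class);
"non-LAD" counts peaks overlapping neither LAD track. Probe↔track
membership is computed once from probe point coordinates and shared by
every stratified analysis.

Stratified Δβ comparisons report the per-stratum median of per-probe
case−control mean differences with an **unpaired** Welch t-test of the
per-probe case means against the per-probe control means; a paired
variant (per-probe differences against zero) is available by flag, as
the original choice is not determinable.

## Track signal

Poised enhancers are maximal chains of ≥2 peaks whose edge-to-edge gaps
are each below 1500 bp, emitted as one region from the first peak's
start to the last peak's end (center-to-center gaps and per-pair output
are flags). LAD/inter-LAD ChIP enrichment is
`log2((chip+0.5)/(input+0.5))` per region — the symmetric pseudocount
keeps zero-coverage regions finite — compared by a two-sided Wilcoxon
rank-sum test: exact enumeration when the pooled sample is ≤12 with no
ties, otherwise the normal approximation with midranks, tie-corrected
variance and a 0.5 continuity correction. Coverage extraction from
alignments is out of scope; region signal is consumed from TSV.

## Epigenetic age

`age(score) = (1+a)·exp(score) − 1` for score < 0 and `(1+a)·score + a`
otherwise, with adult-age anchor a = 20; the branches meet continuously
at score 0. The passage factor `ρ = passages × 3.32 × log₁₀(h/s)` uses
log base 10 — the 3.32 ≈ 1/log₁₀2 constant makes ρ a cumulative
population-doubling count, which is the only reading under which the
constant is meaningful. How ρ should correct an age estimate is left
open by the underlying method; the package reports ρ alongside the raw
Δage and offers least-squares residualisation of Δage on ρ as an
explicitly labelled adjustment. Clock coefficients are consumed from a
TSV plus a YAML side-car (intercept, adult_age); no published
coefficient set is bundled, and tests use synthetic clocks constructed
by inverting the transform at known ages. Missing clock probes error by
default; `mean_impute` substitutes the cohort mean.

## Multi-omic integration

Features map to every gene whose body they overlap by ≥1 bp (promoter
mode: TSS ± 2 kb, an explicit opt-in; no promoter definition is imposed
by default). Gene-set LAD distance uses the union of the lamin A and
lamin B tracks ("and/or"), measured from gene bodies (TSS mode by flag),
with pairwise rank-sum tests between sets. Cross-study expression
correlation intersects genes by id and applies `log2(x+1)` by default
(flag to disable). The cross-disease probe ranking takes the top k
probes by absolute group mean difference with ties broken by probe id.

## Synthetic-data generator

The generator emulates the structure the analyses assume, at desk scale:

- **genome** — 4 chromosomes × 25 Mb; alternating LAD/inter-LAD blocks
  with exponential lengths (mean 500 kb) covering ~20% of the genome for
  lamin A (30% for the independently drawn lamin B track); 2,000 genes
  placed uniformly; 7 histone-mark tracks whose LAD affinity mirrors
  their chromatin class (H3K9me3 0.8, H3K4me1 0.6, H3K27me3 0.5, active
  marks ≤0.1).
- **probes** — 20,000 CpGs, 12% inside LADs (LADs are probe-poor);
  region classes island/PMD/HMD with Beta-distributed values
  parameterised by (mean, concentration): means 0.10/0.60/0.85, per-probe
  sd 0.03/0.05/0.03, probe-level mean jitter 0.05. PMD probability 0.8
  inside LADs, 0.05 outside; solo-WCGW flag on 15% of PMD/HMD probes;
  1% each sex/SNP/cross-reactive flags and 0.5% planted detection
  failures exercise the filter.
- **samples and effects** — 6 controls, 5 + 4 case subgroups (the
  study's design). Cases carry +0.10 beta on 2,000 LAD probes chosen
  from those with headroom (so the shifted mean stays inside (0,1);
  infeasible configs error). Subgroup 2 additionally drifts every probe
  30% of the way toward β = 0.6 — the partial-methylation signature of
  the age-accelerated subgroup.
- **peaks** — 545 differential peaks (397 gained / 148 lost) over 5,000
  uniform background peaks. The in-LAD placement probability for
  differential peaks is solved so the signed fold against the *pooled*
  universe targets 2.6 in expectation (the pooled-universe expectation
  otherwise biases the realised fold below the placement ratio).
- **expression** — 343 DE genes (160 up / 183 down), half drawn from
  genes within 10 kb of a lamin A LAD.
- **clock** — 200 extra probes on a dedicated contig; beta columns are
  constructed by inverting the age transform at planted DNAm ages
  (chronological + 9.73 years for subgroup 2, −1.51 for subgroup 1), so
  the noise-free clock round-trips exactly.
- **ChIP signal** — per LAD/inter-LAD segment, input ~ lognormal at coverage scale (~100) and
  ChIP = input × 2^1.0 inside LADs, for the signal-enrichment stage.

Everything is a pure function of `(config, seed)` (numpy Generator
seeded per stage by `[seed, stage_id]`); outputs are byte-identical
across reruns, and a truth JSON records every planted effect.

What the generator does **not** emulate: spatial autocorrelation of
methylation beyond shared region class, probe-type (Infinium I/II)
chemistry, batch effects, cell-composition heterogeneity, correlated
detection failures, read-level data, and realistic gene/peak length
distributions. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted effects under the
assumed structure — not robustness to array artefacts that the out-of-
scope normalisation steps would address on real data.

## Problem sizes and runtime

Defaults (20,000 probes, 15 samples, reps = 1000, 5,545 peaks, 2,000
genes) run the full pipeline in well under a minute on one CPU; the test
suite's heavier property checks (exhaustive Fisher enumeration over all
2×2 tables with total ≤ 60; 20-seed subtype recovery at reps = 100) are
sized to complete in a few minutes. These sizes are the package's
chosen desk-scale study conditions; all are configurable.

## Known limitations

- K selection, like any resampling-stability criterion, cannot
  distinguish a consistently-splitting outlier sample from a true small
  subgroup; the PAC and delta-area curves should be inspected on real
  data.
- The moderated F assumes normal within-group errors; on bounded beta
  values with moderate concentration the type-I calibration holds
  empirically (acceptance check), but heavy-tailed probes on real arrays
  may benefit from the M-value scale.
- The ρ-correction of DNAm age is a linear residualisation and is
  labelled as such; no claim is made that it reproduces any particular
  published correction.
- Depletion folds are reported on the signed scale (−expected/observed),
  which is undefined (−∞) at observed = 0; the plain ratio column is the
  regular alternative.
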