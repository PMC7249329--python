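# ladomics

LAD-centric integrative epigenomics for progeroid fibroblast studies:
differential DNA methylation with empirical-Bayes variance moderation,
bounded CpG probe clustering, resampling consensus subtyping,
annotation-track enrichment statistics, epigenetic-age estimation with
passage correction, and multi-omic integration of methylation, chromatin
accessibility and expression around lamina-associated domains (LADs).

## The problem

In Hutchinson-Gilford progeria syndrome (HGPS), fibroblasts expressing
the mutant lamin A variant progerin show epigenetic deregulation that is
concentrated in LADs — the gene-poor, heterochromatic genomic regions in
contact with the nuclear lamina. Characterising that deregulation takes
a pipeline of coupled analyses over Infinium EPIC beta values, ATAC-seq
differential peak tables, RNA-seq differential expression tables, and
public annotation tracks (lamin A/B LADs, histone marks, PMD/HMD and
solo-WCGW CpG strata). This package implements that pipeline as a
tested, reusable library with a CLI, plus a seeded synthetic-data
generator that reproduces the study's statistical structure so every
stage is testable without downloads.

## The statistics at the core

**Moderated differential methylation.** Per CpG probe *g*, an OLS fit of
the (beta-scale, optionally M-value) methylation values on a two-level
group indicator gives the residual variance *s²_g* with *d_g = n − 2*
degrees of freedom. A scaled inverse-chi-squared prior *(d₀, s₀²)* is
estimated from all probes by the method of moments on log variances
(trigamma inversion) and shrinks each variance to

&nbsp;&nbsp;&nbsp;&nbsp;*s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)*,

yielding the moderated *F_g = Δβ²_g / (s̃²_g (1/n₁ + 1/n₂))* against
*F(1, d₀ + d_g)*, with Benjamini-Hochberg control across probes. Positive
Δβ = case − control means hypermethylation in cases, everywhere.

**Signed fold enrichment.** For a selection of probes or peaks inside an
annotation track, *expected = n_selected × (n_in_track / n_universe)*;
enrichment is reported as *observed/expected* and depletion as
*−expected/observed* (so −1.56 means 1.56-fold depleted), tested by
Pearson's chi-squared with a capped Yates continuity correction or by
Fisher's exact test.

**Consensus subtyping.** Samples are repeatedly subsampled
(reps × p_item), clustered by average-linkage agglomeration over the
most variable bounded probe clusters, and the pairwise co-clustering
frequencies form per-K consensus matrices; K is selected by the relative
increase in consensus-CDF area subject to a near-binary consensus
(low proportion of ambiguous clustering).

**Epigenetic age.** A sparse linear clock score is mapped to years by
the standard piecewise log-linear transform anchored at adult age 20,
and culture mitotic age is summarised by the passage factor
*ρ = passages × 3.32 × log₁₀(harvested/seeded)*.

## Worked example

```sh
ladomics simulate --out demo_in  --seed 1
ladomics all --in demo_in --out demo_out --seed 1
```

prints

```
INFO ladomics: filtering 20200 probes (detection p > 0.01 in any of 15 samples)
INFO ladomics: differential methylation: 867/19525 significant at q < 0.05
INFO ladomics: consensus clustering: chosen_k=3 (reps=1000, p_item=0.8)
report written to demo_out (chosen_k=3)
```

and `demo_out/summary.json` then contains, among others:

| quantity | value | meaning |
|---|---|---|
| `subtype.chosen_k` | 3 | the 6 controls and the two planted case subgroups are recovered |
| `enrich.lad_stratum_median_delta_beta` | 0.074 | LAD probes are hypermethylated in cases (planted +0.10, diluted by the partial-methylation subgroup) |
| `enrich.peak_lad_signed_fold` | 2.58 | differential peaks are ~2.6-fold enriched in lamin A LADs (planted 2.6) |
| `age.median_delta_age_by_subgroup` | 9.73 / −1.51 / ≈0 | DNAm-age acceleration per consensus subgroup (planted values) |
| `integrate.lad_distance_p.all_genes_vs_de_genes` | 7.7e−09 | differentially expressed genes sit closer to LADs than background |

Each stage can also run standalone on the files of the previous one
(`ladomics filter|diffmeth|clusters|subtype|enrich|age|integrate|report
--in demo_in --out demo_out`), and every stage is importable as a
library function or sklearn-style estimator
(`ModeratedDifferentialMethylation`, `ConsensusClustering`,
`BoundedProbeClusterer`, `EpigeneticClock`).

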