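# Methods

## Overview

`mirmeta` ranks miRNA–mRNA target pairs by the combined, direction-aware
evidence that the miRNA differs between two parental mouse strains, that
the target mRNA differs between the same strains, and that the target mRNA
tracks a quantitative phenotype (LORR, minutes) across a recombinant-inbred
panel. Four independent analyses feed a per-pair signed Stouffer
combination; the pair list is controlled at FDR 0.10 and summarised as a
bipartite network.

## Component models

### miRNA strain test (count studies)

Counts are assumed negative-binomial with the mean–dispersion
parameterisation Var(Y) = μ + φμ². For each feature we fit log-linear
models with the natural log of the per-sample 75th-percentile count
(upper-quartile factor) as offset. The two-level strain factor saturates
the design, so each group mean is a one-dimensional MLE obtained by solving
the score equation Σ (y_j − s_j m)/(1 + φ s_j m) = 0 by bracketed root
finding; this is numerically identical to IRLS (verified against
statsmodels GLM in the test suite) and an order of magnitude faster, which
matters for the replicated calibration studies. φ is a per-feature moment
estimate from the group-saturated Poisson fit, clipped to [1e-8, 1e3] to
stabilise fits at n = 3 + 3.

The test statistic is quasi-likelihood: F = (D₀ − D₁)/(D₁/(n − 2)) with D₀,
D₁ the NB deviances of the intercept-only and strain models, referred to
F(1, n − 2). The deviance-based quasi-dispersion absorbs residual over- or
under-dispersion relative to the working NB model. Simulation at n = 3 + 3,
φ = 0.05 shows the test is well calibrated (type-I error ≈ 0.049 at
α = 0.05) and has ≈ 0.99 power at a true fold change of 4 and moderate
abundance; both are regression-guarded in the tests. Unshrunken per-feature
dispersions are used; spline-shrunken dispersions were considered and not
implemented, since calibration at the target sample size did not require
them.

### Expression filter and normalization

A feature is "expressed" if strictly more than 1 count per million is
attained in at least 3 samples, independently in every study; feature
universes are intersected first. CPM uses total library size; the display/
GLM normalisation uses the upper quartile, computed with the
linear-interpolation (type-7) percentile so values are exactly testable.
`normalize_uq_log` returns ln(count/Q75 + pseudocount) with pseudocount 1.
Adding the pseudocount after scaling keeps the transform invariant under
rescaling all counts in a sample, which we consider the defining property
of a library-size normalisation; adding it to raw counts would break it.

### mRNA strain test (moderated t)

Per gene, an ordinary two-group fit between the parental strains (effect =
ISS − ILS on the log scale, pooled variance s² on d df), then
empirical-Bayes shrinkage: the marginal distribution of s² is modelled as
s₀²·F(d, d₀) and (d₀, s₀²) are estimated by matching the mean and variance
of ln s² (digamma/trigamma moment equations, trigamma inverted by Newton
steps). Moderated variance s̃² = (d₀s₀² + d s²)/(d₀ + d); t = effect/(s̃·√(1/n₁+1/n₂))
on d₀ + d df. When the log-variances show no excess spread the estimate is
d₀ = ∞ and every gene uses s₀² with a normal reference. The implementation
agrees with R limma's `eBayes` to ~1e-14 on shared input and with a direct
numerical MLE of the scaled-F marginal within 10% (both checked in tests).

### Phenotype correlation

Spearman rank correlation (average ranks for ties) between gene strain-mean
expression and strain-level LORR, parental strains excluded. Two-sided p is
computed by full enumeration of all n! rank orders for n ≤ 8 and by the
t-approximation t = ρ√((n−2)/(1−ρ²)) on n − 2 df for larger panels; at the
typical panel size (n = 60) enumeration is infeasible and the
t-approximation is accurate. Constant inputs yield ρ = NaN, p = 1, flagged
degenerate.

### Pair combination and orientation

p-values are clamped to [1e-300, 1] before Φ⁻¹. Orientation constants
(+1, +1, −1, +1) for (miRNA study 1, miRNA study 2, mRNA DE, correlation)
make the repression-concordant configuration add constructively; flipping
every component sign leaves p unchanged and maps the pattern label to its
mirror, so the two concordance classes are treated symmetrically. The
default combines four sources (the two miRNA studies enter separately,
matching the published two-study arithmetic); a 3-source mode that first
collapses the miRNA studies into one meta z is available as a configuration
switch. Benjamini–Hochberg is the step-up procedure from statsmodels;
significance thresholds default to 0.10 (significant set) and 0.05 (top
set), both exposed.

### Network and genomic overlap

Significant pairs form a bipartite graph (networkx); edge weight is
−log₁₀(p) capped at 300. Hubs are miRNAs with ≥ 5 targets. Genomic overlap
between miRNA loci and QTL intervals uses BED conventions (0-based,
half-open, strand ignored) with a per-chromosome sorted sweep, validated
against the quadratic all-pairs oracle.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: two count
studies with 3 replicates per strain each, library sizes log-uniform on
[2M, 7M] (mimicking the median library-size gap between typical small-RNA
batches), heavy-tailed relative abundances (log-normal, σ = 1.5), NB counts
at dispersion 0.05; a 60-strain panel with strain-level LORR ~ N(60, 15²)
truncated at 0; parental mRNA replicates (3 + 3) with residual sd 0.25; and
a target-database snapshot in which ~30% of null pairs carry validation
evidence and predicted support follows a geometric distribution so the
5-of-8 consensus filter removes the large majority.

Planted signal pairs follow the repression-concordant pattern: miRNA mean
ratio ISS/ILS equal to the configured fold change (split symmetrically so
overall abundance is preserved), mRNA shift ISS − ILS (default −0.5, i.e.
up in ILS), and a positive Spearman correlation with LORR planted through a
Gaussian copula: for target rank correlation ρ_s the latent Pearson
correlation is 2·sin(πρ_s/6), so the expected Spearman magnitude equals the
configured value. Because the analysis uses only ranks, only this copula —
not the marginal scales — matters.

What the generator does **not** emulate: batch effects and the
saline-vs-naïve treatment covariate (the studies are analysed
independently), sequencing artefacts upstream of the count matrix,
probe-level array noise, genetic relatedness among panel strains, and
dependence between database support and expression. Passing tests
demonstrate the statistical machinery is correct and calibrated under the
assumed model; they do not certify behaviour under real-data artefacts
outside that model.

## Calibration study design

Null-calibration checks use a node-disjoint pair universe (pair i joins
miRNA i to gene i) generated through the planted-pair slots with all effect
sizes at their null values. This matters: in a realistic pair universe many
pairs share a miRNA or a gene and therefore share evidence, so their
combined p-values are dependent — marginally uniform but not an iid sample,
which would confound a KS uniformity test. With disjoint pairs the combined
null p-values pass KS uniformity (p ≈ 0.8 at ~2100 pairs) and BH at 0.10
keeps the empirical false-discovery proportion ≤ 0.15 over 200 replicates.
Signal recovery uses 10 planted pairs among ~2000 retained null pairs
(300 miRNAs × 1500 genes), fold change 2, shift −0.5, |ρ| = 0.4, averaged
over 20 seeds; observed ranking AUC ≈ 0.999. Problem sizes for these
studies (replicate counts, features per replicate) were chosen as the
smallest giving stable Monte-Carlo estimates of the quantities under test.

## Numerical choices and degenerate inputs

- NB dispersion clipped to [1e-8, 1e3]; root-finding bracket spans 1e±6
  around the count-weighted mean.
- All-zero count features: p = 1, effect 0, flagged degenerate. One strain
  all-zero: infinite log-fold-change with the correct sign; the F-test
  still applies.
- p-value clamp 1e-300 before quantile conversion; edge weights capped at
  −log₁₀ p = 300.
- Effect direction 0 (exactly zero effect) is coerced to +1 when entering
  the signed combination; this only occurs alongside p = 1 where z = 0
  regardless of sign.
- Thresholds are strict where the contract says strict: CPM filter uses
  `> min_cpm`; FDR calls use `q < threshold`.
- Ties in ranks use average ranks with the Pearson-on-ranks formula, which
  equals the tie-corrected Spearman.

## Known limitations

- The QL strain test is a documented NB quasi-likelihood F-test; it is not
  a numerical clone of any specific R package's spline-shrunken variant.
  Its acceptance surface is calibration, not cross-package parity.
- The exact-p Spearman path is exponential in n and restricted to n ≤ 8;
  the t-approximation at panel scale differs slightly from other "exact"
  large-n algorithms.
- The per-pair combination treats the four sources as independent, which
  is the design assumption (different animals/batches per source); shared
  animals between sources would inflate combined significance.
- BH is applied to dependent pair p-values in realistic universes (shared
  miRNAs/genes); BH is robust to this positive dependence but the FDR
  guarantee is then approximate.
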