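# Methods

## Study design

The pipeline analyses a cohort of monozygotic (MZ) twin pairs with blood
DNA methylation measured once (at follow-up) on a 450K-style array and a
composite cognition score measured at two waves roughly a decade apart.
Four association scans are run on a single QC-filtered probe set, plus one
variant:

| scan | unit | phenotype |
|---|---|---|
| paired-cognition | complete pair | Δ follow-up composite |
| paired-cognition-discordant50 | most discordant half of pairs | Δ follow-up composite |
| paired-change | complete pair | Δ 10-year change score |
| unpaired-cognition | individual | follow-up composite |
| unpaired-change | individual | 10-year change score |

The paired scans remove all pair-shared confounding (genotype, shared
environment) by differencing; the unpaired scans keep every individual —
including members of incomplete pairs — and model within-pair dependence
explicitly, avoiding the deflated standard errors naive OLS would produce.

## Probe QC and the M-value scale

QC acts in three ordered stages. Measurement-level masking: a probe×sample
value becomes missing when bead count < 3 (strict), detection p > 0.01
(strict — a p exactly at the cutoff is retained), or the signal is zero.
Probe-level filtering: probes missing in more than 5% of samples are
dropped, and of the remainder any probe on a caller-supplied
cross-reactive list is removed; reasons are mutually exclusive with
missingness taking precedence, so QC reports tally exactly. The ordering
matters because the missingness rule is only meaningful after
measurement-level masking. Surviving values are never altered, and
filtering is idempotent.

Retained betas are mapped to M-values `log2(b/(1−b))` — base 2, the
conventional M-value — after clipping b into `[ε, 1−ε]` with ε = 1e-6
(configurable) so that fully methylated or unmethylated measurements stay
finite. "Zero signal" is taken as a measurement-level boolean supplied with
the QC metrics rather than derived from intensities, since the pipeline
consumes already-normalized betas. Sample-level QC and normalization are
upstream concerns and out of scope.

## Cognitive composite

Six test scores (verbal fluency, immediate recall, delayed recall,
processing speed, attention, working memory) are z-scored with per-test
mean/SD estimated on a single reference wave — intake by default — and the
same parameters are reused at follow-up so the two composites are
commeasurable; the composite is the sum of the six z-scores. If exactly
one component is missing the five-component sum is prorated by 6/5; with
two or more missing the composite is unavailable. The change score is
follow-up minus intake and requires both waves.

Which wave supplied the original standardization parameters is genuinely
open; intake is the default because it makes follow-up decline
interpretable on the baseline scale, and the choice is a keyword argument.
Parameters are estimated over all individuals with the component observed
(no pair weighting).

Cohort-level decline is tested by fitting an intercept-only model with a
pair random intercept (the same REML machinery as the unpaired scan) and a
Wald t on the intercept with df = n − 1. This df is approximate — the
random-intercept fit already discounts pair-shared variance — and is
deliberately simple because only direction and significance of the decline
are of interest, not a precise p.

## Cell composition

Leukocyte differentials (monocytes, lymphocytes, basophils, neutrophils,
eosinophils) enter every scan as covariates. When some samples lack
measured counts, a multivariate partial-least-squares regression is fitted
on the measured samples with `log(count+1)` for the five subtypes as the
joint response; predictors are every probe observed in all samples
(beta scale by default; configurable) plus sex, age at follow-up and the
chip-position dummies (side Left/Right; row 1–6). Predictors are centered
and unit-scaled inside the PLS fit (mixed scales: betas vs. years). The
component count defaults to 10 and can be chosen by K-fold
cross-validation. Predictions are back-transformed with `exp(·)−1` and
floored at 0 (a physical constraint). Measured samples pass through
untouched and imputed ones are flagged. The PLS engine is
scikit-learn's `PLSRegression`. Reference-based deconvolution is a
non-goal: the design assumes measured counts plus imputation.

Cell counts enter the association models as raw counts (differences of raw
counts in the paired scan); the log transform is reserved for imputation,
where it is part of the model definition.

## Paired scan

For each complete pair the minuend is the lexicographically smaller sample
id — a deterministic but arbitrary orientation; an intercept in the
difference regression absorbs any orientation-dependent mean shift, and
the phenotype coefficient is invariant to the convention. The model per
probe is OLS of ΔM on {intercept, Δphenotype, sex (female = 1), age,
5 Δcell counts}, i.e. 9 parameters; inference is an exact two-sided t with
df = n_pairs − 9. Probes with missing differences are fitted on their
complete pairs. The estimator is algebraically identical to the
within-pair fixed-effects (pair-dummy) estimator on individual-level data;
the test suite verifies the equivalence to < 1e-8 per probe.

The discordance subset ranks pairs by |Δphenotype| descending (ties broken
by pair id) and keeps the top ⌈fraction·n⌉ with fraction 0.5 by default;
it is applied to the cross-sectional analysis only.

## Unpaired scan (random-intercept REML)

With clusters of at most two, the compound-symmetric pair covariance
diagonalises exactly: within-pair sums carry variance σ²(1 + 2λ), within-
pair differences σ², and singletons σ²(1 + λ), where λ = σ²_pair/σ²_resid.
REML therefore reduces to a one-dimensional profile over λ: at each
candidate the GLS fit is a weighted least-squares solve on the transformed
rows. The profile is maximised by bounded Brent search on log10 λ over
[−8, 6] (xatol 1e-8); λ = 0 is always evaluated explicitly, so boundary
estimates σ²_pair = 0 are allowed and reproduce OLS exactly. A two-stage
dense grid (1e-2 coarse spacing over log10 λ ∈ [−6, 2], then 1e-4 spacing
around the coarse optimum) serves as an independent oracle in the tests;
statsmodels' `MixedLM` is a second cross-check.

Fixed effects are {intercept, phenotype, sex, age, 5 cell counts}; the
reported statistic is the Wald t on the phenotype coefficient with
df = n − 9. This df is simple and slightly conservative at cohort sizes in
the hundreds; Satterthwaite-style corrections are out of scope. Fixed-
effect SEs are the GLS form σ̂²(X'V⁻¹X)⁻¹ (statsmodels' Hessian-based SEs
differ by ≲1% at these sizes). Per-probe fits are independent and may run
in any order with identical results.

Calibration: under a null with pair-correlated methylation and phenotype,
the scan's type-I error at α = 0.05 averages ~0.05, while naive OLS on the
same data is anticonservative — that gap is the design's reason to exist.
The per-dataset rejection rate varies a few points around 0.05 because all
probes share one realized design; the calibration test therefore pools
2000 null probes across eight independently simulated cohorts so the rate
reflects the estimator rather than one design draw.

## Reporting and enrichment

Probe results are reported against fixed thresholds — suggestive p < 1e-5,
genome-wide significant p < 1e-6, cross-analysis overlap at p < 1e-4, all
strict — rather than FDR-adjusted, matching common 450K practice; a
Benjamini–Hochberg utility is available as an optional column. BH takes an
explicit family size `m_total` because displayed p-value lists are often
truncated below a display threshold; inferring m from the list length
would silently mis-correct, so family size must be supplied (it may exceed
the list length, in which case the unlisted tests are assumed larger than
every listed one). Ties sort stably by probe id everywhere a deterministic
order is needed.

Annotation joins attach nearest gene, position and CGI context without
touching the statistics; unannotated probes are kept with missing fields.
Distances are signed (negative = upstream) and missing when the probe lies
inside its gene. Overlap between analyses is computed at both the probe
and the gene level — two analyses can share a gene through different
probes — and a probe/gene must pass the cutoff in both analyses to count.

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ O) with the reference universe equal to the unique gene symbols on
the filtered array annotation; per set the displayed statistics are
C (set genes in the universe), O (overlap with the hit list), E = C·n/N,
R = O/E. Gene-set catalogs are user-supplied GMT files, never bundled —
database contents drift; the statistic, not the catalog, is what the
package reproduces. BH adjustment uses m = number of sets actually tested
(all sets with ≥ `min_set_size` universe genes, before display filtering).

## Synthetic cohort generator

The generator's defaults describe the cohort the pipeline was designed
around: 243 complete same-sex pairs (111 female / 132 male), ages 55–79 at
follow-up, nine samples without measured cell counts, a mean 10-year
composite decline of −1.64 with SD 3, and ~6% of probes cross-reactive.
Methylation per probe is μ_p + u_pj + e_pij on the M scale with a bimodal
baseline (modes near beta 0.15/0.85, cosmetic realism), pair variance
σ²_pair = 0.12 and individual variance σ²_indiv = 0.12 by default (twin
ICC 0.5; per-probe M-value SD ≈ 0.49, typical of intermediately variable
array probes); a 20% subset of probes carries Gaussian loadings on the
standardized log leukocyte counts. Cognition components arise from a
pair-shared and an individual general factor (each half of the component
variance) plus component-specific noise, with the general-factor split
chosen so the intake composite's twin correlation equals
`cognition_pair_icc` exactly; follow-up components equal intake plus one
sixth of the individual change score. All randomness flows from one root
seed through named `SeedSequence` streams, so cohorts are bit-reproducible
and any file set can be regenerated from its manifest.

Planted associations are written as M = baseline + effect·phenotype +
noise, with the phenotype (follow-up composite or change score) computed
by the package's own phenotype functions before methylation is drawn. Two
consequences: the planted effect is exactly the estimand of every scan
(the regression slope of ΔM on Δphenotype), so recovery tests can assert
unbiasedness; and the slope refers to the same composite scale the
pipeline analyses, avoiding an O(1/√n) bias from re-estimated
standardization parameters. The generator is silent on causal direction —
the scans are symmetric association tests, and the package makes no causal
claim.

What the generator does **not** emulate: co-methylation blocks and LD
structure (probes are independent given the phenotype), batch effects
beyond chip position, non-Gaussian methylation distributions, practice
effects or selective attrition in cognition, and measurement error in cell
counts. Passing tests therefore demonstrate correctness of the estimators
and pipeline plumbing under the stated model, not robustness to every
feature of real array data.

## Problem sizes in the test and acceptance runs

The shipped test suite and acceptance script use cohorts of 20–250 pairs
and 50–2000 probes: oracle equivalences at 30 pairs × 50 probes, the REML
grid check at 120 pairs × 20 probes, calibration at 200 pairs × 2000 null
probes pooled over eight cohorts, effect recovery at 243 pairs × 2000
probes over 50 replicates (residual σ²_indiv = 0.05 there, putting the
expected planted-effect p far below the 1e-5 reporting threshold), and the
decline tests at 100 pairs over 100 signal and 500 null replicates. These
sizes give Monte-Carlo error comfortably below the asserted tolerances;
the `paper-scale` preset (243 pairs × 20,000 probes) runs the full
pipeline in minutes.

## Known limitations

- Wald t df choices (n − 9 for the scans, n − 1 for the decline test) are
  pragmatic approximations; no Satterthwaite/Kenward–Roger correction.
- The unpaired scan models only pair-level relatedness, not arbitrary
  kinship, and offers no robust/sandwich variance option.
- PLS component count is a heuristic default; the CV chooser is provided
  but not run by default.
- The ORA engine assumes nearest-gene annotation is the right gene mapping
  and tests over-representation only (upper tail).
- Genome build is whatever the caller's annotation uses; the pipeline is
  build-agnostic and does no liftover.
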