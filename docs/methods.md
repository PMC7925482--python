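# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the design decisions behind strigakit.

## The trial mixed model

Plot values from a multi-environment alpha-lattice trial are modelled as

    Y_ijko = mu + G_i + E_j + (GE)_ij + R(E)_kj + B(R.E)_ojk + e_ijko

with environment and replicate-within-environment fixed, and genotype,
genotype × environment and incomplete block random.  Fitting is REML by
the average-information algorithm on the dense covariance
V = Σ σ²_c Z_c Z_c' + σ²_e I, with Newton steps from the AI matrix,
step-halving when a step would decrease the restricted likelihood, and a
damped-EM fallback.  Convergence is declared when the relative change in
restricted log-likelihood falls below 1e-8, with a 200-iteration cap;
non-convergence is flagged in the result and the last estimates are
returned.  Components driven to the boundary are pinned at a small floor
(1e-8 × var(y)), reported as 0, and listed in `truncated` — effectively a
truncate-and-refit treatment of negative REML solutions.

Within-environment fits drop the GE term and keep replicate fixed, block
random.  With genotype fixed the same machinery returns BLUEs (reported as
marginal means, i.e. averaged over the fixed environment and replicate
contrasts); with genotype random it returns BLUPs
û = σ²G Z' V⁻¹(y − Xβ̂) plus the grand mean level.  For balanced data the
BLUE of a line equals its arithmetic mean and the BLUP is a uniform
shrinkage of the centred mean — both are used as test oracles.

Entry-mean heritability is h² = σ²G / (σ²G + σ²GE/E + σ²e/(E·R)).  On
within-environment components it reduces to the repeatability
σ²G / (σ²G + σ²e/R).

Two-stage philosophy: GWAS consumes across- or per-environment BLUPs;
genomic prediction consumes per-environment line values and
across-environment BLUEs.  The environment screen (include an environment
when its repeatability ≥ 0.1 and the genotypic-variance LRT — a 0.5·χ²₁
boundary mixture — has p < 0.05) is exposed as
`pheno.select_environments`; the thresholds are configurable because no
canonical values exist for this gate.

AUSNPC integrates emerged-parasite counts at 8, 10 and 12 weeks after
planting by the trapezoidal rule on a *days* time base (t = 56, 70, 84).
The time unit is a convention: it rescales AUSNPC linearly and cancels in
heritability and correlations.  Outlier removal drops records whose
standardized residual from a preliminary all-fixed-effects fit (line +
environment + replicate) exceeds z_max = 3.5 — roughly a 0.05% two-sided
tail under normality, so clean data lose almost nothing.

## Marker tools

QC keeps markers with MAF strictly > 0.05, missing fraction < 0.05 and
heterozygosity < 0.05 (defaults; all configurable), dropping monomorphic
markers unconditionally.  Imputation is marker-mean (2p), which preserves
per-marker means and is adequate at < 5% missingness for relationship
matrices and scans.  The VanRaden relationship matrix uses sample allele
frequencies; solvers add a 1e-6 diagonal ridge for a positive-definite
guarantee, while the stored matrix is exact (the 3×2 hand example in the
tests is reproduced without ridge).  For a fully homozygous panel the mean
diagonal of G is ≈ 2 (inbreeding f ≈ 1); consumers that need a genetic
variance on the data scale must multiply σ²u by the mean diagonal.  An IBS
similarity is exposed as the alternative kinship; VanRaden G is the
default for both the scan and prediction because a single relationship
matrix keeps the two stages consistent — which matrix a given analysis
pipeline used per-stage is in general ambiguous, so both are available.

LD is the squared Pearson correlation of dosages (composite LD, the
appropriate measure for unphased inbred data), collected for all marker
pairs within a window (default 100 kb), binned by physical distance.
Decay distances at r² = 0.1 and 0.2 are the first downward crossings of
the binned means, linearly interpolated between bin midpoints.  The
effective number of independent tests is total mapped genome length
divided by the r² = 0.1 distance, and the genome-wide threshold is
α / n_eff; the conventional printed thresholds (2e-6 / 5.6e-6) remain the
defaults for hit calling, with the LD-based one available as an override.

## The association scan

The MLM is y = Xβ + m·a + u + e with u ~ N(0, K σ²u).  The null model
(marker excluded) is fitted exactly: eigendecompose K once, rotate, and
optimize the restricted profile likelihood of the ratio δ = σ²e/σ²u by
bounded scalar search on log δ (bounds ±12, xatol 1e-8).  The scan then
holds the components fixed (P3D): data are whitened by V^{-1/2}, markers
and response are residualized on the covariates, and each marker gets a
GLS t-test with a per-marker residual-variance rescale (df = n − p − 1).
This is the standard single-pass approximation; against exact per-marker
REML the p-values typically agree within a few percent (median ≈ 0.2% in
the test suite's spot check), though an individual marker can deviate more
when the refitted variance ratio drifts — the documented price of P3D.
The GLM path is the identical scan with V = I.  Effects are reported per
copy of the minor allele; MAF and an optional allele pair accompany every
marker.  With K = I the MLM test reduces exactly to simple regression,
which the tests exploit as an oracle.

Hit post-processing fits all significant markers jointly by OLS
(aliased columns dropped by a rank-guarded greedy sweep) and reports the
adjusted R² (clipped to [0, 1]) and p_G = R²adj/h², flagged when > 1.

## Genomic prediction

Single-environment GBLUP is the two-component spectral REML above with
K = G₁; predictions for any line in the relationship matrix come from the
cross-covariance σ²G·G₁[new, obs]·V⁻¹(y − Xβ̂), which coincides with the
mixed-model-equations ridge solution (a 1e-6-level agreement oracle in the
tests).  The multi-environment model adds a random environment main effect
(I σ²E) and the interaction with covariance G₁ ⊗ I σ²GE — interaction
effects correlated across lines through G₁, independent across
environments — and is fitted by the AI-REML engine on the stacked
observations.  Fixed effects are an intercept plus optional marker-dosage
covariates.  Environment main effects are random rather than fixed so that
a previously unobserved environment has a well-defined prediction (the
genomic main effect alone); with only a handful of environments the σ²E
estimate is poor but harmless for ranking lines.

Estimation is REML throughout rather than a Bayesian sampler: the point
predictions coincide in expectation, and a deterministic fit is testable
against closed forms.

Cross-validation: CV0 is leave-one-environment-out (deterministic, no
folds); CV1 masks each line fold in *all* environments; CV2 masks each
test-fold line in a uniformly drawn non-empty proper subset of
environments, guaranteeing at least one observed environment per test
line.  Folds are drawn from a counter-based stream keyed by (seed,
repetition) only, so CV1 and CV2 share identical partitions and their
accuracies are paired.  Accuracy is the Pearson correlation of predicted
vs observed per (environment, repetition), pooled over folds within a
repetition and averaged over repetitions (mean of per-repetition
correlations, not a correlation of pooled predictions).  The default
repetition count is 100; the test suite and the acceptance script use 10
as their stated problem size.  Variance components are re-estimated on
each training fold.

Marker-covariate augmentation has two modes: `snp_covariates` fits dosages
chosen on the whole panel (this leaks test-line information into marker
selection and is known to overestimate accuracy slightly) and
`augment_selector` re-selects markers per training fold, which is the
leakage-free variant.  Both are exposed; the tests assert the documented
ordering.

## The collaborative filter

The lines × (trait, environment) matrix is column-standardized on observed
cells (sample SD, n−1 — matching the Pearson-weight convention); item-item
weights are pairwise-complete Pearson correlations of the standardized
columns (minimum 3 complete pairs); and a missing cell is predicted as

    ẑ_ij = Σ_{j′∈N_i(j)} z_ij′ w_jj′ / Σ_{j′∈N_i(j)} w_jj′ ,
    ŷ_ij = μ_j + σ_j ẑ_ij

over the neighborhood of items the line has observed.  The denominator is
the *signed* weight sum, the formulation this predictor is usually written
with; a near-zero signed sum (|Σw| < 1e-8) makes the prediction undefined
(emitted as missing and flagged), and an absolute-value denominator is
available as a config switch — under it the affine-equivariance of
predictions extends to negative rescalings of the target column, whereas
the signed form is equivariant for positive affine maps.  Negative weights
are kept by default (they carry signal through sign flips); top-k
neighborhoods, a drop-negative option and a restrict-to-other-environments
option are exposed since the neighborhood rule admits several readings.

The hold-out evaluation masks line folds (default 5) in the target
(trait, environment) columns and predicts them from everything else; a
fully masked column would leave no observations to standardize or
correlate against, so fold-based masking is the only coherent reading of
the incomplete-field-trial comparison.  Folds come from the same
counter-based stream as the GBLUP cross-validation, so the two methods are
compared on paired masks.

## The synthetic-data generator

The generator defines the study conditions for every test:

* **Genotypes.**  Ancestral allele frequencies uniform on (0.1, 0.9);
  subpopulation frequencies by a Balding–Nichols draw at divergence `fst`
  (default 0.2, typical of structured breeding panels); lines assigned
  round-robin to subpopulations.  Along each of 10 chromosomes a haplotype
  is a first-order *copy-chain*: each allele copies the previous marker's
  allele with probability `ld_rho`, otherwise draws fresh at the marker's
  subpopulation frequency.  This yields the closed-form decay
  r²(k steps) ≈ ld_rho^(2k) used as an analytic oracle, and is valid for
  any frequency spectrum — a chain parameterized by a fixed adjacent
  *correlation* would violate the Fréchet bounds between Bernoulli
  variables of unequal frequency.  The realized marginal frequencies are a
  geometric smoothing of the drawn ones, which only flattens the MAF
  spectrum slightly.  Genotypes are doubled haplotypes (inbreds);
  heterozygous and missing calls are injected at rates (defaults 0.005 and
  0.01) below the QC thresholds so a default panel passes QC by design.
  Marker positions are equally spaced (1 kb default).
* **Trials.**  Line genetic values come from additive effects at 50
  randomly placed QTL, rescaled so the realized sample variance equals
  σ²G exactly (sharp recovery tests); environment-specific QTL deviations
  supply σ²GE per environment, implying a cross-environment genetic
  correlation σ²G/(σ²G + σ²GE).  Defaults (σ²G, σ²GE, σ²e) = (1.0, 0.25,
  1.0) with E = 3, R = 2 — a moderately heritable trait with genetic
  correlation 0.8 across environments, the regime of interest.  Environment
  shifts are fixed draws (σ²E = 1.0); replicates nest in environments and
  incomplete blocks of 5 consecutive plots nest in replicates (the
  alpha-lattice layout), with a warning and a short final block when the
  block size does not tile the panel.
* **Counts.**  Emerged-parasite counts are negative-binomial with log-mean
  = log(baseline_t) + s·z − s²/2, z the standardized genetic liability and
  s = 0.3; the correction keeps grand means at the baselines (defaults
  6.2, 30, 65 at 8/10/12 WAP, the magnitudes such trials report).
  Overdispersion 0.3 by default; 0 gives Poisson.  The raw-count
  distribution in real trials is unknown, so these defaults are calibrated
  to reported means and ranges only.  Downstream stages analyse the raw
  counts with Gaussian mixed models, as such trials conventionally do; no
  transformation is applied by default.
* **Multi-trait panels.**  For the collaborative-filter studies, genetic
  values are drawn from N(0, G σ²G) (consistent with the relationship
  matrix), traits share a common factor with loading √trait_corr, and
  within-column heritability is set by the residual scale.

What the generator does *not* emulate: linkage maps with recombination
hotspots or coalescent genealogies, dominance and epistasis, spatial field
trend, count zero-inflation, and genotyping error beyond random missing
calls.  Passing tests therefore certify the estimators under the stated
covariance structure, not robustness to those real-data features.

## Problem sizes and seeds

The acceptance script runs the single-trait stages at 300 lines × 2,000
markers and the cross-validation stages at 200 lines × 1,000 markers with
10 repetitions of 5 folds — sizes at which every estimator's sampling
error is small relative to the effects being checked, while a full run
stays within a few minutes on one CPU.  Parameter-recovery checks average
20 independent seeds.  All generators and fold streams are pure functions
of their seeds; the pipeline fans a master seed out to per-stage child
seeds by stable hashing of the stage name, so toggling stages never
perturbs another stage's stream.

## Directional comparisons

Two benchmark constructions fix the qualitative comparison between the
collaborative filter and GBLUP under CV2-style masking, mirroring the two
trait archetypes such panels contain:

* a family of six mutually correlated (trait correlation 0.9), moderately
  heritable (h² = 0.55) traits with high cross-environment genetic
  correlation (0.85) on a moderate-structure panel — here the filter's
  noise-averaging across many correlated items beats kinship-limited
  GBLUP;
* a single trait with near-zero cross-trait and cross-environment
  correlations on a relatedness-rich panel (fst 0.3, long LD) — here the
  filter has nothing to borrow and GBLUP's same-environment kinship
  information wins.

## Known limitations

* The AI-REML engine builds dense n × n covariance kernels; it is
  comfortable to a few thousand plots but not designed for very large
  trials.
* P3D is an approximation; markers with very strong effects shift the
  variance ratio and their p-values can deviate from exact per-marker REML
  by more than the typical few percent.
* CV1 accuracy on noise-free data is bounded below 1 by the conditional
  variance of a new line's genetic value given the training lines — a
  property of the relationship matrix, not an estimator defect.
* Mean imputation attenuates LD slightly; at the < 5% missingness the QC
  admits this is negligible for the scan and the relationship matrix.
* The IBCF hold-out and GBLUP CV2 are paired on masks but differ in what
  they may use (other traits vs markers); the comparison is a practical
  benchmark, not a like-for-like estimator contrast.
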