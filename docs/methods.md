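# Methods

This note documents the statistical procedures, the generative model behind
the synthetic studies, the defaults and why they were chosen, the numerical
conventions, and the limitations. Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The two-step design

The pipeline estimates (1) the causal effect of an adiposity exposure on a
panel of circulating inflammatory mediators, and (2) the causal effect of
the exposure-driven mediators on disease. Step 1 uses individual-level data
from several cohorts; step 2 uses only summary statistics from
non-overlapping samples.

### Phenotype preparation

Cytokine-type mediators are right-skewed and zero-inflated, so each trait is
processed as: rank-based inverse normal transform (RNT) → ordinary
least-squares residualization on age, sex and 10 genetic principal
components → second RNT of the residuals. The RNT maps the value with rank
r among n non-missing values to Φ⁻¹((r − c)/(n − 2c + 1)).

* **Offset c = 3/8 (Blom).** No offset is canonical for this design; Blom
  is the common default and the choice is exposed as a parameter.
* **Ties → average ranks.** Zero-inflated traits produce heavy ties at the
  detection limit; average ranks keep the transform deterministic. Random
  tie-breaking was rejected because it would make reruns non-reproducible.
* **Missingness.** Rows missing the trait or any covariate are dropped from
  fitting and stay missing in the output; both RNTs are fit on complete
  cases. Traits with more than `missing_threshold` (default 90 %) missing
  are excluded outright with a recorded reason.
* Exposure standardization is (x − mean)/SD over non-missing rows, so
  step-1 effects read as normalized SD units per SD of exposure.

### One-sample MR

The instrument is a weighted genetic risk score over the exposure's
instrument SNPs (default 97), with published per-allele weights; missing
dosages are imputed as 2×EAF. A rescaled score (×n_snps/Σw) is provided so
"one unit" means one average effect allele. The causal effect is estimated
by two-stage least squares. The coefficient standard error is the classical
IV variance: stage-2 coefficients combined with residuals computed using the
*observed* exposure. The first-stage partial F for the instrument block is
reported as the weak-instrument diagnostic.

Endogeneity is tested with the Durbin score statistic in its
control-function form: first-stage residuals v̂ join the outcome-side
regressors, and n·R² from the auxiliary regression of the OLS residuals on
[1, x, C, v̂] is referred to χ²₁. This form was chosen because it is
well-defined at small n and agrees asymptotically with the t-test on the v̂
coefficient; it is oracle-tested against an explicit projection-matrix
computation.

Cohorts are combined by inverse-variance meta-analysis. The observational
(step-1a) pooling is fixed-effect. The MR (step-1b) pooling defaults to
DerSimonian–Laird random effects — the convention of general-purpose
meta-analysis tooling — with the fixed-effect result always reported
alongside, because the two conventions genuinely differ here and the choice
of gate model matters (see the worked example in the README). τ² is the DL
moment estimator truncated at zero, so homogeneous inputs reproduce the
fixed model exactly.

Mediators with meta-analyzed MR P < 0.001 pass to step 2 (0.05/41 ≈ 0.001,
a Bonferroni-style penalty for the panel size). Mediators with suggestive
evidence (P < 0.05) are re-run on the ln(x+1) scale, adjusting for age and
sex only, so that exp(β) is a ratio of geometric means of (value+1) per SD
of exposure. The +1 shift accommodates exact zeros; its effect on the
geometric-mean interpretation is a documented approximation.

### Two-sample MR

Instrument selection runs in the order: genome-wide threshold (P < 5×10⁻⁸)
→ cross-match to the outcome table with proxy substitution → greedy LD
clumping → allele harmonization.

* **Proxies.** An instrument absent from the outcome data may be replaced by
  the available SNP in highest LD above r² = 0.8 (ties broken by SNP id).
  The proxy's own exposure-table record substitutes for the original — the
  proxy is harmonized directly against the exposure table and the
  substitution is logged with its r².
* **Clumping.** SNPs sorted by ascending p (ties by id); accept a SNP iff
  its r² with every accepted SNP is below 0.01. LD pairs absent from the
  reference map are treated as independent and counted in the provenance.
* **Harmonization.** Swapped alleles flip the outcome beta and complement
  its EAF; strand flips resolve by complementing. Palindromic (A/T, C/G)
  SNPs are oriented by EAF concordance and dropped when either EAF is
  missing or falls in [0.42, 0.58] — the conventional two-sample default,
  configurable. Downstream estimates are invariant to relabelling the
  outcome records (tested to 1e-12).
* A fixed user-supplied instrument list (e.g. a cis set for an acute-phase
  protein) bypasses the p-value gate.

Per-SNP Wald ratios β_gy/β_gx are pooled by fixed-effect IVW
(se = (Σ 1/se_w²)^(-1/2); residual scale fixed at 1). A multiplicative
random-effect variant (SE inflated by √max(1, Q/df)) is available by flag.
Cochran's Q with df = k−1 accompanies every pooled estimate. Outcome GWAS
below `min_outcome_n` (default 50,000) are excluded with a recorded reason.
No multiplicity penalty is applied in step 2.

The Wald ratio SE is first-order delta only (|se_gy/β_gx|): the
SNP-exposure uncertainty is omitted. This understates the variance when
instruments are weak on the exposure side; with the default design
(per-SNP F ≈ 30–100) the effect is negligible, and it is the standard
convention the IVW weights assume.

### Power

Power for a continuous-outcome MR test uses the non-centrality
approximation z = β·√(n·r²_gx): power = Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂).
`detectable_effect` inverts it numerically (Brent). At n = 8,000 and
r²_gx = 0.027 — the approximate variance a ~97-SNP adiposity score explains
— 80 % power at α = 0.05 corresponds to a detectable effect of ≈ 0.19 SD.
Binary-outcome power with a case-control ratio is not implemented.

## The synthetic-study generator

The generator emulates the study conditions end to end; its defaults are
the design's stated conditions, not tuning knobs.

**Genotypes.** Hard-call dosages are sums of two Hardy–Weinberg allele
draws. Within an LD block, the latent Gaussians behind the allele draws are
equicorrelated, with the latent correlation solved (bivariate-normal orthant
probability, Brent) so the realized dosage r² matches the requested target;
blocks share a MAF drawn from `maf_range` (default U(0.05, 0.5)) and are
mutually independent. This gives tunable LD without coalescent machinery.
The panel returns both the generative target and the realized within-block
r² map.

**Exposure.** X = √h²·G_std + c_U·U + ε, scaled to unit variance, with
G_std the standardized weighted allele score, U a standard-normal
confounder, and fixed small loadings (0.05) from age, sex and 10 PC-like
covariates. Reported BMI is 27 + 4.5·X kg/m² (cohort means ≈ 26–28, SD
≈ 4.5). Default h² = 0.027, consistent with the ≈ 0.19-SD detectable effect
at the pooled sample size and with first-stage F statistics in the tens
(median ≈ 58 at the default sizes, computed by the acceptance script).

**Mediators.** M_k = θ_k·X + d_U·U + g_k + ε_k on a unit-variance core,
with g_k an optional direct SNP contribution of variance share
`mediator_h2` from a separate mediator SNP panel (LD blocks; a configurable
fraction flagged pleiotropic). The observed value is exp(M_k) —
right-skewed by construction, since the real traits' distribution families
are unreported — then left-censored to exact zeros at the `zero_inflation`
quantile (default 10 %), emulating an assay detection limit, and masked
missing at `missing_fraction` (default 2 %). Censoring the *lowest* values,
rather than zeroing a random subset, matches how assay zeros arise and
preserves rank information. Confounder defaults c_U = 0.3, d_U = 0.5 give
an observational bias of c_U·d_U = 0.15 on the standardized scale.

**GRS weights.** Published weights are emulated by adding sampling noise at
an external-consortium size (n = 339,224) to the true per-allele effects on
the BMI scale.

**Two-sample structure.** `simulate_study` draws one genotype panel across
all individuals and splits it into the three cohorts (defaults 1,980 /
4,608 / 1,705) plus an optional disjoint outcome sample, honoring the
no-sample-overlap requirement. Disease status is drawn from
logit P = b₀ + λ·z(M_RNT) (+ direct per-SNP effects for pleiotropic
variants), with b₀ set from the case fraction (default 1/3, a 1:2
case-control ratio). The disease depends on the *normalized* mediator so
the log-odds scale matches the normalized-SD units of the exposure-side
summary statistics — the two-sample estimand then equals λ by construction.
Per-SNP summary statistics come from vectorized simple linear regressions
(mediator side) and vectorized Newton–Raphson single-SNP logistic
regressions (disease side), both cross-checked against statsmodels in the
test suite.

**Randomness.** Every generator is a pure function of its parameters and a
single integer seed; sub-streams derive from fixed spawn keys, so identical
parameters give byte-identical output (tested via SHA-256 of the full
report).

### What the generator does and does not emulate

It reproduces the causal structure the analysis assumes — exposure →
mediator → disease with shared confounding, LD-blocked instruments,
trans/pleiotropic variants, skewed zero-inflated mediators, split-sample
summary statistics — and the marginal scales of the real cohorts. It does
not emulate realistic allele-frequency spectra, imputation quality,
relatedness, population structure beyond PC covariates, assay batch
effects, or between-cohort heterogeneity in SNP-mediator effects (e.g.
anticoagulant artefacts). Passing tests therefore demonstrate correctness
and calibration of the *procedures* under the assumed model, not robustness
to those real-data complications.

## Problem sizes used in validation

The acceptance checks run at the design's cohort sizes (1,980/4,608/1,705;
pooled 8,293): 200 replicates for one-sample recovery (θ = 0.2 with
confounder path 0.5 × 0.2, chosen so the observational slope biases to
≈ 0.3), 500 replicates each for the Durbin–Wu–Hausman (n = 2,000, no
confounding), step-1 gate (θ = 0) and Cochran's Q (k = 10) calibrations,
and 200 replicates for two-sample null coverage (30 instruments,
mediator h² = 0.25, outcome n = 60,000, λ = ln 1.2 for the recovery arm).
The unit-test fixture uses smaller cohorts (300/400/250) with
exposure h² = 0.15 so the first-stage F matches the strong-instrument
regime of the full design.

## Numerical conventions and edge cases

* χ² and normal tail probabilities in double precision; p-values are never
  truncated. 2SLS p-values use the t distribution with stage-2 df.
* An instrument identical to the exposure is the exogenous limit: 2SLS
  returns the OLS slope (first-stage F reported as effectively infinite)
  and the Durbin statistic is 0 with p = 1.
* 2SLS requires n ≥ 30 and positive instrument variance; a first-stage
  F < 10⁻⁶ is a degenerate fit and raises. The Durbin test requires only
  enough residual df, so small hand-checkable fixtures are valid.
* Clumping and proxy ties break lexicographically by SNP id; clump output
  is invariant to input row order.
* `detectable_effect` rejects power requests outside (α, 1).
* Empty instrument sets, all-case/all-control disease draws, rank-deficient
  covariates (named columns), irreconcilable alleles (named SNPs) and
  overlapping two-sample splits all raise or record structured reasons
  rather than propagating silently.

## Known limitations

* The Wald SE omits the second-order (SNP-exposure) term, as noted above.
* One-sample 2SLS at modest first-stage F carries the usual finite-sample
  bias toward OLS (of order bias_OLS/F); at the default design it is ≪ the
  sampling error, and the first-stage F quantifies a realized instrument
  distribution whose far left tail (P < 10⁻³) can dip below 10.
* The DL random-effects model with three cohorts estimates τ² very noisily;
  both models are therefore always reported, and the gate model is
  configurable.
* Estimators for pleiotropy-robust analysis (MR-Egger, weighted median/
  mode) are deliberately out of scope: with few instruments per mediator
  they lack power, and the design relies on heterogeneity statistics
  instead.
* LD is block-equicorrelated; long-range LD and allele-frequency-dependent
  LD decay are not modelled.
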