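# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices that matter for reproducing its
behaviour.

## Generative model for GWAS summary statistics

Within each LD block with correlation matrix `R`, the observed z-scores of
trait *t* are

    z_t = sqrt(N_t) R beta_t + eps_t,     eps_t ~ N(0, R),

the standard polygenic model on standardized genotypes and phenotypes.
Overlapping samples induce a cross-trait noise correlation
`c = rho_e * n_overlap / sqrt(N1 N2)` (`rho_e` = phenotypic correlation in
the shared subsample), implemented exactly in the noise draw.  True
effects are i.i.d. within the causal set with per-SNV variance `h2/m`;
shared (pleiotropic) SNVs receive correlated effects with correlation
`rho_b = rg * sqrt(m1 m2) / n_shared`, which realizes the requested
genome-wide genetic correlation in expectation (an unattainable
combination raises).  `effect_dist="fixed"` (equal magnitudes, random
signs) and `causal_placement="spread"` exist for experiments that need
every planted hit individually detectable; `shared_blocks` confines the
shared causal SNVs to chosen blocks to plant local-only covariance.

LD blocks are AR(1) with parameter `ld_decay`, scaled per block by a fixed
heterogeneity cycle (1, 0, 2/3, 1/3).  Real genomes mix tight and loose LD
neighbourhoods; the cycle gives the LD scores enough spread to identify
the LD-score-regression intercept separately from its slope, which a
homogeneous panel cannot.  Blocks are laid out in ascending (chromosome,
position) order, 5 kb between SNVs, so coordinate windows behave like real
ones while blocks stay exchangeable.

What the generator does **not** emulate: real LD maps, minor-allele-
frequency/LD-dependent architectures, imputation noise, relatedness and
ancestry structure.  Passing recovery tests therefore demonstrate
correctness of the estimators under the polygenic model, not robustness to
those real-data complications.

Default sample sizes follow the source GWASs (417,580 exposure / 426,824
outcome); most simulation experiments run at N = 20,000–100,000 with
M = 5,000 SNVs, chosen so the signal-per-SNV regime (mean chi-square
1.1–3) matches what genome-scale LDSC sees, which is also the regime where
the intercept is identifiable.

## LD-score regression

`chi2_j` is regressed on `N * l_j / M` (bivariate: `z1 z2` on
`sqrt(N1 N2) l_j / M`) with a free intercept and weights `1/max(l_j, 1)` —
a single-step simplification of the two-step heteroskedasticity weighting
of genome-scale tools, adequate at simulation scale and documented here
for users.  Standard errors come from a 200-block delete-one jackknife;
r_g re-estimates the full ratio `gencov / sqrt(h2_1 h2_2)` in every
jackknife replicate.  The bivariate intercept estimates the sample-overlap
term `c` and is exposed for downstream overlap-aware procedures.

## Local genetic covariance scan

Per region the local LD matrix is eigendecomposed, the leading K
components covering ≥ 90% of the trace retained (`var_kept`), and both
traits' z-scores projected to whitened coordinates
`w_t = Lambda_K^{-1/2} U_K' z_t`.  `w1'w2 - K c` estimates
`sqrt(N1 N2)` times the local genetic covariance.  Under the polygenic
null (both traits locally heritable but uncorrelated) the components are
marginally normal with variances `v_tk = 1 + N_t lambda_k h2_t / M`, so
the statistic is a weighted sum of products of correlated normals; its
exact null law is a weighted chi-square difference, and p-values use the
Lugannani–Rice saddlepoint, accurate at Bonferroni-level tails where the
CLT fails.  The 90% truncation discards directions where whitening would
amplify noise, at the cost of capturing slightly less than all of the
regional signal.

Calibration is exact under Gaussian (infinitesimal) effects.  Under
sparse architectures (few causal SNVs per region) regional signal energies
fluctuate beyond the Gaussian model and the p-values become heavy-tailed —
a known limitation shared by moment-based local-covariance estimators; the
null-calibration tests therefore run the infinitesimal architecture, and
the planted-signal tests the sparse one.

## Two-sample MR

IVW defaults to multiplicative random effects (fixed-effect SE inflated by
`sqrt(max(1, Q/(n-1)))`): with ~143 heterogeneous instruments a pure
fixed-effect analysis is anti-conservative.  MR-Egger is weighted least
squares with a free intercept on instruments oriented exposure-positive
(the convention under which the InSIDE assumption is stated); its SEs use
a t reference with an overdispersion factor floored at 1.  The weighted
median interpolates the ratio at cumulative weight one half with weights
`bx^2/se_y^2`, SE by seeded parametric bootstrap (default 1,000 draws).
The PRESSO-style global test simulates the leave-one-out residual sum of
squares under the fitted no-pleiotropy model (default 5,000 draws — large
enough that the per-instrument Bonferroni threshold 0.05/n_iv stays above
the Monte-Carlo floor); flagged outliers are removed and IVW re-fit.
Steiger filtering removes instruments whose outcome variance explained
exceeds the exposure's with Fisher-z p < 0.05.  Multivariable IVW is
no-intercept WLS on the exposure-beta matrix; all-zero exposure columns
are dropped with a warning (their estimate is undefined) rather than
failing the joint fit.

## One-sample MR

The instrument is the unweighted count of exposure-increasing alleles:
with the GWAS and the cohort overlapping, externally weighted scores would
re-use the same data twice, so allele counting is the defensible choice.
The Wald ratio divides the covariate-adjusted reduced-form coefficient by
the covariate-adjusted first stage; by Frisch–Waugh–Lovell this equals
2SLS with the score as single instrument (verified to machine precision in
tests).  Its SE is the first-order delta method without the
numerator–denominator covariance term; with first-stage F in the hundreds
the omitted term is negligible.  A first-stage |t| below 1 raises a
weak-instrument error.

Subgroups: sex, age band (default <65 / ≥65, closed lower bound — a person
aged exactly 65 belongs to the older band), and menopause within females;
the stratification covariate is dropped from the adjustment set.
Nonlinear MR stratifies on residual exposure — observed exposure minus the
mean-centred genetic contribution, operationalized as first-stage-slope ×
score (`mode="raw"` switches to the raw score) — with quantile cuts, ties
to the lower stratum and the remainder to the first.  Per-stratum Wald
ratios feed Cochran's Q (chi-square, strata−1 df) and a weighted
meta-regression of estimates on stratum mean exposure whose slope Wald
test is the nonlinearity p-value.  Stratum-specific first stages are the
default (a common-first-stage switch is the `residual_stratify` fitted
contribution reused across strata).

The cohort generator applies the causal dose-response to the
rank-inverse-normalized exposure, so planted slopes are on the analysis
scale; the single standard-normal confounder with loadings on both traits
makes naive OLS biased while IV estimation stays consistent.  Covariates
(age, sex, BMI, centre, month, supplement use, menopause, PCs) enter both
traits with small fixed loadings and stand in for the real adjustment set
as generic columns.

## Pleiotropy scan

Per SNV, `u = C^{-1/2} (z1, z2)` decorrelates the null (C from the LDSC
cross-intercept or from the truncation-corrected correlation of
null-region z-scores; the empirical mode inverts both the per-trait
variance inflation and the box-truncation attenuation of a bivariate
normal, exactly under the null model).  The statistic is the LRT of
`tau^2 = 0` in `u ~ N(0, I + tau^2 Omega~)` with `Omega~` the decorrelated
unit-trace genetic covariance — power is aimed along the genetic direction.
With one bivariate observation per SNV the asymptotic 50:50
chi2(0)/chi2(1) mixture is only a rough reference (the true mass at zero
depends on `Omega~`), so p-values are computed against seeded Monte-Carlo
draws of the statistic under the null — one shared draw set per scan, the
null law being SNV-independent — with the analytic mixture as the far-tail
extension beyond the draws (default 10^6 draws; the mixture is mildly
conservative near the boundary, which at genome-wide thresholds is the
safe direction).  The profile maximization runs on a log-spaced tau grid
with parabolic refinement (array path) or Brent (scalar path); the two
agree to 1e-4 and the scalar path matches a brute-force grid to 1e-6.
The GLS omnibus `z' C^{-1} z` (2 df) is provided as a documented
cross-check mode.

Index SNVs come from greedy PLINK-style clumping of the pleiotropy
p-values (p1 5e-8, p2 1e-5, r² 0.2, ±500 kb; ties by ascending
chromosome/position; windows closed ± intervals).  Significance requires
the index to pass P_pleio < 5e-8 with both single-trait P < 1e-5; novelty
additionally requires (1) neither trait alone genome-wide significant,
(2) no LD r² ≥ 0.2 with a supplied known-hit list, (3) no genome-wide
significant single-trait neighbour within ±500 kb.  Known-hit catalogs
are plain SNV-id lists — no live database access.

## Fine-mapping and colocalization

Per-variant evidence is the Wakefield approximate Bayes factor
`log ABF = 0.5 (log(1-r) + r z^2)`, `r = w^2/(w^2+se^2)`, which for the
normal-normal model is the exact marginal likelihood ratio (quadrature-
verified).  The effect-prior SD defaults to 0.15 for quantitative traits.
Fine-mapping assumes one causal variant per locus with equal priors
("flat prior"); the 99% credible set is the minimal posterior-descending
prefix (ties broken by ascending position).  Colocalization accumulates
the five hypothesis evidences in log space by log-sum-exp (the H3 term
subtracts same-variant pairs via a stable log-diff) with priors
p1 = p2 = 1e-4, p12 = 1e-5 — the cited framework's documented defaults —
and flags PPH4 > 0.75 (strict).  Locus windows are ±500 kb closed
intervals around the index position.

## Harmonization and clumping conventions

Coordinates are 1-based; clump windows are ± kb closed intervals.
Outcome effects are re-signed when alleles are swapped, strand flips
(A↔T/C↔G complement) are attempted before exclusion, palindromic SNVs are
kept only when `min(EAF, 1-EAF) < 0.42` in both studies (orientation then
fixed by frequency agreement) and excluded as ambiguous otherwise — the
source GWASs are EAF-annotated, which is what makes the frequency rule
usable; every exclusion is recorded with a reason.  Unknown-LD pairs are
treated as r² = 0 with a warning (fail-open with an audit trail).
Instrument selection is the same greedy clump with p2 = p1, a 10-Mb
window and r² < 0.01 at p < 5e-8.

## Pipeline

`crosstrait run-all` executes simulate → harmonize → LDSC → local scan →
two-sample MR → one-sample MR → pleiotropy scan → fine-mapping → coloc →
report; every stage derives its seed from the master seed plus the stage
name, and the JSON manifest records content digests of each output, so
identical configurations reproduce identical tables.

## Problem sizes

Simulation experiments default to M = 5,000 SNVs (100 blocks × 50),
N = 20,000–100,000 per GWAS, cohorts of 10,000–40,000, 200,000 Monte-Carlo
null draws per scan, and 20–1,000 replicates per calibration experiment —
sizes at which every estimator's sampling error is small against the
tolerances being checked while a full run stays interactive.

## Known limitations

- The local scan's null assumes Gaussian effect sizes; sparse
  architectures give heavy-tailed region statistics (see above).
- The empirical null-correlation mode assumes the post-truncation sample
  is bivariate normal; strong per-SNV signal heterogeneity biases it, and
  the LDSC-intercept mode is preferred when the intercept is identifiable.
- The Wald-ratio SE omits the numerator–denominator covariance.
- Single-causal-variant fine-mapping only; no multi-signal (SuSiE-style)
  extension, no eQTL colocalization, no annotation-stratified LDSC, no
  binary-outcome MR.
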