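# Methods

This note records the statistical model mrkit implements, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Setting and assumptions

mrkit performs two-sample Mendelian randomization on summary statistics:
per-variant exposure associations $(\hat\beta_{Xj}, \sigma_{Xj})$ and
outcome associations $(\hat\beta_{Yj}, \sigma_{Yj})$ estimated in
non-overlapping samples, for J variants assumed mutually independent
(LD-pruned upstream — mrkit performs no clumping). The instrumental-variable
assumptions are the usual three: each variant is (i) associated with the
exposure, (ii) independent of exposure–outcome confounders, and (iii)
affects the outcome only through the exposure. The estimators relax (iii)
to different degrees; none relaxes (i) or (ii). Effects are treated as
linear and homogeneous; exposure and outcome are on SD scales, and odds
ratios reported alongside are exp(beta) per SD of exposure.

## Harmonization

Outcome effects are re-expressed per copy of the exposure's effect allele.
Non-palindromic variants are matched exactly, by allele swap (negate beta,
complement frequency), by strand complement, or by both; anything else is
an irreconcilable allele pair and is excluded. For palindromic variants
(A/T, C/G) the strand cannot be read off the labels, so alignment uses
allele-frequency agreement alone: orientations are matched when the
exposure and outcome effect-allele frequencies fall on the same side of
0.5, and the variant is excluded as ambiguous when either frequency lies
inside (0.5 − w, 0.5 + w) or is missing. The window half-width defaults to
w = 0.08 — the conventional choice in two-sample MR practice — and is
exposed as a parameter. Joins are by rsID; duplicate IDs keep the first
record; every exclusion carries a reason code
(`not_in_outcome`, `palindromic_ambiguous`, `allele_mismatch`,
`weak_instrument`, `confounder_associated`) so that the instrument count
always reconciles: retained + excluded = presented.

Confounder screening is deliberately file-based: the user supplies a list
of rsIDs to exclude (e.g. from a phenome-wide lookup done elsewhere);
mrkit performs no web queries.

## Instrument strength

$F_j = (\hat\beta_{Xj}/\sigma_{Xj})^2$, the large-sample identity for a
single-SNP regression F-statistic. Variance explained uses the regression
anatomy $R_j^2 = F_j/(F_j + n - 2)$, which needs only the exposure sample
size; a frequency-based alternative $2\,\mathrm{MAF}(1-\mathrm{MAF})\beta^2$
(valid for a unit-variance trait) is selectable when n is unreliable.
Aggregate $R^2$ is the plain sum over retained instruments, valid under
the independence assumption. The weak-instrument screen removes F < 10 by
default.

## Estimators

* **IVW** is weighted least squares of $\hat\beta_Y$ on $\hat\beta_X$
  through the origin with weights $\sigma_Y^{-2}$ — algebraically the
  inverse-variance-weighted mean of the Wald ratios with weights
  $\hat\beta_X^2/\sigma_Y^2$. Cochran's Q uses those same ratio-scale
  weights, with J − 1 df. The random-effects variant (the primary
  analysis) multiplies the fixed-effect SE by $\max(1, \sqrt{Q/(J-1)})$:
  a multiplicative-overdispersion model that never reports less
  uncertainty than fixed effects. P-values are standard normal.
* **MR-Egger** adds an unconstrained intercept to the same weighted
  regression after orienting every instrument to $\hat\beta_X \ge 0$
  (instruments with $\hat\beta_X = 0$ carry no orientation and are
  dropped with a log line). Both SEs carry the residual scale
  $\max(1, \sqrt{RSS_w/(J-2)})$ and p-values use t with J − 2 df — the
  small-sample convention for a fitted two-parameter regression. Whether
  to allow under-dispersion is debatable; clamping at 1 was chosen for
  symmetry with the IVW treatment and is the conservative option.
* **Weighted median**: Wald ratios sorted ascending, normalized weights
  $w'_j$, cumulative midpoints $s_j = \sum_{k\le j} w'_k - w'_j/2$, linear
  interpolation of ratio against $s$ at 0.5 (clamped to the extreme ratios
  when 0.5 falls outside the midpoint range). Its SE is a parametric
  bootstrap: redraw both betas from their sampling normals, recompute,
  take the SD over n_boot = 1,000 seeded draws.
* **Leave-one-out** re-runs random-effects IVW J times, dropping one
  instrument each time, in input order.

## MR-PRESSO

Implemented from the published description as a re-derivation, not a port.
For each instrument the expected outcome effect is $\hat\theta_{-j}
\hat\beta_{Xj}$ with $\hat\theta_{-j}$ the leave-one-out IVW slope; the
observed residual is weighted by $\sigma_{Yj}^{-2}$ (the residual is in
outcome-beta units, so the outcome variance is the dimensionally correct
weight). The null distribution comes from n_sim parametric replicates that
redraw both sides ($\beta^*_{Xj} \sim N(\hat\beta_{Xj}, \sigma_{Xj})$,
$\beta^*_{Yj} \sim N(\hat\theta_{-j}\hat\beta_{Xj}, \sigma_{Yj})$) and
recompute the statistic in full, leave-one-out slopes included. P-values
use the add-one estimator (never exactly zero); per-instrument p-values
are Bonferroni-adjusted by J and flagged below alpha = 0.05.

Resolution caveat: the smallest attainable adjusted p is J/(n_sim + 1),
so the conventional default n_sim = 1,000 cannot flag anything once J ≥ 50 at
alpha = 0.05. The function warns in exactly that regime; analyses with
~50–100 instruments should use n_sim ≥ 5,000, which is what the tests and
examples do.

The outlier-corrected estimate is random-effects IVW on the unflagged
instruments. The distortion coefficient is
$D = 100(\hat\theta_{corr} - \hat\theta_{orig})/|\hat\theta_{orig}|$; its
null distribution removes 1,000 random subsets of the same size, and the
reported p is the two-sided tail proportion $\Pr(|D_{null}| \ge |D|)$
(a plain proportion — it can legitimately reach 1.0). With no outliers the
corrected estimate equals the original and the distortion p is
not-applicable (NaN/NA).

## Analytic power

For a continuous outcome of sample size n and instruments explaining a
fraction $R^2$ of exposure variance, the IVW sampling variance is
approximately $1/(nR^2)$, giving power
$\Phi(|\theta|\sqrt{nR^2} - z_{1-\alpha/2})$ for a two-sided level-alpha
test. This closed form agrees with the empirical rejection rate of the
full pipeline on generated data to within sampling error (checked at the
proteomics-scale scenario: analytic 99.0%/94.0% at OR 0.80/1.20 versus
simulated rejection over 1,000 replicates, within ±3 points). Odds-ratio
inputs enter as ln(OR); display rounds to whole percent, full precision is
kept internally.

## Synthetic generator

One scenario draws, per variant: MAF ~ Uniform(0.05, 0.5); a half-normal
exposure effect rescaled so aggregate variance explained is exactly
`r2_target`; standard errors from the unit-variance anatomy
$\sigma = (2\,\mathrm{MAF}(1-\mathrm{MAF})\,n)^{-1/2}$; independent
exposure/outcome noise (non-overlapping samples); optional direct effects
$\alpha_j \sim N(\mu_\alpha, \sigma_\alpha)$ and gross outliers of
magnitude `outlier_scale` outcome-SEs. Effects are reported for the
exposure-increasing allele — the convention of published instrument lists —
which is what makes "directional" pleiotropy directional relative to the
orientation MR-Egger uses. Allele pairs are random, with configurable
fractions palindromic, swapped and strand-recoded in the outcome file to
exercise harmonization end to end. All randomness flows from one seed
through named per-quantity child streams (one draw per SNP, in index
order), so enlarging a scenario appends draws without reshuffling earlier
ones, and identical seeds give byte-identical files.

Default scenario constants mirror the urate → telomere-length study design:
101 instruments, exposure n = 288,649, outcome n = 472,174, aggregate
R² = 10.21%, θ = −0.040 ("ltl-like"); the "interval-protein-like" preset
uses n = 3,301, J = 113, R² = 11.24% and θ = ln 0.8, the effect size that
design is powered for.

What the generator does **not** emulate: LD between instruments, sample
overlap, winner's-curse selection of instruments, allele-frequency
differences between the two studies, non-linear or heterogeneous effects,
and binary outcomes. Passing calibration on generated data therefore shows
the estimators are correctly implemented and calibrated under the stated
model, not that real-data violations of that model are handled.

## Numerical and interface decisions

* P-values of exactly 0 on input are floored to the smallest positive
  double with a warning; rows violating hard invariants (se ≤ 0, invalid
  alleles, p ∉ [0,1], eaf ∉ [0,1]) are dropped and counted, never repaired.
* The results table carries both a display column (`OR_95CI`, 2 d.p.,
  matching the conventional "0.96 (0.95, 0.97)" layout) and full-precision
  numeric columns, so the file is simultaneously human-readable and
  round-trippable to 1e-12.
* The 95% CI critical value is 1.959964 and configurable; reports never
  silently filter on significance.
* Variants are keyed by rsID only; chromosome/position columns are ignored
  for joining, avoiding genome-build coordination.
* The library API is the primary surface; the `mrkit` CLI and the
  `examples/` scripts are thin wrappers over the same functions, and the
  pipeline writes a manifest (versions, seed, config hash) for
  reproducibility. Re-running with the same configuration and seed is
  bit-identical.

## Problem sizes used in the test suite

Calibration checks run at the scale the statistics need, chosen as the
package's own test design: 1,000 replicates for CI coverage (bounds
0.93–0.97), Egger intercept type-I error (0.03–0.07) and empirical-vs-
analytic power (±3 points); 200 replicates for MR-PRESSO injection
recovery (≥95% flagging of a 10-SE outlier among 51 instruments at
n_sim = 5,000) and null flag rate (≤5%). Estimator/oracle identities are
checked to 1e-10 against statsmodels WLS fits and brute-force
re-implementations.

## Known limitations

* No LD-proxy lookup for instruments missing from the outcome (dropped,
  as logged); no clumping, Steiger filtering, multivariable MR, or
  mode-based estimators.
* MR-Egger's consistency argument needs strong instruments: with weak
  ones, orienting by the *observed* exposure-beta sign attenuates the
  slope (visible in the generator when per-SNP F is small). mrkit screens
  at F ≥ 10 but does not otherwise correct for this.
* Wald-ratio SEs are first-order (no exposure-side term), standard for
  strong instruments.
* Binary-outcome power and sample-size inversion are out of scope.
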