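# Methods

## Problem and estimand

The package studies average-treatment-effect (ATE) estimation by
propensity-score weighting when the covariate pool contains, besides true
confounders, *instrumental variables* (IVs: predictors of treatment only)
and spurious covariates. Including IVs in a propensity model adds no
confounding control but widens the propensity distribution toward 0 and 1,
inflating inverse-probability weights and — when covariates are correlated —
amplifying any residual bias. Three strategies for keeping IVs out of the
weights are compared around a common estimator: the outcome-adaptive lasso
(OAL), stable balancing weights (SBW), and stable confounder selection
(SCS).

All methods feed into the augmented inverse-probability-of-treatment
weighting (AIPTW) estimator

    tau_hat = (1/n) * sum_i [ (2Z_i - 1) W_i (Y_i - m_{Z_i}(X_i))
                              + m_1(X_i) - m_0(X_i) ],

with W_i = Z_i/e(X_i) + (1-Z_i)/(1-e(X_i)) and outcome-model predictions
m_z. AIPTW is doubly robust: consistent if either the propensity model or
the outcome model is correct, which is what licenses data-adaptive covariate
selection. The variance is estimated by the sample variance of the per-unit
influence contributions psi_i = (2Z_i-1) W_i (Y_i - m_{Z_i}) + m_1 - m_0 -
tau_hat, giving se = SD(psi)/sqrt(n) (ddof = 1) and Wald 95% intervals
tau_hat ± 1.959964·se.

## Synthetic data-generating process

One scenario is parameterized by sample size n, covariate count J ≥ 6,
equicorrelation rho ∈ [0,1), IV strength theta, and effect type:

* X ~ N_J(0, Sigma), Sigma with unit variances and all correlations rho
  (drawn exactly via the one-factor representation).
* logit P(Z=1|X) = 0.5·X1 + 0.5·X2 + theta·X5 + theta·X6.
* Y = tau·Z + X1 + X2 + X3 + X4 + eps, eps ~ N(0, 2²), tau = 1; under
  heterogeneous effects tau·Z is replaced by (1 + X1 + X2)·Z, which keeps
  the ATE at 1 because E[1 + X1 + X2] = 1.

So X1, X2 are confounders, X3, X4 outcome-only predictors, X5, X6
instruments, and the remaining J−6 covariates noise. Defaults (n = 500,
J = 20, rho = 0, theta = 0.5, sigma_eps = 2) are the study's core cell;
the full factorial design is n ∈ {500, 2000} × J ∈ {20, 40} ×
rho ∈ {0, 0.5} × theta ∈ {0.5, 1} × both effect types (32 scenarios).
theta = 0.5 and 1 mark "moderate" and "strong" instruments: with J = 20 the
fraction of true propensities outside [0.1, 0.9] grows from ≈ 0.03
(rho = 0, theta = 0.5) to ≈ 0.37 (rho = 0.5, theta = 1). The fraction uses
strict inequalities, so boundary values count as non-extreme.

Each dataset uses one master seed split (via `numpy.random.SeedSequence`)
into independent sub-streams for covariates, treatment, and noise, so any
component can be regenerated in isolation and the whole draw is
reproducible bit-for-bit.

What the generator does *not* emulate: non-Gaussian or discrete covariates,
nonlinear treatment or outcome links, binary outcomes, measurement error,
or missingness. Passing the Monte Carlo checks therefore demonstrates
correctness of the estimators under this linear-Gaussian design, not
performance on real observational data.

## Estimator variants

* **Target** — logistic propensity + OLS outcome model on X1–X4 (the
  benchmark; its MSE is the denominator of relative MSE).
* **Confounders** — X1–X6 (adds the instruments).
* **AllCovariates** — everything, including noise.
* **OAL / SCS / SBW** — data-adaptive, below.

Every model-based variant uses the same covariates in its outcome model as
in its propensity model. The outcome model is one joint OLS with main
effects of Z and the covariates (not arm-specific fits); arm-specific fits
would be a one-line change but the joint fit is the default throughout.
Fitted propensities are clipped to [1e-6, 1-1e-6] before inversion — the
clip only matters for degenerate fits (separation) and leaves the study's
scenarios untouched. Plain logistic fits use iteratively reweighted least
squares (tolerance 1e-8 on the step, max 100 iterations); non-convergence
is flagged with a warning rather than raised, since a clipped degenerate
fit is still a usable weight source.

## Outcome-adaptive lasso

The propensity coefficients maximize the sum-scale penalized log-likelihood
with per-covariate penalty factors omega_j = min(|alpha_tilde_j|^(-gamma),
1e8), where alpha_tilde are the covariate coefficients of an OLS of Y on
(1, Z, standardized X), computed once. The cap 1e8 both avoids infinite
penalties at alpha_tilde_j = 0 and is treated as "effectively infinite":
capped covariates are fixed at exactly zero.

lambda ranges over n^c, c ∈ {−10, −5, −2, −1, −0.75, −0.5, −0.25, 0.25,
0.49}; gamma is tied to lambda by lambda·n^(gamma/2−1) = n², i.e.
gamma = 2(3 − ln lambda / ln n). The fit is by IRLS with inner
coordinate-descent soft-thresholding (glmnet-style), intercept unpenalized,
run on standardized covariates. lambda is selected by the weighted absolute
mean difference (wAMD): sum_j |alpha_tilde_j| · |Hajek-weighted treated
mean − Hajek-weighted control mean| of standardized X_j, with ties broken
toward the smaller lambda (less shrinkage). wAMD uses standardized
covariates so that the |alpha_tilde| weights and the mean differences share
a scale. The final propensities are the penalized fit itself (no
unpenalized refit), and the OAL outcome model uses the covariates with
nonzero penalized coefficients.

## Stable balancing weights

Per group (control shown; treated analogous):

    min sum_i (w_i - wbar)^2  s.t.  |sum_i w_i B_k(X_i) - mean_n B_k| <= delta_k,
                                    sum_i w_i = 1,  w_i >= 0.

Balance functions default to the raw covariates (K = J); richer sets
(squares, interactions) can be supplied through `BalanceSpec`. Since the
weights sum to one, minimizing their variance equals minimizing
sum w_i², a strictly convex QP. It is solved through its Lagrangian dual —
dimension 2K+1 regardless of group size — by L-BFGS-B with an LP (HiGHS)
feasibility pre-check; the primal is recovered as w = max(0, mu − B·lambda),
renormalized, and accepted only if every constraint holds within a 1e-6
standardized slack. Infeasibility is a status, not an exception, so the
delta search can skip over it.

delta_k = delta · S_k^z with S_k^z the unweighted within-group SD, and the
common multiplier delta is chosen from {0.0001, 0.001, 0.002, 0.005, 0.01,
0.02, 0.05, 0.1} by bootstrap: weights are solved once on the original
sample; each of B resamples (default 200) draws n units with replacement,
carries their original weights renormalized within group, and contributes
the sum over k of standardized absolute distances of both groups' weighted
means from the original overall means; the delta minimizing the bootstrap
average wins (ties toward the smaller delta). Resample draws are shared
across the delta candidates, which removes between-delta bootstrap noise
from the comparison. A variant that re-solves the QP on every resample is
available (`resolve_per_bootstrap=True`); it favors tighter tolerances but
is markedly slower, and the carried-weights reading is the default. For
estimation, the within-group weights are rescaled by n to the
inverse-probability scale expected by the AIPTW sum, and the SBW outcome
model uses all covariates.

## Stable confounder selection

Covariates are ordered by min(|z|, |t|): the absolute Wald statistic in the
full logistic propensity model versus the absolute t-statistic in the full
OLS outcome model. The minimum prioritizes dual-association confounders
and demotes instruments (null t) and outcome-only predictors (null z); ties
break by the larger of the two statistics, then by index. AIPTW is run on
every nested top-k set, and stability is assessed against the
inverse-variance-weighted moving average over windows of five consecutive
estimates, MA_k = sum_{m=k..k+4} tau_m/se_m² / sum 1/se_m² (zero SEs are
weight-capped at 1e12; failed fits drop out of their windows). The
selected size is the smallest k minimizing |tau_k − MA_k| over the defined
windows. This specific stability criterion is one defensible reading of
"smallest set with the most stable estimate" and is isolated in
`select_stable` so alternatives can be swapped in; different readings move
how often small versus large sets win, and with them the severity of the
method's post-selection coverage deficit. The reported SE is the naive
influence-function SE at the selected set — deliberately no selection-aware
correction, which is exactly why coverage can fall below nominal when
selection is unstable.

## Monte Carlo harness and metrics

Per scenario, replicate r uses dataset seed base_seed + r; all requested
variants see the same dataset. Per method: bias = |mean error| (signed bias
retained), MSE about the true ATE of 1, EmpSE = across-replicate SD
(ddof=1), AvgSE = mean model SE, CovRate = fraction of 95% intervals
covering 1, R-MSE = MSE / MSE(Target). Monte Carlo uncertainty: EmpSE/√R
for bias, SD(squared errors)/√R for MSE, sqrt(p(1−p)/R) for CovRate.
Method failures are excluded from that method's metrics and counted, never
imputed.

The reproduction script (`scripts/acceptance.py`) runs the overlap cells on
single n = 10 000 draws and the performance cells at n = 500 with 500
replicates for the cheap logistic/OLS variants, 200 replicates with 50
bootstrap resamples for the SBW cells, 200 replicates for the SCS cell, and
150 replicates for the heterogeneous-effect SBW cell — problem sizes chosen
to keep the full recomputation in the minutes range while holding the
Monte Carlo SE of each reported quantity well below its comparison
tolerance. At these scales ratio quantities (R-MSE) still carry visible
replication noise (roughly ±0.1); the harness accepts any replicate count
when more precision is wanted.

## Numerical choices

* Propensity clipping 1e-6; IRLS tolerance 1e-8, max 100 iterations.
* Penalized-lasso coordinate descent: tolerance 1e-8 on coefficient steps,
  outer IRLS capped at 200 passes; capped-penalty covariates excluded
  exactly.
* QP dual: L-BFGS-B (gtol 1e-10, ftol 1e-14, maxiter 5000), uniform-weight
  warm start; constraint acceptance slack 1e-6 (standardized) + 1e-9
  absolute.
* IVW moving-average weight cap 1e12 for zero SEs.
* Standardization uses ddof = 1 SDs.

## Known limitations

* The SCS stability criterion is a documented design choice (see above);
  results that depend on its fine structure — especially the size of the
  coverage deficit — vary across defensible readings.
* The SBW bootstrap tuning is the carried-weights reading; re-solving per
  resample systematically prefers tighter balance tolerances.
* Influence-function SEs ignore the variability of data-adaptive selection
  steps for OAL and SCS (by design, matching common practice).
* Binary outcomes are accepted by the estimator plumbing (the outcome model
  is a plug-in) but are not part of the simulated design or its checks.
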