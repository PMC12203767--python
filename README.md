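# ivweights

Propensity-score weighting for average treatment effects when the covariate
pool contains **instrumental variables** — covariates that predict treatment
but not outcome. Adjusting for instruments adds no confounding control, but
it pushes propensity scores toward 0 and 1, blows up inverse-probability
weights, and (with correlated covariates) amplifies bias. This package
implements and compares three strategies for keeping instruments and
spurious covariates out of the weights, all built around one doubly robust
estimator:

* **OAL** — the *outcome-adaptive lasso*: an L1-penalized logistic
  propensity model whose penalty factors ω̂ⱼ = |α̃ⱼ|^(−γ) come from the
  outcome regression, so covariates irrelevant to the outcome are shrunk to
  exactly zero; λ is tuned by the weighted absolute mean difference (wAMD).
* **SBW** — *stable balancing weights*: per-group minimum-variance weights
  from a quadratic program that balances covariate means toward the overall
  sample means within tolerances δ·Sₖᶻ, with δ chosen by a bootstrap
  criterion. No propensity model is fitted at all.
* **SCS** — *stable confounder selection*: covariates ranked by
  min(|z|-statistic in the propensity model, |t|-statistic in the outcome
  model), estimates computed along nested top-k sets, and the smallest set
  whose estimate agrees with a five-wide inverse-variance-weighted moving
  average selected.

Every method feeds the augmented inverse-probability-of-treatment-weighting
(AIPTW) estimator

τ̂ = n⁻¹ Σᵢ [ (2Zᵢ−1) Ŵᵢ (Yᵢ − m̂_{Zᵢ}(Xᵢ)) + m̂₁(Xᵢ) − m̂₀(Xᵢ) ],
  Ŵᵢ = Zᵢ/ê(Xᵢ) + (1−Zᵢ)/(1−ê(Xᵢ)),

with influence-function standard errors (sample SD of the per-unit
contributions over √n) and 95% Wald intervals. A synthetic data-generating
module reproduces the benchmark design — equicorrelated Gaussian
covariates with two confounders, two outcome-only predictors, two
instruments of strength θ, and J−6 noise covariates — and a Monte Carlo
harness tabulates bias, MSE, relative MSE versus the ideal-adjustment-set
benchmark, empirical and average model-based SEs, and coverage. See
`docs/methods.md` for the full model account.

Intended users: biostatisticians and epidemiologists studying covariate
selection for weighting estimators, and anyone needing a tested reference
implementation of OAL / SBW / SCS in Python.

## Worked example

```python
import ivweights as iw

cfg = iw.ScenarioConfig(n=500, J=20, rho=0.5, theta=1.0, seed=7)
data = iw.simulate_dataset(cfg)
print("extreme PS fraction:", round(iw.extreme_ps_fraction(data.true_ps), 3))

res = iw.run_replicate(cfg, ["Target", "AllCovariates", "OAL", "SCS", "SBW"],
                       sbw_spec=iw.BalanceSpec(n_bootstrap=50))
for m, est in res.items():
    print(f"{m:>13}: tau_hat = {est.tau_hat:6.3f}  se = {est.se:.3f}  "
          f"95% CI = ({est.ci_low:.3f}, {est.ci_high:.3f})")
```

prints

```
extreme PS fraction: 0.358
       Target: tau_hat =  0.899  se = 0.244  95% CI = (0.421, 1.376)
AllCovariates: tau_hat =  0.044  se = 0.895  95% CI = (-1.711, 1.799)
          OAL: tau_hat =  0.899  se = 0.243  95% CI = (0.423, 1.375)
          SCS: tau_hat =  0.042  se = 0.860  95% CI = (-1.643, 1.727)
          SBW: tau_hat =  0.762  se = 0.237  95% CI = (0.298, 1.226)
```

This is a hard draw: strong correlated instruments put 36% of the true
propensities outside [0.1, 0.9] (the true ATE is 1). Adjusting for all 20
covariates drags the estimate to 0.04 with a 3.5×-wider interval, while
OAL recovers the benchmark exactly (it selected X1–X4) and SBW stays close
with the tightest interval. Weighting diagnostics for any weight vector:

```python
ps = iw.fit_logistic_ps(data.X, data.Z)
w = iw.ipw_weights(ps.fitted_ps, data.Z).weights
print(iw.diagnostics_report(data.X, w, data.Z, fitted_ps=ps.fitted_ps).summary())
```

```
Weighting diagnostics
---------------------
group 0: ESS = 19.1, max normalized weight x100 = 20.71, max PSD = 0.313
group 1: ESS = 130.5, max normalized weight x100 = 4.51, max PSD = 0.232
fraction of propensity scores outside [0.1, 0.9]: 0.404
```

The unweighted control group has 169 units, but the fitted inverse
weights concentrate on a handful of them (effective sample size 19, one
unit carrying 21% of the weight) — the bias-amplification mechanism in one
line.

A full scenario table (here 200 replicates, three estimators):

```python
tab = iw.run_scenario(iw.ScenarioConfig(n=500, J=20, rho=0.5, theta=1.0),
                      n_reps=200, base_seed=11,
                      methods=["Target", "Confounders", "AllCovariates"])
```

The same is scriptable from the shell: `ivweights simulate`,
`ivweights run-scenario`, `ivweights full-grid --config grid.yaml`,
`ivweights diagnose`.

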