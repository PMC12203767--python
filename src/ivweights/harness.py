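"""Monte Carlo harness: run the estimator variants over replicated scenarios
and summarize bias, MSE, relative MSE, empirical and average model-based
standard errors, and confidence-interval coverage.

Six variants are compared on every simulated dataset:

* ``Target``        — logistic PS + OLS on the true confounders and outcome
  predictors (X1-X4); the benchmark whose MSE defines R-MSE = 1.
* ``Confounders``   — X1-X6, i.e. the target set plus the two instruments.
* ``AllCovariates`` — every covariate, including the spurious ones.
* ``OAL`` / ``SCS`` / ``SBW`` — the data-adaptive methods.

All variants share the dataset within a replicate, and the outcome model of
each model-based variant uses the same covariates as its propensity model.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dgp import ScenarioConfig, simulate_dataset
from .estimators import (
    EffectEstimate,
    aiptw_estimate,
    fit_logistic_ps,
    fit_outcome_model,
    ipw_weights,
)
from .oal import OALConfig, oal_estimate
from .sbw import BalanceSpec, sbw_estimate
from .scs import scs_estimate

__all__ = [
    "METHODS",
    "adjustment_set_for",
    "run_replicate",
    "performance_metrics",
    "run_scenario",
    "run_grid",
]

METHODS = ("Target", "Confounders", "AllCovariates", "OAL", "SCS", "SBW")

_FIXED_SETS = {
    "Target": lambda J: list(range(4)),
    "Confounders": lambda J: list(range(6)),
    "AllCovariates": lambda J: list(range(J)),
}


def adjustment_set_for(method: str, J: int) -> list[int] | None:
    """Fixed adjustment set (0-based) for the non-adaptive variants."""
    rule = _FIXED_SETS.get(method)
    return None if rule is None else rule(J)


def _model_based_estimate(X, Z, Y, subset: list[int], label: str) -> EffectEstimate:
    Xs = X[:, subset]
    ps = fit_logistic_ps(Xs, Z, adjustment_set=subset)
    m1, m0, _ = fit_outcome_model(Xs, Z, Y)
    return aiptw_estimate(
        Y, Z, ipw_weights(ps.fitted_ps, Z), m1, m0, method=label, adjustment_set=subset
    )


def run_replicate(
    config: ScenarioConfig,
    methods: Sequence[str] = METHODS,
    oal_config: OALConfig | None = None,
    sbw_spec: BalanceSpec | None = None,
) -> dict[str, EffectEstimate | None]:
    """Simulate one dataset and run the requested estimator variants on it.

    A method that fails (non-convergence, infeasibility) is recorded as
    None without aborting the replicate.  SBW's bootstrap seed is derived
    from the scenario seed so replicates are fully reproducible.
    """
    data = simulate_dataset(config)
    X, Z, Y = data.X, data.Z, data.Y
    results: dict[str, EffectEstimate | None] = {}
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if method in _FIXED_SETS:
                    results[method] = _model_based_estimate(
                        X, Z, Y, _FIXED_SETS[method](config.J), method
                    )
                elif method == "OAL":
                    results[method] = oal_estimate(X, Z, Y, oal_config)[0]
                elif method == "SCS":
                    results[method] = scs_estimate(X, Z, Y)[0]
                elif method == "SBW":
                    spec = sbw_spec or BalanceSpec()
                    spec = dataclasses.replace(spec, seed=config.seed + 1_000_003)
                    results[method] = sbw_estimate(X, Z, Y, spec)[0]
                else:
                    raise ValueError(f"unknown method {method!r}")
        except ValueError as exc:
            if "unknown method" in str(exc):
                raise
            results[method] = None
        except (RuntimeError, np.linalg.LinAlgError):
            results[method] = None
    return results


def performance_metrics(
    estimates: np.ndarray,
    ses: np.ndarray,
    ci_flags: np.ndarray,
    truth: float,
    target_mse: float | None = None,
) -> dict[str, float]:
    """Summarize one method's replicates.

    bias = |mean estimate - truth| (signed bias also reported); MSE about
    the truth; EmpSE = sample SD of estimates; AvgSE = mean model SE;
    CovRate = fraction of CIs covering the truth; R-MSE = MSE/target_mse.
    Monte Carlo SEs: EmpSE/sqrt(R) for bias, SD of squared errors/sqrt(R)
    for MSE, sqrt(p(1-p)/R) for CovRate.
    """
    tau = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    cover = np.asarray(ci_flags, float)
    ok = ~np.isnan(tau)
    tau, se, cover = tau[ok], se[ok], cover[ok]
    R = len(tau)
    if R < 2:
        raise ValueError("need at least 2 successful replicates")
    if target_mse is not None and target_mse <= 0:
        raise ValueError("target_mse must be positive")
    err = tau - truth
    emp_se = float(np.std(tau, ddof=1))
    mse = float(np.mean(err**2))
    p_cov = float(np.mean(cover))
    out = {
        "bias": float(abs(np.mean(err))),
        "bias_signed": float(np.mean(err)),
        "mse": mse,
        "emp_se": emp_se,
        "avg_se": float(np.mean(se)),
        "cov_rate": p_cov,
        "n_reps": R,
        "n_failed": int(np.sum(~ok)),
        "bias_mcse": emp_se / np.sqrt(R),
        "mse_mcse": float(np.std(err**2, ddof=1) / np.sqrt(R)),
        "cov_rate_mcse": float(np.sqrt(p_cov * (1 - p_cov) / R)),
    }
    if target_mse is not None:
        out["r_mse"] = mse / target_mse
    return out


def run_scenario(
    config: ScenarioConfig,
    n_reps: int = 500,
    base_seed: int = 0,
    methods: Sequence[str] = METHODS,
    oal_config: OALConfig | None = None,
    sbw_spec: BalanceSpec | None = None,
    keep_replicates: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run one scenario for n_reps replicates and tabulate the metrics.

    Replicate r uses dataset seed base_seed + r.  R-MSE is relative to
    Target when Target is among the methods.
    """
    methods = list(methods)
    records: dict[str, dict[str, list]] = {
        m: {"tau": [], "se": [], "cover": []} for m in methods
    }
    raw_rows = []
    for r in range(n_reps):
        cfg = dataclasses.replace(config, seed=base_seed + r)
        res = run_replicate(cfg, methods, oal_config=oal_config, sbw_spec=sbw_spec)
        for m in methods:
            est = res[m]
            if est is None:
                records[m]["tau"].append(np.nan)
                records[m]["se"].append(np.nan)
                records[m]["cover"].append(np.nan)
            else:
                records[m]["tau"].append(est.tau_hat)
                records[m]["se"].append(est.se)
                records[m]["cover"].append(
                    float(est.ci_low <= config.tau <= est.ci_high)
                )
                if keep_replicates:
                    raw_rows.append(
                        {"replicate": r, "method": m, **est.as_dict()}
                    )
    target_mse = None
    if "Target" in methods:
        tau_t = np.asarray(records["Target"]["tau"], float)
        target_mse = float(np.nanmean((tau_t[~np.isnan(tau_t)] - config.tau) ** 2))
    rows = []
    for m in methods:
        row = {"method": m}
        row.update(
            performance_metrics(
                np.asarray(records[m]["tau"]),
                np.asarray(records[m]["se"]),
                np.asarray(records[m]["cover"]),
                truth=config.tau,
                target_mse=target_mse,
            )
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    meta_cols = ["n", "J", "rho", "theta", "effect_type"]
    for c in meta_cols:
        table[c] = getattr(config, c)
    table["base_seed"] = base_seed
    if keep_replicates:
        return table, pd.DataFrame(raw_rows)
    return table


def run_grid(
    scenarios: Sequence[ScenarioConfig],
    n_reps: int,
    base_seed: int,
    methods: Sequence[str] = METHODS,
    out_dir: str | Path | None = None,
    **kwargs,
) -> list[pd.DataFrame]:
    """Run a list of scenarios; optionally write one CSV per scenario.

    Output files carry a provenance sidecar (config, seeds) as JSON.
    """
    tables = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, cfg in enumerate(scenarios):
        table = run_scenario(cfg, n_reps, base_seed, methods, **kwargs)
        tables.append(table)
        if out_dir is not None:
            stem = (
                f"scenario_n{cfg.n}_J{cfg.J}_rho{cfg.rho}_theta{cfg.theta}"
                f"_{cfg.effect_type}"
            )
            table.to_csv(out_dir / f"{stem}.csv", index=False)
            (out_dir / f"{stem}.json").write_text(
                json.dumps(
                    {
                        "config": dataclasses.asdict(cfg),
                        "n_reps": n_reps,
                        "base_seed": base_seed,
                        "methods": list(methods),
                    },
                    indent=2,
                )
            )
    return tables


def scenario_grid(
    ns: Sequence[int] = (500, 2000),
    Js: Sequence[int] = (20, 40),
    rhos: Sequence[float] = (0.0, 0.5),
    thetas: Sequence[float] = (0.5, 1.0),
    effects: Sequence[str] = ("homogeneous", "heterogeneous"),
) -> list[ScenarioConfig]:
    """The full factorial study design (32 scenarios at the defaults)."""
    return [
        ScenarioConfig(n=n, J=J, rho=r, theta=t, effect_type=e)
        for e in effects
        for r in rhos
        for J in Js
        for t in thetas
        for n in ns
    ]
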