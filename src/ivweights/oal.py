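"""Outcome-adaptive lasso (OAL) for propensity-score variable selection.

The propensity model is an L1-penalized logistic regression whose
covariate-specific penalty factors come from the outcome model: with
alpha_tilde_j the OLS coefficient of (standardized) covariate j in the
outcome regression, the penalty weight is omega_j = |alpha_tilde_j|^(-gamma).
Covariates strongly associated with the outcome are penalized lightly and
survive; instruments and spurious covariates, whose outcome coefficients are
near zero, receive enormous penalties and are shrunk to exactly zero.

The coefficients maximize the penalized log-likelihood (sum scale)

    sum_i [ Z_i (b0 + x_i'b) - log(1 + exp(b0 + x_i'b)) ]
        - lambda_n * sum_j omega_j |b_j|,

with the intercept unpenalized.  lambda_n ranges over n^c for a fixed grid
of exponents c; gamma is tied to lambda_n through
lambda_n * n^(gamma/2 - 1) = n^2, i.e. gamma = 2*(3 - ln(lambda)/ln(n)),
which keeps the adaptive-lasso oracle conditions (lambda_n/n -> 0 and
lambda_n * n^(gamma/2-1) -> infinity) satisfied along the whole grid.
lambda_n is then selected by the weighted absolute mean difference (wAMD):
the sum over covariates of |alpha_tilde_j| times the absolute difference of
Hajek-weighted group means — imbalance only counts where it matters for the
outcome.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimators import (
    PS_CLIP,
    EffectEstimate,
    aiptw_estimate,
    fit_outcome_model,
    ipw_weights,
)

__all__ = [
    "OALConfig",
    "OALFit",
    "standardize",
    "outcome_association_coefs",
    "gamma_for_lambda",
    "penalty_weights",
    "fit_penalized_logistic",
    "wamd",
    "oal_estimate",
]

DEFAULT_LAMBDA_EXPONENTS = (-10.0, -5.0, -2.0, -1.0, -0.75, -0.5, -0.25, 0.25, 0.49)


@dataclasses.dataclass(frozen=True)
class OALConfig:
    lambda_exponents: tuple[float, ...] = DEFAULT_LAMBDA_EXPONENTS
    gamma_target_exponent: float = 2.0  # right-hand side n^2 of the gamma equation
    omega_cap: float = 1e8

    def lambdas(self, n: int) -> np.ndarray:
        lam = np.power(float(n), np.asarray(self.lambda_exponents, float))
        if np.any(lam <= 0):
            raise ValueError("lambda values must be strictly positive")
        return lam


@dataclasses.dataclass
class OALFit:
    alpha_tilde: np.ndarray
    path: pd.DataFrame  # per-lambda: lambda_exponent, lambda, gamma, wamd, n_nonzero
    coefs: np.ndarray  # per-lambda slope coefficients (standardized scale)
    intercepts: np.ndarray
    selected_index: int
    selected_lambda: float
    selected_set: list[int]
    fitted_ps: np.ndarray

    def path_csv(self, path) -> None:
        out = self.path.copy()
        for j in range(self.coefs.shape[1]):
            out[f"beta_X{j + 1}"] = self.coefs[:, j]
        out.to_csv(path, index=False)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns to mean 0 and scale to SD 1 (ddof=1).

    Returns (X_std, means, sds); the transform parameters allow back-mapping
    of coefficients to the raw scale.
    """
    X = np.asarray(X, float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant column(s) cannot be standardized: {bad.tolist()}")
    return (X - means) / sds, means, sds


def outcome_association_coefs(X_std: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Covariate coefficients from OLS of Y on intercept, Z, and X_std."""
    X_std = np.asarray(X_std, float)
    n = len(Y)
    Xd = np.column_stack([np.ones(n), np.asarray(Z, float), X_std])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient outcome design")
    coef = np.linalg.lstsq(Xd, np.asarray(Y, float), rcond=None)[0]
    return coef[2:]


def gamma_for_lambda(lam: float, n: int, target_exponent: float = 2.0) -> float:
    """Solve lambda * n^(gamma/2 - 1) = n^target_exponent for gamma.

    gamma = 2 * (target_exponent + 1 - ln(lambda)/ln(n)).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return 2.0 * (target_exponent + 1.0 - np.log(lam) / np.log(n))


def penalty_weights(alpha_tilde: np.ndarray, gamma: float, omega_cap: float = 1e8) -> np.ndarray:
    """Adaptive penalty factors omega_j = min(|alpha_tilde_j|^(-gamma), cap)."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    a = np.abs(np.asarray(alpha_tilde, float))
    omega = np.empty_like(a)
    zero = a == 0
    omega[zero] = omega_cap
    with np.errstate(over="ignore"):
        omega[~zero] = np.minimum(a[~zero] ** (-gamma), omega_cap)
    return omega


def fit_penalized_logistic(
    X_std: np.ndarray,
    Z: np.ndarray,
    lam: float,
    omega: np.ndarray,
    omega_cap: float = 1e8,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, np.ndarray]:
    """Weighted-L1 penalized logistic fit by IRLS + coordinate descent.

    Maximizes the sum-scale penalized log-likelihood with an unpenalized
    intercept.  Covariates whose penalty factor reached the cap are treated
    as having infinite penalty and are fixed at exactly zero.  Returns
    (intercept, slopes) on the standardized-covariate scale.
    """
    X = np.asarray(X_std, float)
    Zf = np.asarray(Z, float)
    n, p = X.shape
    omega = np.asarray(omega, float)
    if lam < 0 or np.any(omega < 0):
        raise ValueError("lambda and penalty factors must be nonnegative")
    active = omega < omega_cap  # capped factors mean exclusion
    thresh = lam * omega

    beta = np.zeros(p)
    b0 = float(np.log(np.clip(Zf.mean(), 1e-12, 1 - 1e-12) / (1 - np.clip(Zf.mean(), 1e-12, 1 - 1e-12))))
    eta = np.full(n, b0)
    sq = np.einsum("ij,ij->j", X, X)  # updated with IRLS weights each outer pass

    for _ in range(max_iter):
        mu = expit(np.clip(eta, -30, 30))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        zwork = eta + (Zf - mu) / w
        wsum = w.sum()
        sq = np.einsum("i,ij,ij->j", w, X, X)
        resid = zwork - eta  # working residual; eta tracks b0 + X @ beta
        max_delta_outer = 0.0
        # a few coordinate-descent sweeps on the quadratic approximation
        for _sweep in range(100):
            max_delta = 0.0
            b0_new = b0 + (w * resid).sum() / wsum
            d0 = b0_new - b0
            if d0 != 0.0:
                resid -= d0
                b0 = b0_new
                max_delta = abs(d0)
            for j in range(p):
                if not active[j]:
                    continue
                rho_j = w * X[:, j] @ resid + sq[j] * beta[j]
                bj = _soft(rho_j, thresh[j]) / sq[j]
                dj = bj - beta[j]
                if dj != 0.0:
                    resid -= dj * X[:, j]
                    beta[j] = bj
                    max_delta = max(max_delta, abs(dj))
            max_delta_outer = max(max_delta_outer, max_delta)
            if max_delta < tol:
                break
        eta = zwork - resid
        if max_delta_outer < tol:
            break
    else:
        raise RuntimeError(
            f"penalized logistic fit did not converge (lambda={lam:.3g}, "
            f"max penalty={thresh.max():.3g})"
        )
    beta[~active] = 0.0
    return b0, beta


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def wamd(X: np.ndarray, Z: np.ndarray, fitted_ps: np.ndarray, alpha_tilde: np.ndarray) -> float:
    """Weighted absolute mean difference of covariates between groups.

    Hajek (normalized) inverse-probability-weighted group means, with each
    covariate's imbalance weighted by |alpha_tilde_j|.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z)
    e = np.asarray(fitted_ps, float)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("fitted_ps must be strictly inside (0, 1)")
    w1 = np.where(Z == 1, 1.0 / e, 0.0)
    w0 = np.where(Z == 0, 1.0 / (1.0 - e), 0.0)
    s1, s0 = w1.sum(), w0.sum()
    if s1 == 0 or s0 == 0:
        raise ValueError("a treatment group has zero total weight")
    mean1 = w1 @ X / s1
    mean0 = w0 @ X / s0
    return float(np.abs(alpha_tilde) @ np.abs(mean1 - mean0))


def oal_estimate(
    X: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    config: OALConfig | None = None,
) -> tuple[EffectEstimate, OALFit]:
    """Full outcome-adaptive-lasso pipeline ending in an AIPTW estimate.

    Standardizes X, computes the outcome-association coefficients once, fits
    the penalized propensity model over the lambda grid, selects lambda by
    minimal wAMD (ties to the smaller lambda), and runs AIPTW with the
    outcome model on the selected (nonzero-coefficient) covariates.
    """
    config = config or OALConfig()
    X = np.asarray(X, float)
    n, p = X.shape
    X_std, _, _ = standardize(X)
    alpha_tilde = outcome_association_coefs(X_std, Z, Y)

    order = np.argsort(config.lambda_exponents)  # ascending lambda
    exps = np.asarray(config.lambda_exponents, float)[order]
    lams = config.lambdas(n)[order]

    rows = []
    coefs = np.zeros((len(lams), p))
    intercepts = np.zeros(len(lams))
    ps_per_lambda = np.zeros((len(lams), n))
    for idx, (ex, lam) in enumerate(zip(exps, lams)):
        gamma = gamma_for_lambda(lam, n, config.gamma_target_exponent)
        omega = penalty_weights(alpha_tilde, gamma, config.omega_cap)
        b0, beta = fit_penalized_logistic(X_std, Z, lam, omega, config.omega_cap)
        ps = np.clip(expit(np.clip(b0 + X_std @ beta, -30, 30)), PS_CLIP, 1 - PS_CLIP)
        w = wamd(X_std, Z, ps, alpha_tilde)
        rows.append(
            {
                "lambda_exponent": ex,
                "lambda": lam,
                "gamma": gamma,
                "wamd": w,
                "n_nonzero": int(np.count_nonzero(beta)),
            }
        )
        coefs[idx] = beta
        intercepts[idx] = b0
        ps_per_lambda[idx] = ps
    path = pd.DataFrame(rows)
    sel = int(np.argmin(path["wamd"].to_numpy()))  # first minimum = smallest lambda
    selected_set = np.flatnonzero(coefs[sel]).tolist()
    fitted_ps = ps_per_lambda[sel]

    fit = OALFit(
        alpha_tilde=alpha_tilde,
        path=path,
        coefs=coefs,
        intercepts=intercepts,
        selected_index=sel,
        selected_lambda=float(lams[sel]),
        selected_set=selected_set,
        fitted_ps=fitted_ps,
    )
    X_out = X[:, selected_set] if selected_set else None
    m1, m0, _ = fit_outcome_model(X_out, Z, Y)
    wv = ipw_weights(fitted_ps, Z)
    wv.source = "oal_ps"
    est = aiptw_estimate(Y, Z, wv, m1, m0, method="OAL", adjustment_set=selected_set)
    return est, fit
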