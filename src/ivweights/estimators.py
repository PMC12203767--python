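"""Working models and the doubly robust AIPTW estimator.

The estimator is augmented inverse-probability-of-treatment weighting:

    tau_hat = n^-1 * sum_i [ (2Z_i - 1) W_i (Y_i - m_{Z_i,i}) + m1_i - m0_i ]

with inverse-probability weights W_i = Z_i/e_i + (1-Z_i)/(1-e_i) and
outcome-model predictions m1/m0 at Z=1/Z=0.  Its variance is estimated from
the sample variance of the per-unit influence-function contributions

    psi_i = (2Z_i - 1) W_i (Y_i - m_{Z_i,i}) + m1_i - m0_i - tau_hat.

tau_hat is consistent if either the propensity model or the outcome model is
correctly specified (double robustness), which is what makes it safe to pair
with data-adaptive covariate selection.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "PSFit",
    "WeightVector",
    "EffectEstimate",
    "fit_logistic_ps",
    "fit_outcome_model",
    "ipw_weights",
    "aiptw",
    "influence_se",
    "wald_ci",
    "aiptw_estimate",
]

PS_CLIP = 1e-6  # fitted propensities clipped to [PS_CLIP, 1 - PS_CLIP]


@dataclasses.dataclass
class PSFit:
    """A fitted (possibly penalized) logistic propensity model."""

    intercept: float
    coef: np.ndarray
    fitted_ps: np.ndarray
    adjustment_set: list[int]
    converged: bool = True
    cov: np.ndarray | None = None  # (1+p)x(1+p) inverse-information, if available

    def z_statistics(self) -> np.ndarray:
        """Wald z-statistics of the slope coefficients."""
        if self.cov is None:
            raise ValueError("no covariance available for this fit")
        se = np.sqrt(np.diag(self.cov)[1:])
        return self.coef / se


@dataclasses.dataclass
class WeightVector:
    """Per-unit weights with an explicit scale convention.

    ``ipw`` scale means the weights are directly usable in the AIPTW sum:
    each treated unit carries about 1/e_hat, each control about 1/(1-e_hat),
    so each group's weights sum to roughly n.  ``hajek_group`` weights sum to
    one within each group and must be rescaled (multiplied by n) first.
    """

    weights: np.ndarray
    scale: str = "ipw"
    source: str = "logistic_ps"

    def __post_init__(self) -> None:
        if self.scale not in ("ipw", "hajek_group"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("weights must be nonnegative")


@dataclasses.dataclass
class EffectEstimate:
    """Point estimate with influence-function SE and 95% Wald interval."""

    tau_hat: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    adjustment_set: list[int]

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.tau_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _irls_logistic(
    Xd: np.ndarray, Z: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Xd includes the intercept column.  Returns (coefficients, covariance,
    converged).  Separation shows up as non-convergence with exploding
    coefficients; the caller flags it.
    """
    n, p = Xd.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = Xd.T @ (Z - mu)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(Xd @ beta, -30, 30)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, converged


def fit_logistic_ps(
    X_subset: np.ndarray, Z: np.ndarray, adjustment_set: Sequence[int] | None = None
) -> PSFit:
    """ML logistic propensity fit on the given covariate subset.

    Fitted propensities are clipped into [1e-6, 1-1e-6] so downstream
    inverse weights stay finite; separation or non-convergence yields a
    flagged fit with a warning rather than an exception.
    """
    X_subset = np.asarray(X_subset, float)
    if X_subset.ndim == 1:
        X_subset = X_subset[:, None]
    Z = np.asarray(Z)
    if len(np.unique(Z)) < 2:
        raise ValueError("treatment indicator is constant; cannot fit a propensity model")
    n = X_subset.shape[0]
    Xd = np.column_stack([np.ones(n), X_subset])
    beta, cov, converged = _irls_logistic(Xd, Z.astype(float))
    if not converged:
        warnings.warn(
            "logistic propensity fit did not converge (possible separation); "
            "fitted propensities are clipped",
            RuntimeWarning,
        )
    ps = np.clip(expit(np.clip(Xd @ beta, -30, 30)), PS_CLIP, 1.0 - PS_CLIP)
    if adjustment_set is None:
        adjustment_set = list(range(X_subset.shape[1]))
    return PSFit(
        intercept=float(beta[0]),
        coef=beta[1:],
        fitted_ps=ps,
        adjustment_set=list(adjustment_set),
        converged=converged,
        cov=cov,
    )


def fit_outcome_model(
    X_subset: np.ndarray | None, Z: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of Y on intercept, Z, and the covariate subset (joint main effects).

    Returns (m1, m0, coef) where m1/m0 are per-unit predictions at Z=1/Z=0
    and coef is the full coefficient vector (intercept, Z, covariates).
    m1 - m0 equals the Z coefficient for every unit.  Aliased columns are
    dropped (set to zero) with a warning via lstsq's minimum-norm solution.
    """
    Z = np.asarray(Z, float)
    Y = np.asarray(Y, float)
    n = len(Y)
    if X_subset is None or (hasattr(X_subset, "size") and X_subset.size == 0):
        Xd = np.column_stack([np.ones(n), Z])
    else:
        X_subset = np.asarray(X_subset, float)
        if X_subset.ndim == 1:
            X_subset = X_subset[:, None]
        Xd = np.column_stack([np.ones(n), Z, X_subset])
    if len(Z) != n or Xd.shape[0] != n:
        raise ValueError("X, Z, Y must share the row count")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        warnings.warn(
            "rank-deficient outcome design; using the minimum-norm least-squares fit",
            RuntimeWarning,
        )
    coef = np.linalg.lstsq(Xd, Y, rcond=None)[0]
    base = Xd @ coef
    m1 = base + (1.0 - Z) * coef[1]
    m0 = base - Z * coef[1]
    return m1, m0, coef


def ipw_weights(fitted_ps: np.ndarray, Z: np.ndarray) -> WeightVector:
    """Inverse-probability weights: 1/e for treated, 1/(1-e) for controls."""
    fitted_ps = np.asarray(fitted_ps, float)
    if np.any(fitted_ps <= 0) or np.any(fitted_ps >= 1):
        raise ValueError("fitted_ps must be strictly inside (0, 1)")
    Z = np.asarray(Z)
    w = np.where(Z == 1, 1.0 / fitted_ps, 1.0 / (1.0 - fitted_ps))
    return WeightVector(weights=w, scale="ipw", source="logistic_ps")


def _aiptw_terms(
    Y: np.ndarray, Z: np.ndarray, weights: WeightVector | np.ndarray,
    m1: np.ndarray, m0: np.ndarray,
) -> np.ndarray:
    if isinstance(weights, WeightVector):
        if weights.scale != "ipw":
            raise ValueError(
                "weights must be on the ipw scale; rescale hajek_group weights "
                "(multiply by n) first"
            )
        w = np.asarray(weights.weights, float)
    else:
        w = np.asarray(weights, float)
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)
    m_obs = np.where(Z == 1, m1, m0)
    return (2.0 * Z - 1.0) * w * (Y - m_obs) + m1 - m0


def aiptw(
    Y: np.ndarray, Z: np.ndarray, weights: WeightVector | np.ndarray,
    m1: np.ndarray, m0: np.ndarray,
) -> float:
    """Doubly robust AIPTW point estimate of the ATE."""
    return float(np.mean(_aiptw_terms(Y, Z, weights, m1, m0)))


def influence_se(
    Y: np.ndarray, Z: np.ndarray, weights: WeightVector | np.ndarray,
    m1: np.ndarray, m0: np.ndarray, tau_hat: float,
) -> float:
    """Influence-function standard error: SD(psi_hat)/sqrt(n)."""
    terms = _aiptw_terms(Y, Z, weights, m1, m0)
    n = len(terms)
    if n < 2:
        raise ValueError("need at least 2 units for a standard error")
    psi = terms - tau_hat
    return float(np.std(psi, ddof=1) / np.sqrt(n))


def wald_ci(tau_hat: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Two-sided normal-quantile confidence interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = norm.ppf(0.5 + level / 2.0)
    return tau_hat - z * se, tau_hat + z * se


def aiptw_estimate(
    Y: np.ndarray,
    Z: np.ndarray,
    weights: WeightVector | np.ndarray,
    m1: np.ndarray,
    m0: np.ndarray,
    method: str = "AIPTW",
    adjustment_set: Sequence[int] | None = None,
) -> EffectEstimate:
    """Convenience wrapper bundling point estimate, SE, and 95% Wald CI."""
    tau = aiptw(Y, Z, weights, m1, m0)
    se = influence_se(Y, Z, weights, m1, m0, tau)
    lo, hi = wald_ci(tau, se)
    return EffectEstimate(
        tau_hat=tau,
        se=se,
        ci_low=lo,
        ci_high=hi,
        method=method,
        adjustment_set=list(adjustment_set) if adjustment_set is not None else [],
    )
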