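"""Stable confounder selection (SCS).

Covariates are ordered by the strength of their joint association with
treatment and outcome: each covariate's priority is the smaller of its
absolute Wald z-statistic in the full logistic propensity model and its
absolute t-statistic in the full OLS outcome model, so dual-association
confounders outrank instruments (strong on the treatment side only) and
pure outcome predictors.  AIPTW estimates are then computed along the
nested covariate sets (top-1, top-2, ..., top-J), and the smallest set whose
estimate is closest to the inverse-variance-weighted moving average of a
five-wide window of neighboring estimates is selected.  Once enough
covariates are included to control confounding, further additions should
leave the estimate stable; instability flags an insufficient set.

The reported standard error is the plain influence-function SE at the
selected set — no post-selection correction — which is why coverage can
fall below nominal when selection is unstable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .estimators import (
    EffectEstimate,
    aiptw_estimate,
    fit_logistic_ps,
    fit_outcome_model,
    ipw_weights,
)

__all__ = [
    "SCSPath",
    "rank_covariates",
    "nested_estimates",
    "ivw_moving_average",
    "select_stable",
    "scs_estimate",
]

IVW_WEIGHT_CAP = 1e12  # a zero SE dominates its window rather than dividing by 0
DEFAULT_WINDOW = 5


@dataclasses.dataclass
class SCSPath:
    ranking: np.ndarray  # covariate indices in decreasing priority
    criterion: np.ndarray  # min(|z|, |t|) per covariate, in ranking order
    estimates: np.ndarray  # tau_hat_k for top-k sets, k = 1..J
    ses: np.ndarray
    moving_average: np.ndarray  # MA_k for k = 1..J-width+1, NaN-padded to J
    selected_k: int
    selected_estimate: EffectEstimate

    def to_frame(self) -> pd.DataFrame:
        J = len(self.ranking)
        return pd.DataFrame(
            {
                "rank": np.arange(1, J + 1),
                "covariate": self.ranking + 1,
                "criterion": self.criterion,
                "tau_hat": self.estimates,
                "se": self.ses,
                "moving_average": self.moving_average,
                "selected": np.arange(1, J + 1) == self.selected_k,
            }
        )


def _ols_t_statistics(X: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t-statistics of the covariate coefficients in OLS of Y on (1, Z, X)."""
    n = len(Y)
    Xd = np.column_stack([np.ones(n), np.asarray(Z, float), np.asarray(X, float)])
    coef, *_ = np.linalg.lstsq(Xd, np.asarray(Y, float), rcond=None)
    resid = Y - Xd @ coef
    dof = n - Xd.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for t-statistics")
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return (coef / se)[2:]


def rank_covariates(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Order covariates by min(|z| in full PS model, |t| in full outcome model).

    Descending; ties broken by the larger of the two statistics, then by
    covariate index.  Returns (ranking, criterion values in ranking order).
    """
    X = np.asarray(X, float)
    ps_fit = fit_logistic_ps(X, Z)
    zstat = np.abs(ps_fit.z_statistics())
    tstat = np.abs(_ols_t_statistics(X, Z, Y))
    crit = np.minimum(zstat, tstat)
    tiebreak = np.maximum(zstat, tstat)
    order = np.lexsort((np.arange(X.shape[1]), -tiebreak, -crit))
    return order, crit[order]


def nested_estimates(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray, ranking: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """AIPTW estimate and influence SE for each nested top-k covariate set.

    A failed fit at some k is recorded as NaN and later excluded from the
    moving-average window.
    """
    X = np.asarray(X, float)
    J = len(ranking)
    taus = np.full(J, np.nan)
    ses = np.full(J, np.nan)
    for k in range(1, J + 1):
        subset = np.asarray(ranking[:k])
        try:
            Xs = X[:, subset]
            ps = fit_logistic_ps(Xs, Z, adjustment_set=subset)
            m1, m0, _ = fit_outcome_model(Xs, Z, Y)
            est = aiptw_estimate(Y, Z, ipw_weights(ps.fitted_ps, Z), m1, m0)
            taus[k - 1] = est.tau_hat
            ses[k - 1] = est.se
        except (ValueError, np.linalg.LinAlgError):
            continue
    return taus, ses


def ivw_moving_average(
    estimates: np.ndarray, ses: np.ndarray, width: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Inverse-variance-weighted moving average over windows of `width`.

    MA_k = sum_{m=k}^{k+width-1} tau_m/se_m^2 / sum 1/se_m^2, for
    k = 1..J-width+1.  Missing (NaN) entries are dropped from their windows;
    an all-missing window yields NaN.  Returned array has length J with the
    trailing width-1 positions NaN.
    """
    taus = np.asarray(estimates, float)
    ses = np.asarray(ses, float)
    J = len(taus)
    if width < 1:
        raise ValueError("width must be >= 1")
    if J < width:
        raise ValueError(f"need at least {width} estimates for width-{width} windows")
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(ses)
    w = np.minimum(w, IVW_WEIGHT_CAP)
    w[np.isnan(taus) | np.isnan(ses)] = 0.0
    tw = np.where(w > 0, taus * w, 0.0)
    ma = np.full(J, np.nan)
    for k in range(J - width + 1):
        denom = w[k : k + width].sum()
        if denom > 0:
            ma[k] = tw[k : k + width].sum() / denom
    return ma


def select_stable(
    estimates: np.ndarray, ses: np.ndarray, moving_average: np.ndarray
) -> int:
    """Smallest k (1-based) minimizing |tau_k - MA_k| where MA_k is defined."""
    taus = np.asarray(estimates, float)
    ma = np.asarray(moving_average, float)
    dev = np.abs(taus - ma)
    valid = ~np.isnan(dev)
    if not valid.any():
        raise ValueError("no defined moving-average window")
    # argmin over valid entries; first occurrence = smallest k
    dev = np.where(valid, dev, np.inf)
    return int(np.argmin(dev)) + 1


def scs_estimate(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray, width: int = DEFAULT_WINDOW
) -> tuple[EffectEstimate, SCSPath]:
    """Full stable-confounder-selection pipeline ending in an AIPTW estimate."""
    X = np.asarray(X, float)
    ranking, crit = rank_covariates(X, Z, Y)
    taus, ses = nested_estimates(X, Z, Y, ranking)
    ma = ivw_moving_average(taus, ses, width)
    k = select_stable(taus, ses, ma)
    subset = ranking[:k].tolist()
    # recompute the selected estimate so the CI comes from one code path
    Xs = X[:, subset]
    ps = fit_logistic_ps(Xs, Z, adjustment_set=subset)
    m1, m0, _ = fit_outcome_model(Xs, Z, Y)
    est = aiptw_estimate(
        Y, Z, ipw_weights(ps.fitted_ps, Z), m1, m0, method="SCS", adjustment_set=subset
    )
    path = SCSPath(
        ranking=ranking,
        criterion=crit,
        estimates=taus,
        ses=ses,
        moving_average=ma,
        selected_k=k,
        selected_estimate=est,
    )
    return est, path
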