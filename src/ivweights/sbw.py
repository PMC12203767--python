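"""Stable balancing weights (SBW).

Rather than modeling the propensity score, SBW solves, separately for the
treated and control groups, the quadratic program

    minimize    sum_{i in group} (w_i - wbar)^2
    subject to  | sum_i w_i B_k(X_i) - (1/n) sum_all B_k(X) | <= delta_k,
                sum_i w_i = 1,   w_i >= 0,

i.e. the minimum-variance weights that balance each balance function B_k
toward its overall sample mean within tolerance delta_k.  Because the
weights are constrained to sum to one, minimizing their variance is the
same as minimizing sum w_i^2, so the program is a strictly convex QP.

The tolerance is parameterized as delta_k = delta * S_k^z with S_k^z the
unweighted within-group SD of B_k, and the common multiplier delta is picked
from a fixed grid by a bootstrap criterion: weights are solved once on the
original sample, bootstrap resamples carry those weights (renormalized
within group), and the delta minimizing the bootstrap-averaged sum of
standardized absolute distances to the overall means wins.

The QP is solved through its Lagrangian dual, whose dimension is only
2K + 1 (one multiplier pair per balance constraint plus one for the
normalization), with an LP feasibility pre-check.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .estimators import EffectEstimate, WeightVector, aiptw_estimate, fit_outcome_model

__all__ = [
    "BalanceSpec",
    "SBWFit",
    "solve_group_weights",
    "delta_candidates",
    "bootstrap_select_delta",
    "sbw_estimate",
]

DEFAULT_DELTA_MULTIPLIERS = (0.0001, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1)
CONSTRAINT_SLACK = 1e-6  # accepted violation of balance constraints after solving


@dataclasses.dataclass(frozen=True)
class BalanceSpec:
    """Configuration of the balance constraints and the delta search.

    ``balance_functions`` maps the raw covariate matrix to the K columns to
    be balanced; the default (None) balances the covariates themselves
    (K = J).  ``resolve_per_bootstrap`` re-solves the QP on every bootstrap
    resample instead of carrying the original-sample weights.
    """

    balance_functions: Callable[[np.ndarray], np.ndarray] | None = None
    delta_multipliers: tuple[float, ...] = DEFAULT_DELTA_MULTIPLIERS
    n_bootstrap: int = 200
    seed: int = 0
    resolve_per_bootstrap: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.delta_multipliers, float)
        if np.any(m <= 0) or np.any(np.diff(m) <= 0):
            raise ValueError("delta_multipliers must be positive and strictly ascending")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    def apply(self, X: np.ndarray) -> np.ndarray:
        B = X if self.balance_functions is None else self.balance_functions(X)
        return np.atleast_2d(np.asarray(B, float))


@dataclasses.dataclass
class SBWFit:
    weights_treated: np.ndarray  # sum to 1 over treated units
    weights_control: np.ndarray  # sum to 1 over control units
    selected_delta: float
    delta_table: pd.DataFrame  # delta, feasible_treated, feasible_control, mean_bootstrap_asd
    achieved_imbalance: np.ndarray  # per-k |weighted mean - overall mean|, both groups stacked

    def weights_ipw(self, Z: np.ndarray) -> np.ndarray:
        """Full-sample weights rescaled to the IPW scale (multiplied by n)."""
        Z = np.asarray(Z)
        n = len(Z)
        w = np.empty(n)
        w[Z == 1] = self.weights_treated * n
        w[Z == 0] = self.weights_control * n
        return w

    def to_frame(self, Z: np.ndarray) -> pd.DataFrame:
        Z = np.asarray(Z)
        n = len(Z)
        group_w = np.empty(n)
        group_w[Z == 1] = self.weights_treated
        group_w[Z == 0] = self.weights_control
        return pd.DataFrame(
            {
                "unit": np.arange(n),
                "group": Z,
                "weight_group_scale": group_w,
                "weight_ipw_scale": group_w * n,
            }
        )


def solve_group_weights(
    B_group: np.ndarray,
    target_means: np.ndarray,
    delta_k: np.ndarray | float,
) -> tuple[np.ndarray | None, str]:
    """Solve the per-group QP; returns (weights, status).

    status is "optimal" or "infeasible"; on infeasibility the weights are
    None (the caller's delta search treats this as a skipped candidate, not
    an error).
    """
    B = np.atleast_2d(np.asarray(B_group, float))
    m, K = B.shape
    if m < 2:
        raise ValueError("group must contain at least 2 units")
    t = np.asarray(target_means, float)
    d = np.broadcast_to(np.asarray(delta_k, float), (K,)).astype(float)
    if np.any(d < 0):
        raise ValueError("delta_k must be nonnegative")

    # LP feasibility pre-check (HiGHS): any w >= 0 with 1'w = 1, |B'w - t| <= d
    res = linprog(
        c=np.zeros(m),
        A_ub=np.vstack([B.T, -B.T]),
        b_ub=np.concatenate([t + d, -(t - d)]),
        A_eq=np.ones((1, m)),
        b_eq=np.ones(1),
        bounds=(0, None),
        method="highs",
    )
    if res.status != 0:
        return None, "infeasible"

    # Dual of min 1/2 ||w||^2 s.t. constraints; variables nu = (mu, lam+, lam-).
    # w*(nu) = max(0, mu - B @ (lam+ - lam-)); maximize
    #   g(nu) = mu - lam+'(t+d) + lam-'(t-d) - 1/2 ||w*||^2.
    upper = t + d
    lower = t - d

    def neg_dual(nu: np.ndarray) -> tuple[float, np.ndarray]:
        mu, lp, lm = nu[0], nu[1 : 1 + K], nu[1 + K :]
        v = mu - B @ (lp - lm)
        w = np.maximum(v, 0.0)
        g = mu - lp @ upper + lm @ lower - 0.5 * (w @ w)
        Bw = B.T @ w
        grad = np.concatenate(([1.0 - w.sum()], Bw - upper, lower - Bw))
        return -g, -grad

    nu0 = np.zeros(1 + 2 * K)
    nu0[0] = 1.0 / m  # uniform weights correspond to (mu=1/m, lam=0)
    bounds = [(None, None)] + [(0.0, None)] * (2 * K)
    opt = minimize(
        neg_dual,
        nu0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    mu, lp, lm = opt.x[0], opt.x[1 : 1 + K], opt.x[1 + K :]
    w = np.maximum(mu - B @ (lp - lm), 0.0)
    s = w.sum()
    if s <= 0:
        return None, "infeasible"
    w = w / s  # enforce the normalization exactly
    scale = np.maximum(np.abs(t), 1.0)
    if np.any(B.T @ w > upper + CONSTRAINT_SLACK * scale + 1e-9) or np.any(
        B.T @ w < lower - CONSTRAINT_SLACK * scale - 1e-9
    ):
        return None, "infeasible"
    return w, "optimal"


def delta_candidates(
    B: np.ndarray, group_indicator: np.ndarray, multipliers: Sequence[float] = DEFAULT_DELTA_MULTIPLIERS
) -> dict[int, np.ndarray]:
    """Per-group matrix of candidate tolerances delta_k = multiplier * S_k^z.

    Returns {z: array of shape (len(multipliers), K)} with S_k^z the
    unweighted SD (ddof=1) of balance function k within group z.
    """
    B = np.atleast_2d(np.asarray(B, float))
    Z = np.asarray(group_indicator)
    mult = np.asarray(multipliers, float)
    out: dict[int, np.ndarray] = {}
    for z in (0, 1):
        sd = B[Z == z].std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"balance function(s) {zero.tolist()} constant within group {z}"
            )
        out[z] = mult[:, None] * sd[None, :]
    return out


def _group_sds(B: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return B[Z == 0].std(axis=0, ddof=1), B[Z == 1].std(axis=0, ddof=1)


def bootstrap_select_delta(
    X: np.ndarray, Z: np.ndarray, spec: BalanceSpec
) -> tuple[float, pd.DataFrame, dict[float, tuple[np.ndarray, np.ndarray]]]:
    """Select the delta multiplier by the bootstrap ASD criterion.

    For each feasible delta the group weights are solved once on the
    original sample; each bootstrap resample (drawn with replacement from
    the full sample, shared across deltas) carries the original weights,
    renormalized within group, and contributes

        sum_k [ |wmean_1(B_k) - mean(B_k)| / S_k^1
              + |wmean_0(B_k) - mean(B_k)| / S_k^0 ],

    with the overall means and group SDs from the original sample.  The
    delta with the smallest bootstrap-averaged ASD wins (ties to the
    smaller delta).  Returns (selected_delta, per-delta table,
    {delta: (weights_control, weights_treated)}).
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z)
    B = spec.apply(X)
    n, K = B.shape
    overall = B.mean(axis=0)
    sd0, sd1 = _group_sds(B, Z)
    if np.any(sd0 == 0) or np.any(sd1 == 0):
        raise ValueError("a balance function is constant within a group")
    idx0, idx1 = np.flatnonzero(Z == 0), np.flatnonzero(Z == 1)

    rng = np.random.default_rng(spec.seed)
    boot_idx = rng.integers(0, n, size=(spec.n_bootstrap, n))

    rows = []
    solutions: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for mult in spec.delta_multipliers:
        w0, st0 = solve_group_weights(B[idx0], overall, mult * sd0)
        w1, st1 = solve_group_weights(B[idx1], overall, mult * sd1)
        feasible = st0 == "optimal" and st1 == "optimal"
        row = {
            "delta": mult,
            "feasible_treated": st1 == "optimal",
            "feasible_control": st0 == "optimal",
            "mean_bootstrap_asd": np.nan,
        }
        if feasible:
            if spec.resolve_per_bootstrap:
                asd = _asd_resolved(B, Z, overall, sd0, sd1, mult, boot_idx)
            else:
                asd = _asd_carried(B, Z, overall, sd0, sd1, w0, w1, idx0, idx1, boot_idx)
            row["mean_bootstrap_asd"] = asd
            solutions[mult] = (w0, w1)
        rows.append(row)
    table = pd.DataFrame(rows)
    if not solutions:
        raise RuntimeError(
            "no delta candidate is feasible; enlarge the multiplier grid"
        )
    feas = table.dropna(subset=["mean_bootstrap_asd"])
    selected = float(feas.loc[feas["mean_bootstrap_asd"].idxmin(), "delta"])
    return selected, table, solutions


def _asd_carried(B, Z, overall, sd0, sd1, w0, w1, idx0, idx1, boot_idx) -> float:
    """Bootstrap ASD with original-sample weights carried by resampled units."""
    n = len(Z)
    wfull = np.zeros(n)
    wfull[idx0] = w0
    wfull[idx1] = w1
    Zb = np.asarray(Z)[boot_idx]  # (Bn, n)
    Wb = wfull[boot_idx]
    total = 0.0
    count = 0
    for b in range(boot_idx.shape[0]):
        zb, wb, ib = Zb[b], Wb[b], boot_idx[b]
        s1 = wb[zb == 1].sum()
        s0 = wb[zb == 0].sum()
        if s1 <= 0 or s0 <= 0:
            continue  # degenerate resample: a group has no weight mass
        m1 = wb[zb == 1] @ B[ib[zb == 1]] / s1
        m0 = wb[zb == 0] @ B[ib[zb == 0]] / s0
        total += float(
            np.sum(np.abs(m1 - overall) / sd1) + np.sum(np.abs(m0 - overall) / sd0)
        )
        count += 1
    if count == 0:
        return np.inf
    return total / count


def _asd_resolved(B, Z, overall, sd0, sd1, mult, boot_idx) -> float:
    """Bootstrap ASD re-solving the QP on every resample (optional variant)."""
    total = 0.0
    count = 0
    for b in range(boot_idx.shape[0]):
        ib = boot_idx[b]
        zb = np.asarray(Z)[ib]
        if zb.sum() < 2 or (1 - zb).sum() < 2:
            continue
        Bb = B[ib]
        bsd0 = Bb[zb == 0].std(axis=0, ddof=1)
        bsd1 = Bb[zb == 1].std(axis=0, ddof=1)
        if np.any(bsd0 == 0) or np.any(bsd1 == 0):
            continue
        w0, st0 = solve_group_weights(Bb[zb == 0], overall, mult * bsd0)
        w1, st1 = solve_group_weights(Bb[zb == 1], overall, mult * bsd1)
        if st0 != "optimal" or st1 != "optimal":
            continue
        m0 = w0 @ Bb[zb == 0]
        m1 = w1 @ Bb[zb == 1]
        total += float(
            np.sum(np.abs(m1 - overall) / sd1) + np.sum(np.abs(m0 - overall) / sd0)
        )
        count += 1
    if count == 0:
        return np.inf
    return total / count


def sbw_estimate(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray, spec: BalanceSpec | None = None
) -> tuple[EffectEstimate, SBWFit]:
    """SBW weights at the bootstrap-selected delta, fed into AIPTW.

    The within-group weights (summing to one) are rescaled to the IPW scale
    by multiplying by n; the outcome model is OLS on the full covariate set.
    """
    spec = spec or BalanceSpec()
    X = np.asarray(X, float)
    Z = np.asarray(Z)
    selected, table, solutions = bootstrap_select_delta(X, Z, spec)
    w0, w1 = solutions[selected]
    fit = SBWFit(
        weights_treated=w1,
        weights_control=w0,
        selected_delta=selected,
        delta_table=table,
        achieved_imbalance=_achieved_imbalance(spec.apply(X), Z, w0, w1),
    )
    wv = WeightVector(weights=fit.weights_ipw(Z), scale="ipw", source="sbw")
    m1, m0, _ = fit_outcome_model(X, Z, Y)
    est = aiptw_estimate(
        Y, Z, wv, m1, m0, method="SBW", adjustment_set=list(range(X.shape[1]))
    )
    return est, fit


def _achieved_imbalance(B: np.ndarray, Z: np.ndarray, w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    overall = B.mean(axis=0)
    m0 = w0 @ B[np.asarray(Z) == 0]
    m1 = w1 @ B[np.asarray(Z) == 1]
    return np.vstack([np.abs(m0 - overall), np.abs(m1 - overall)])
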