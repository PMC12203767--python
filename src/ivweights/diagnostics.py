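"""Weighting diagnostics: effective sample size, maximum normalized weight,
and population standardized differences.

ESS = (sum w)^2 / sum w^2 within a group is the equal-precision equivalent
number of unweighted observations; it is maximized (at the group size) when
all weights are equal and collapses toward 1 under extreme weights.  The
population standardized difference (PSD) of covariate j in group z is
|weighted group mean - unweighted overall mean| / unweighted within-group
SD; values above 0.1 are conventionally read as inadequate balance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["DiagnosticsReport", "ess", "max_weight_pct", "psd", "diagnostics_report"]


def ess(weights_in_group: np.ndarray) -> float:
    """Effective sample size (sum w)^2 / (sum w^2); scale-invariant."""
    w = np.asarray(weights_in_group, float)
    if w.size == 0:
        raise ValueError("empty group")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    return float(w.sum() ** 2 / (w @ w))


def max_weight_pct(weights_in_group: np.ndarray) -> float:
    """Largest within-group-normalized weight, times 100."""
    w = np.asarray(weights_in_group, float)
    if w.size == 0:
        raise ValueError("empty group")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return float(100.0 * w.max() / s)


def psd(X: np.ndarray, weights: np.ndarray, Z: np.ndarray, group: int) -> np.ndarray:
    """Population standardized differences for one group, per covariate.

    |weighted mean within group - unweighted overall mean| divided by the
    group's unweighted SD (ddof=1).
    """
    X = np.atleast_2d(np.asarray(X, float))
    w = np.asarray(weights, float)
    Z = np.asarray(Z)
    mask = Z == group
    if not mask.any():
        raise ValueError(f"no units in group {group}")
    Xg, wg = X[mask], w[mask]
    s = wg.sum()
    if s <= 0:
        raise ValueError("group weights sum to zero")
    sd = Xg.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"covariate(s) {zero.tolist()} constant within group {group}")
    wmean = wg @ Xg / s
    overall = X.mean(axis=0)
    return np.abs(wmean - overall) / sd


@dataclasses.dataclass
class DiagnosticsReport:
    ess_by_group: dict[int, float]
    max_weight_pct_by_group: dict[int, float]
    psd_table: pd.DataFrame  # covariate x group
    extreme_ps_fraction: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for z in sorted(self.ess_by_group):
            rows.append(
                {
                    "group": z,
                    "ess": self.ess_by_group[z],
                    "max_weight_pct": self.max_weight_pct_by_group[z],
                    "max_psd": float(self.psd_table[f"group_{z}"].max()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Weighting diagnostics", "---------------------"]
        for z in sorted(self.ess_by_group):
            lines.append(
                f"group {z}: ESS = {self.ess_by_group[z]:.1f}, "
                f"max normalized weight x100 = {self.max_weight_pct_by_group[z]:.2f}, "
                f"max PSD = {self.psd_table[f'group_{z}'].max():.3f}"
            )
        if self.extreme_ps_fraction is not None:
            lines.append(
                f"fraction of propensity scores outside [0.1, 0.9]: "
                f"{self.extreme_ps_fraction:.3f}"
            )
        return "\n".join(lines)


def diagnostics_report(
    X: np.ndarray,
    weights: np.ndarray,
    Z: np.ndarray,
    fitted_ps: np.ndarray | None = None,
) -> DiagnosticsReport:
    """Bundle ESS, maximum normalized weight, and PSDs for both groups."""
    from .dgp import extreme_ps_fraction as _epf

    Z = np.asarray(Z)
    w = np.asarray(weights, float)
    ess_g = {z: ess(w[Z == z]) for z in (0, 1)}
    mw_g = {z: max_weight_pct(w[Z == z]) for z in (0, 1)}
    X = np.atleast_2d(np.asarray(X, float))
    table = pd.DataFrame(
        {
            "covariate": [f"X{j + 1}" for j in range(X.shape[1])],
            "group_0": psd(X, w, Z, 0),
            "group_1": psd(X, w, Z, 1),
        }
    )
    frac = None if fitted_ps is None else _epf(np.asarray(fitted_ps, float))
    return DiagnosticsReport(
        ess_by_group=ess_g,
        max_weight_pct_by_group=mw_g,
        psd_table=table,
        extreme_ps_fraction=frac,
    )
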