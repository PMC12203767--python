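"""Synthetic data-generating process for the weighting simulation study.

Covariates are J-variate standard normal with a common (equicorrelated)
correlation ``rho``.  The first six covariates have fixed structural roles:

* ``X1, X2``  — true confounders (affect both treatment and outcome),
* ``X3, X4``  — outcome-only predictors,
* ``X5, X6``  — instrumental variables (treatment-only predictors, strength
  ``theta``),
* ``X7..XJ``  — spurious noise covariates.

Treatment is Bernoulli with logit(P(Z=1|X)) = beta0 + beta'X where
beta = (0.5, 0.5, 0, 0, theta, theta, 0, ..., 0).  The outcome is linear,
Y = tau*Z + alpha0 + alpha'X + eps with alpha = (1, 1, 1, 1, 0, ..., 0) and
eps ~ N(0, sigma_eps^2).  Under heterogeneous effects tau*Z is replaced by
(1 + X1 + X2)*Z; the average treatment effect stays tau = 1 because
E[1 + X1 + X2] = 1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "generate_covariates",
    "treatment_coefficients",
    "outcome_coefficients",
    "true_propensity",
    "generate_treatment",
    "generate_outcome",
    "extreme_ps_fraction",
    "simulate_dataset",
]

EffectType = Literal["homogeneous", "heterogeneous"]


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """All simulation knobs for one scenario plus the fixed truth parameters.

    ``tau`` (true ATE), ``beta0``/``alpha0`` (model intercepts) and
    ``sigma_eps`` (outcome noise SD) are part of the study design and
    rarely changed.
    """

    n: int = 500
    J: int = 20
    rho: float = 0.0
    theta: float = 0.5
    effect_type: str = "homogeneous"
    tau: float = 1.0
    beta0: float = 0.0
    alpha0: float = 0.0
    sigma_eps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.J < 6:
            raise ValueError(
                f"J must be >= 6 (first six covariates have fixed roles), got {self.J}"
            )
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.effect_type not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")

    def to_file(self, path: str | Path) -> None:
        """Serialize as a flat YAML/JSON key-value mapping."""
        path = Path(path)
        payload = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls(**payload)


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    """One simulated sample: covariates, treatment, outcome, and the truth."""

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    true_ps: np.ndarray
    true_ate: float

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.Z) == len(self.Y) == len(self.true_ps) == n):
            raise ValueError("X, Z, Y, true_ps must share the row count")
        if np.any(self.true_ps <= 0) or np.any(self.true_ps >= 1):
            raise ValueError("true_ps must be strictly inside (0, 1)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"Y": self.Y, "Z": self.Z.astype(int)}
        for j in range(self.J):
            cols[f"X{j + 1}"] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_dataset_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a delimited dataset (columns Y, Z, X1..XJ) into (X, Z, Y)."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("missing values are not allowed in input datasets")
    xcols = sorted(
        (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return df[xcols].to_numpy(float), df["Z"].to_numpy(int), df["Y"].to_numpy(float)


def generate_covariates(
    n: int, J: int, rho: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n rows from a J-variate standard normal with equicorrelation rho.

    Uses the one-factor representation X = sqrt(rho)*G + sqrt(1-rho)*E with a
    shared scalar G per row, which is exact for the equicorrelation matrix
    (valid for rho >= 0; the matrix is positive definite for rho < 1).
    """
    if n < 2 or J < 1:
        raise ValueError("need n >= 2 and J >= 1")
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"rho={rho} invalid: the equicorrelation matrix requires 0 <= rho < 1"
        )
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, J))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique


def treatment_coefficients(J: int, theta: float) -> np.ndarray:
    """Treatment-model slopes (0.5, 0.5, 0, 0, theta, theta, 0, ..., 0)."""
    if J < 6:
        raise ValueError(f"J must be >= 6, got {J}")
    beta = np.zeros(J)
    beta[0] = beta[1] = 0.5
    beta[4] = beta[5] = theta
    return beta


def outcome_coefficients(J: int) -> np.ndarray:
    """Outcome-model slopes (1, 1, 1, 1, 0, ..., 0)."""
    if J < 6:
        raise ValueError(f"J must be >= 6, got {J}")
    alpha = np.zeros(J)
    alpha[:4] = 1.0
    return alpha


def true_propensity(X: np.ndarray, beta: np.ndarray, beta0: float = 0.0) -> np.ndarray:
    """Inverse-logit of beta0 + X @ beta."""
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but beta has length {beta.shape[0]}")
    from scipy.special import expit

    return expit(beta0 + X @ beta)


def generate_treatment(true_ps: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(true_ps) draws."""
    true_ps = np.asarray(true_ps, float)
    if np.any(true_ps <= 0) or np.any(true_ps >= 1):
        raise ValueError("true_ps must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    return (rng.random(true_ps.shape) < true_ps).astype(int)


def generate_outcome(
    X: np.ndarray,
    Z: np.ndarray,
    effect_type: str,
    seed: int | np.random.Generator,
    tau: float = 1.0,
    alpha0: float = 0.0,
    sigma_eps: float = 2.0,
) -> np.ndarray:
    """Continuous outcome under homogeneous or heterogeneous treatment effects.

    homogeneous:   Y = tau*Z + alpha0 + X @ alpha + eps
    heterogeneous: Y = (1 + X1 + X2)*Z + alpha0 + X @ alpha + eps

    with eps ~ N(0, sigma_eps^2).  Both imply ATE = tau = 1 in the study
    design (heterogeneous because E[1 + X1 + X2] = 1).
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    if X.shape[1] < 2:
        raise ValueError("X needs at least 2 columns")
    if effect_type == "homogeneous":
        effect = tau * Z
    elif effect_type == "heterogeneous":
        effect = (1.0 + X[:, 0] + X[:, 1]) * Z
    else:
        raise ValueError(f"unknown effect_type {effect_type!r}")
    alpha = outcome_coefficients(X.shape[1]) if X.shape[1] >= 6 else np.zeros(X.shape[1])
    if X.shape[1] < 6:
        # small toy designs: first min(4, J) covariates predict the outcome
        alpha[: min(4, X.shape[1])] = 1.0
    rng = np.random.default_rng(seed)
    eps = sigma_eps * rng.standard_normal(len(Z))
    return effect + alpha0 + X @ alpha + eps


def extreme_ps_fraction(ps: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Fraction of propensity scores strictly outside the closed [lo, hi] band.

    Boundary values count as non-extreme ("outside the range [0.1, 0.9]").
    """
    ps = np.asarray(ps, float)
    if ps.size == 0:
        raise ValueError("empty propensity-score vector")
    if not lo < hi:
        raise ValueError("require lo < hi")
    return float(np.mean((ps < lo) | (ps > hi)))


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Generate one dataset under the scenario.

    The master seed is split into independent sub-streams for covariates,
    treatment, and outcome noise, so each component is reproducible in
    isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_trt, s_out = ss.spawn(3)
    X = generate_covariates(config.n, config.J, config.rho, np.random.default_rng(s_cov))
    beta = treatment_coefficients(config.J, config.theta)
    ps = true_propensity(X, beta, config.beta0)
    # guard the open-interval invariant against floating-point saturation
    ps = np.clip(ps, 1e-12, 1.0 - 1e-12)
    Z = generate_treatment(ps, np.random.default_rng(s_trt))
    Y = generate_outcome(
        X,
        Z,
        config.effect_type,
        np.random.default_rng(s_out),
        tau=config.tau,
        alpha0=config.alpha0,
        sigma_eps=config.sigma_eps,
    )
    return SimulatedDataset(X=X, Z=Z, Y=Y, true_ps=ps, true_ate=config.tau)
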