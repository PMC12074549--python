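"""Seeded generators for the benchmark simulation designs.

Each generator returns the observable sample ``(Y, X, T)`` together with the
ground truth (index directions, structural dimension, centering constants)
needed by subspace-recovery studies.  Three families are provided:

* **Model I** — single index (q = 1), ``Y = exp(X'b1) - c + 1.5 sin(2 pi T) + eps``
  with T ~ U[0,1] independent of X.  Scenario A uses p = 20 i.i.d.
  Bernoulli(1/2) covariates and b1 = (1/sqrt(19))(1,...,1,0)'; scenario B uses
  p = 10 standard normal covariates and b1 with 1/sqrt(2) in positions 1 and 3.
* **Model II** — two indices (q = 2) with an equicorrelated joint normal
  design for (X, T): ``Y = 1.5 sin(X'b1) + sin^2(X'b2) - c + sin(2 pi T) + eps``.
* **Model III** — single index with a linear conditioning effect,
  ``Y = theta T + 3 sin(b1'X / 4) + 0.2 eps`` with everything standard normal
  and independent; case A has p = 6, case B has p = 10.

All index components are centered to population mean zero (the additive-model
identifiability convention E[g] = E[f] = 0); the centering constants have
closed forms and are stored in the returned :class:`TrueStructure`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RegressionSample",
    "TrueStructure",
    "SimulationConfig",
    "generate_model_I",
    "generate_model_II",
    "generate_model_III",
    "generate",
    "MODEL_IDS",
]

MODEL_IDS = ("I-A", "I-B", "II", "III-A", "III-B")


@dataclass(frozen=True)
class RegressionSample:
    """Observed triples (Y, X, T) for n units.

    Y and T are length-n vectors, X is an n-by-p matrix; no missing values.
    """

    Y: np.ndarray
    X: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if Y.ndim != 1 or T.ndim != 1 or X.ndim != 2:
            raise ValueError("Y and T must be 1-d, X must be 2-d")
        n = Y.shape[0]
        if n < 1:
            raise ValueError("need at least one observation")
        if T.shape[0] != n or X.shape[0] != n:
            raise ValueError("Y, X, T must have the same number of rows")
        if not (np.isfinite(Y).all() and np.isfinite(X).all() and np.isfinite(T).all()):
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "T", T)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class TrueStructure:
    """Ground truth of a simulated design, for recovery tests.

    ``B_true`` has unit-norm columns spanning the true index subspace;
    ``q_true`` is its column count.  ``g_center``/``f_center`` are the
    population means subtracted from the raw index / nonlinear components.
    """

    B_true: np.ndarray
    q_true: int
    g_center: float
    f_center: float
    model_id: str
    gamma: Optional[float] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B_true, dtype=float))
        if B.shape[1] != self.q_true:
            raise ValueError("q_true must equal the number of columns of B_true")
        norms = np.linalg.norm(B, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("B_true columns must have unit Euclidean norm")
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if (self.gamma is not None) != (self.model_id == "II"):
            raise ValueError("gamma is present iff model_id is 'II'")
        object.__setattr__(self, "B_true", B)


@dataclass(frozen=True)
class SimulationConfig:
    """Plumbing record: which design, at what size, from which seed."""

    model_id: str
    n: int
    seed: int
    gamma: float = 0.2
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def model_I_g_center(scenario: str) -> float:
    """Population mean of exp(X'b1) for Model I.

    Scenario A: X_k iid Bernoulli(1/2), b1 = (1/sqrt19)(1,..,1,0) in R^20, so
    E exp(X'b1) = ((1 + e^{1/sqrt19})/2)^19.  Scenario B: X'b1 ~ N(0,1), so
    E exp(X'b1) = e^{1/2}.
    """
    if scenario == "A":
        return float(((1.0 + np.exp(1.0 / np.sqrt(19.0))) / 2.0) ** 19)
    if scenario == "B":
        return float(np.exp(0.5))
    raise ValueError(f"unknown scenario {scenario!r}")


def generate_model_I(
    n: int,
    scenario: str,
    seed: int,
    noise_scale: float = 1.0,
) -> tuple[RegressionSample, TrueStructure]:
    """Single-index design Y = exp(X'b1) - c + 1.5 sin(2 pi T) + noise.

    Parameters
    ----------
    n : sample size (>= 1).
    scenario : 'A' (p=20 Bernoulli covariates) or 'B' (p=10 normal covariates).
    seed : RNG seed; identical seeds give bitwise-identical samples.
    noise_scale : multiplier on the N(0,1) error (0 switches noise off).
    """
    if scenario not in ("A", "B"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if scenario == "A":
        p = 20
        X = rng.integers(0, 2, size=(n, p)).astype(float)
        beta1 = np.zeros(p)
        beta1[:19] = 1.0 / np.sqrt(19.0)
    else:
        p = 10
        X = rng.standard_normal((n, p))
        beta1 = np.zeros(p)
        beta1[[0, 2]] = 1.0 / np.sqrt(2.0)
    T = rng.uniform(0.0, 1.0, size=n)
    eps = rng.standard_normal(n)
    g_center = model_I_g_center(scenario)
    g = np.exp(X @ beta1) - g_center
    f = 1.5 * np.sin(2.0 * np.pi * T)
    Y = g + f + noise_scale * eps
    truth = TrueStructure(
        B_true=_normalize(beta1)[:, None],
        q_true=1,
        g_center=g_center,
        f_center=0.0,
        model_id=f"I-{scenario}",
    )
    return RegressionSample(Y=Y, X=X, T=T), truth


def model_II_g_center(gamma: float) -> float:
    """Population mean of sin^2(X'b2) under the equicorrelated normal design.

    X'b2 ~ N(0, s2) with s2 = b2' Sigma b2, and
    E sin^2(N(0, s2)) = (1 - e^{-2 s2}) / 2.
    """
    beta2 = np.zeros(10)
    beta2[1] = 1.0 / np.sqrt(2.0)
    Sigma = np.full((10, 10), gamma)
    np.fill_diagonal(Sigma, 1.0)
    s2 = float(beta2 @ Sigma @ beta2)
    return float((1.0 - np.exp(-2.0 * s2)) / 2.0)


def generate_model_II(
    n: int,
    gamma: float,
    seed: int,
    noise_scale: float = 1.0,
) -> tuple[RegressionSample, TrueStructure]:
    """Two-index design with equicorrelated joint normal covariates.

    The (p+1)-vector (X', T)' is multivariate normal with unit variances and
    every off-diagonal correlation equal to ``gamma``;
    Y = 1.5 sin(X'b1) + sin^2(X'b2) - c + sin(2 pi T) + noise with
    b1 = e1/sqrt2, b2 = e2/sqrt2 in R^10.
    """
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    p = 10
    rng = np.random.default_rng(seed)
    Sigma = np.full((p + 1, p + 1), gamma)
    np.fill_diagonal(Sigma, 1.0)
    L = np.linalg.cholesky(Sigma)
    W = rng.standard_normal((n, p + 1)) @ L.T
    X, T = W[:, :p], W[:, p]
    beta1 = np.zeros(p)
    beta1[0] = 1.0 / np.sqrt(2.0)
    beta2 = np.zeros(p)
    beta2[1] = 1.0 / np.sqrt(2.0)
    g_center = model_II_g_center(gamma)
    g = 1.5 * np.sin(X @ beta1) + np.sin(X @ beta2) ** 2 - g_center
    f = np.sin(2.0 * np.pi * T)
    eps = rng.standard_normal(n)
    Y = g + f + noise_scale * eps
    B = np.stack([_normalize(beta1), _normalize(beta2)], axis=1)
    truth = TrueStructure(
        B_true=B,
        q_true=2,
        g_center=g_center,
        f_center=0.0,
        model_id="II",
        gamma=gamma,
    )
    return RegressionSample(Y=Y, X=X, T=T), truth


def generate_model_III(
    n: int,
    case: str,
    seed: int,
    noise_scale: float = 1.0,
    theta: float = 0.3,
) -> tuple[RegressionSample, TrueStructure]:
    """Single-index design with a linear conditioning effect.

    Y = theta W + 3 sin(b1'X / 4) + 0.2 * noise; X ~ N(0, I_p), W ~ N(0,1),
    all independent.  The linear term theta*W plays the role of f(T) with
    T := W.  Case A: p = 6, b1 = (1/sqrt3)(1,1,1,0,0,0)'; case B: p = 10,
    b1 with 1/2 in positions 1-4.
    """
    if case not in ("A", "B"):
        raise ValueError(f"unknown case {case!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if case == "A":
        p = 6
        beta1 = np.zeros(p)
        beta1[:3] = 1.0 / np.sqrt(3.0)
    else:
        p = 10
        beta1 = np.zeros(p)
        beta1[:4] = 0.5
    X = rng.standard_normal((n, p))
    T = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    Y = theta * T + 3.0 * np.sin((X @ beta1) / 4.0) + 0.2 * noise_scale * eps
    truth = TrueStructure(
        B_true=_normalize(beta1)[:, None],
        q_true=1,
        g_center=0.0,
        f_center=0.0,
        model_id=f"III-{case}",
        theta=theta,
    )
    return RegressionSample(Y=Y, X=X, T=T), truth


def generate(config: SimulationConfig) -> tuple[RegressionSample, TrueStructure]:
    """Dispatch on ``config.model_id``; same config gives identical output."""
    mid = config.model_id
    if mid in ("I-A", "I-B"):
        return generate_model_I(config.n, mid[-1], config.seed, config.noise_scale)
    if mid == "II":
        return generate_model_II(config.n, config.gamma, config.seed, config.noise_scale)
    return generate_model_III(config.n, mid[-1], config.seed, config.noise_scale)
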