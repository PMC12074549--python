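"""Density-ratio weighted kernel estimation of the additive components.

After dimension reduction the model is a standard additive regression

    Y = alpha~ + g~(Z) + f~(T) + eps,      Z = X B_hat,

with both components centered (E g~ = E f~ = 0).  Each component is isolated
by marginal integration with a density-ratio weight: multiplying Y by
Phi(Z, T) = f_Z(Z) f_T(T) / f(Z, T) and averaging conditional on Z = z wipes
out the f~ component, because E[Phi | Z = z] = 1 and E[Phi f~(T) | Z = z] = 0.
The sample version is the "fast instrumental variable pilot" estimator

    g*(z) = n^{-1} sum_i K_h1(Z_i, z) * f_T(T_i) / f(Z_i, T_i) * Y_i,

with plug-in kernel density estimates (standard normal product kernels), and
symmetrically for f*(t) with the roles of Z and T exchanged.  The intercept
is alpha~ = Ybar, and the centered components are g~ = g* - alpha,
f~ = f* - alpha, re-centered over the training sample so the identifiability
convention holds exactly in finite samples.

Ratios f_T / f are trimmed at the 1st percentile of the training joint
density: points below the floor are dropped from the sums (the ratio is
unstable where the joint density is near zero) and the retained count is the
divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .psdr import ReductionEstimate
from .simulate import RegressionSample

__all__ = [
    "Bandwidths",
    "AdditiveEstimate",
    "kde",
    "estimate_alpha",
    "g_star_hat",
    "f_star_hat",
    "center_components",
    "cv_bandwidth",
    "fit_additive",
    "predict",
    "reference_bandwidth",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Bandwidths:
    """The five smoothing scales of the pilot stage.

    h0: joint-mean kernel (only formal: the intercept reduces to Ybar);
    h1: index-block kernel of the g* sum; h2: T-marginal density;
    h3: joint (Z, T) density; h4: T-block kernel of the f* sum.
    """

    h0: float
    h1: float
    h2: float
    h3: float
    h4: float

    def __post_init__(self) -> None:
        for name in ("h0", "h1", "h2", "h3", "h4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bandwidth {name} must be strictly positive")


def _gauss_product(points: np.ndarray, eval_points: np.ndarray, h: float) -> np.ndarray:
    """Matrix of product-Gaussian kernel weights K_h(points_i, eval_j).

    Entry (i, j) = h^{-d} prod_l phi((points_il - eval_jl)/h); shapes are
    (n, d) and (m, d).
    """
    P = np.atleast_2d(points)
    E = np.atleast_2d(eval_points)
    if P.shape[1] != E.shape[1]:
        raise ValueError("dimension mismatch between points and eval points")
    d = P.shape[1]
    # squared distances via broadcasting; n*m*d memory transient
    diff = P[:, None, :] - E[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    return np.exp(-0.5 * sq / h**2) / (h * _SQRT_2PI) ** d


def kde(points: np.ndarray, eval_points: np.ndarray, h: float) -> np.ndarray:
    """Product-Gaussian kernel density estimate at the evaluation points.

    ``points`` is (n, d) (or length-n for d = 1); returns a length-m vector of
    strictly positive density values.
    """
    if h <= 0:
        raise ValueError("bandwidth must be strictly positive")
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[0] == 0:
        raise ValueError("points must be non-empty")
    E = np.asarray(eval_points, dtype=float)
    scalar = E.ndim == 0
    if E.ndim <= 1 and P.shape[1] == 1:
        E = np.atleast_1d(E)[:, None]
    E = np.atleast_2d(E)
    out = _gauss_product(P, E, h).mean(axis=0)
    return float(out[0]) if scalar else out


def estimate_alpha(Y: np.ndarray) -> float:
    """Intercept estimate: the kernel double-sum identity reduces to Ybar."""
    Y = np.asarray(Y, dtype=float)
    if Y.size == 0:
        raise ValueError("Y must be non-empty")
    return float(Y.mean())


def _density_ratios(
    Z: np.ndarray, T: np.ndarray, bw: Bandwidths
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Training-point densities f_T(T_i), f_Z(Z_i), f(Z_i, T_i) and trim mask."""
    U = np.column_stack([Z, T])
    fT = kde(T, T, bw.h2)
    fZ = kde(Z, Z, bw.h3)  # q-variate marginal shares the joint-density scale
    fU = kde(U, U, bw.h3)
    keep = _trim_mask(fU)
    return fT, fZ, fU, keep


def _trim_mask(fU: np.ndarray) -> np.ndarray:
    """Drop the floor(n/100) training points with the lowest joint density."""
    n = fU.shape[0]
    k = n // 100
    keep = np.ones(n, dtype=bool)
    if k > 0:
        keep[np.argpartition(fU, k - 1)[:k]] = False
    return keep


def g_star_hat(
    z: np.ndarray,
    sample_reduced: tuple[np.ndarray, np.ndarray, np.ndarray],
    bandwidths: Bandwidths,
) -> np.ndarray:
    """Marginal-integration estimate g*(z) = mean_i K_h1(Z_i,z) fT(T_i)/f(Z_i,T_i) Y_i.

    ``sample_reduced`` is (Z, T, Y) with Z of shape (n, q); ``z`` is a single
    q-vector or an (m, q) grid.  Training points whose joint density falls
    below the trimming floor are excluded and the retained count divides.
    """
    Z, T, Y = (np.asarray(a, dtype=float) for a in sample_reduced)
    if Z.ndim == 1:
        Z = Z[:, None]
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0 or (z_arr.ndim == 1 and Z.shape[1] > 1)
    if z_arr.ndim == 0:
        z_arr = z_arr[None, None]
    elif z_arr.ndim == 1:
        z_arr = z_arr[None, :] if Z.shape[1] > 1 else z_arr[:, None]
    fT, _, fU, keep = _density_ratios(Z, T, bandwidths)
    W = _gauss_product(Z[keep], z_arr, bandwidths.h1)
    ratio = fT[keep] / fU[keep]
    vals = (W * (ratio * Y[keep])[:, None]).sum(axis=0) / keep.sum()
    return float(vals[0]) if scalar else vals


def f_star_hat(
    t: np.ndarray,
    sample_reduced: tuple[np.ndarray, np.ndarray, np.ndarray],
    bandwidths: Bandwidths,
) -> np.ndarray:
    """Mirror of :func:`g_star_hat` with Z and T exchanged (kernel h4)."""
    Z, T, Y = (np.asarray(a, dtype=float) for a in sample_reduced)
    if Z.ndim == 1:
        Z = Z[:, None]
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.asarray(t).ndim == 0
    _, fZ, fU, keep = _density_ratios(Z, T, bandwidths)
    W = _gauss_product(T[keep, None], t_arr[:, None], bandwidths.h4)
    ratio = fZ[keep] / fU[keep]
    vals = (W * (ratio * Y[keep])[:, None]).sum(axis=0) / keep.sum()
    return float(vals[0]) if scalar else vals


def center_components(
    g_star: Callable[[np.ndarray], np.ndarray],
    f_star: Callable[[np.ndarray], np.ndarray],
    alpha_hat: float,
    Z_train: np.ndarray | None = None,
    T_train: np.ndarray | None = None,
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Centered evaluators g~ = g* - alpha and f~ = f* - alpha.

    When training points are supplied, each component is additionally
    re-centered by its training-sample mean so that mean g~(Z_i) = 0 and
    mean f~(T_i) = 0 hold exactly.
    """
    if not np.isfinite(alpha_hat):
        raise ValueError("alpha_hat must be finite")
    g_shift = alpha_hat
    f_shift = alpha_hat
    if Z_train is not None:
        g_shift = g_shift + float(np.mean(g_star(Z_train)) - alpha_hat)
    if T_train is not None:
        f_shift = f_shift + float(np.mean(f_star(T_train)) - alpha_hat)

    def g_tilde(z):
        return g_star(z) - g_shift

    def f_tilde(t):
        return f_star(t) - f_shift

    return g_tilde, f_tilde


def reference_bandwidth(points: np.ndarray, dim: int) -> float:
    """Rule-of-thumb scale sigma_hat * n^{-1/(4+dim)} for a dim-variate smoother."""
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    sigma = float(P.std(axis=0, ddof=1).mean())
    if sigma <= 0:
        sigma = 1.0
    return sigma * n ** (-1.0 / (4.0 + dim))


def _loo_fit(Z, T, Y, bw: Bandwidths) -> np.ndarray:
    """Leave-one-out composite predictions alpha + g~(Z_i) + f~(T_i)."""
    n = Y.shape[0]
    q = Z.shape[1]
    U = np.column_stack([Z, T])
    KT = _gauss_product(T[:, None], T[:, None], bw.h2)
    KU = _gauss_product(U, U, bw.h3)
    KZq = _gauss_product(Z, Z, bw.h3)
    # leave-one-out training densities at the training points
    dg = np.arange(n)
    fT = (KT.sum(axis=0) - KT[dg, dg]) / (n - 1)
    fZ = (KZq.sum(axis=0) - KZq[dg, dg]) / (n - 1)
    fU = (KU.sum(axis=0) - KU[dg, dg]) / (n - 1)
    keep = _trim_mask(fU)
    ratio_g = np.where(keep, fT / fU, 0.0) * Y
    ratio_f = np.where(keep, fZ / fU, 0.0) * Y
    KG = _gauss_product(Z, Z, bw.h1)
    KF = _gauss_product(T[:, None], T[:, None], bw.h4)
    m = keep.sum() - keep  # retained count excluding self where retained
    m = np.maximum(m, 1)
    g_star = (KG.T @ ratio_g - KG[dg, dg] * ratio_g) / m
    f_star = (KF.T @ ratio_f - KF[dg, dg] * ratio_f) / m
    alpha = (Y.sum() - Y) / (n - 1)
    g_t = g_star - alpha
    f_t = f_star - alpha
    g_t = g_t - g_t.mean()
    f_t = f_t - f_t.mean()
    return alpha + g_t + f_t


def cv_bandwidth(
    sample_reduced: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid_spec: Sequence[float] = (0.5, 0.75, 1.0, 1.5, 2.0),
    seed: int | None = None,
) -> Bandwidths:
    """Bandwidths by leave-one-out CV on a shared multiplicative grid.

    Each role's candidates are c * sigma_hat * n^{-1/(4+dim)} for c in
    ``grid_spec`` (dim = smoothing dimension of the role).  Roles are
    optimized one at a time against the leave-one-out squared error of the
    composite predictor alpha + g~ + f~, holding the other roles at their
    current values.  Deterministic given the inputs; ``seed`` is accepted for
    interface symmetry.
    """
    if len(grid_spec) == 0:
        raise ValueError("grid_spec must be non-empty")
    Z, T, Y = (np.asarray(a, dtype=float) for a in sample_reduced)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = Y.shape[0]
    if n < 20:
        raise ValueError("need at least 20 observations for cross-validation")
    q = Z.shape[1]
    U = np.column_stack([Z, T])
    ref = {
        "h0": reference_bandwidth(U, q + 1),
        "h1": reference_bandwidth(Z, q),
        "h2": reference_bandwidth(T, 1),
        "h3": reference_bandwidth(U, q + 1),
        "h4": reference_bandwidth(T, 1),
    }
    bw = Bandwidths(**ref)
    for role in ("h1", "h2", "h3", "h4"):
        best_val, best_err = getattr(bw, role), np.inf
        for c in grid_spec:
            cand = replace(bw, **{role: c * ref[role]})
            err = float(np.mean((Y - _loo_fit(Z, T, Y, cand)) ** 2))
            if err < best_err - 1e-15:
                best_err, best_val = err, c * ref[role]
        bw = replace(bw, **{role: best_val})
    return bw


@dataclass(frozen=True)
class AdditiveEstimate:
    """Fitted pilot stage: intercept, centered evaluators, bandwidths.

    ``g_tilde``/``f_tilde`` evaluate the centered components at new points;
    the training-sample means of g~(Z_i) and f~(T_i) are zero by
    construction.  Density evaluators for f_Z, f_T and the joint f(z, t) are
    retained for diagnostics.
    """

    alpha_hat: float
    q: int
    g_tilde: Callable[[np.ndarray], np.ndarray]
    f_tilde: Callable[[np.ndarray], np.ndarray]
    g_star: Callable[[np.ndarray], np.ndarray]
    f_star: Callable[[np.ndarray], np.ndarray]
    bandwidths: Bandwidths
    Z_train: np.ndarray
    T_train: np.ndarray
    Y_train: np.ndarray
    density_Z: Callable[[np.ndarray], np.ndarray]
    density_T: Callable[[np.ndarray], np.ndarray]
    density_joint: Callable[[np.ndarray], np.ndarray]
    trimmed_fraction: float = 0.0


def fit_additive(
    sample: RegressionSample,
    reduction: ReductionEstimate,
    bandwidth_policy: str | Bandwidths = "cv",
) -> AdditiveEstimate:
    """Fit the pilot-stage additive decomposition on the reduced data.

    Forms Z = X B_hat, selects bandwidths by cross-validation (or accepts a
    fixed :class:`Bandwidths`), and returns centered evaluators for g~ and f~
    together with the intercept alpha_hat = Ybar.
    """
    if reduction.d_hat < 1:
        raise ValueError("reduction must supply at least one direction")
    Z = sample.X @ reduction.B_hat
    if Z.ndim == 1:
        Z = Z[:, None]
    T, Y = sample.T, sample.Y
    if isinstance(bandwidth_policy, Bandwidths):
        bw = bandwidth_policy
    elif bandwidth_policy == "cv":
        bw = cv_bandwidth((Z, T, Y))
    else:
        raise ValueError("bandwidth_policy must be 'cv' or a Bandwidths instance")
    alpha = estimate_alpha(Y)
    _, _, fU, keep = _density_ratios(Z, T, bw)

    def g_star(z):
        return g_star_hat(z, (Z, T, Y), bw)

    def f_star(t):
        return f_star_hat(t, (Z, T, Y), bw)

    g_tilde, f_tilde = center_components(g_star, f_star, alpha, Z, T)
    U = np.column_stack([Z, T])
    return AdditiveEstimate(
        alpha_hat=alpha,
        q=Z.shape[1],
        g_tilde=g_tilde,
        f_tilde=f_tilde,
        g_star=g_star,
        f_star=f_star,
        bandwidths=bw,
        Z_train=Z,
        T_train=T,
        Y_train=Y,
        density_Z=lambda z: kde(Z, z, bw.h3),
        density_T=lambda t: kde(T, t, bw.h2),
        density_joint=lambda u: kde(U, u, bw.h3),
        trimmed_fraction=float(1.0 - keep.mean()),
    )


def predict(
    additive_estimate: AdditiveEstimate,
    B_hat: np.ndarray,
    x_new: np.ndarray,
    t_new: float,
) -> float:
    """Point prediction alpha + g~(x'B) + f~(t) for one new observation."""
    x = np.asarray(x_new, dtype=float)
    B = np.atleast_2d(np.asarray(B_hat, dtype=float))
    if B.shape[0] == 1 and x.shape[0] > 1:
        B = B.T
    if x.shape[0] != B.shape[0]:
        raise ValueError("x_new has wrong length for the basis")
    z = x @ B
    g = additive_estimate.g_tilde(z[None, :])
    f = additive_estimate.f_tilde(float(t_new))
    return float(additive_estimate.alpha_hat + np.asarray(g).ravel()[0] + np.asarray(f).ravel()[0])
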