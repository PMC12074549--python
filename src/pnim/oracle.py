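"""Oracle-efficient second stage: local-polynomial re-fits on pseudo-responses.

The pilot estimators carry an inflated variance.  A second stage removes it:
subtract the pilot estimate of the *other* component from Y to form a
pseudo-response, then fit a univariate (for f) or q-variate (for g) local
polynomial.  Asymptotically the refit behaves as if the other component were
known exactly — the oracle property — so the finite-sample refit should never
degrade materially on the components it targets.

Pseudo-responses (both starred pilots estimate alpha + centered component):

    Y_{i,-g} = Y_i + alpha_hat - g*(Z_i)   (targets alpha + f~(T_i))
    Y_{i,-f} = Y_i + alpha_hat - f*(T_i)   (targets alpha + g~(Z_i))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .additive import AdditiveEstimate, _gauss_product

__all__ = ["OracleFit", "pseudo_responses", "local_poly_fit", "refine"]


def pseudo_responses(
    Y: np.ndarray,
    alpha_hat: float,
    g_star_vals: np.ndarray,
    f_star_vals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-responses removing each pilot component in turn.

    Returns ``(Y_minus_g, Y_minus_f)`` where
    Y_minus_g = Y + alpha - g*(Z) and Y_minus_f = Y + alpha - f*(T).
    """
    Y = np.asarray(Y, dtype=float)
    g_vals = np.asarray(g_star_vals, dtype=float)
    f_vals = np.asarray(f_star_vals, dtype=float)
    if not (Y.shape == g_vals.shape == f_vals.shape):
        raise ValueError("Y, g_star_vals, f_star_vals must have equal length")
    return Y + alpha_hat - g_vals, Y + alpha_hat - f_vals


def local_poly_fit(
    x0: np.ndarray,
    X_local: np.ndarray,
    Y_pseudo: np.ndarray,
    h: float,
    degree: int = 1,
) -> float:
    """Intercept of the kernel-weighted polynomial fit centered at x0.

    Works for scalar x0 (univariate smoothing) and q-vector x0 with a
    product Gaussian kernel.  ``degree`` >= 1; the multivariate design uses
    all pure monomials of each coordinate up to ``degree`` (multi-indices
    |lambda| <= degree truncated to per-coordinate powers, sufficient for the
    default local-linear case).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if h <= 0:
        raise ValueError("bandwidth must be strictly positive")
    X = np.asarray(X_local, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    x0v = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0v.shape[0] != X.shape[1]:
        raise ValueError("x0 has wrong dimension")
    Y = np.asarray(Y_pseudo, dtype=float)
    w = _gauss_product(X, x0v[None, :], h).ravel()
    centered = X - x0v
    D = np.hstack(
        [np.ones((X.shape[0], 1))] + [centered**deg for deg in range(1, degree + 1)]
    )
    sw = np.sqrt(w)
    A = D * sw[:, None]
    b = Y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 1 or not np.isfinite(coef[0]):
        raise ValueError("insufficient local data near x0")
    return float(coef[0])


@dataclass(frozen=True)
class OracleFit:
    """Refined evaluators and their settings."""

    degree: int
    h5: float
    h6: float
    g_star_refined: Callable[[np.ndarray], np.ndarray]
    f_star_refined: Callable[[np.ndarray], np.ndarray]
    g_refined: Callable[[np.ndarray], np.ndarray]
    f_refined: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.h5 <= 0 or self.h6 <= 0:
            raise ValueError("bandwidths must be strictly positive")


def refine(
    additive_estimate: AdditiveEstimate,
    sample_reduced: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    h5: float | None = None,
    h6: float | None = None,
    degree: int = 1,
) -> OracleFit:
    """Second-stage local-polynomial refits of both components.

    g*_e(z) fits the pseudo-response Y_{-f} on Z at bandwidth h5 (default:
    the pilot h1); f*_e(t) fits Y_{-g} on T at h6 (default: the pilot h4).
    The centered evaluators subtract alpha_hat.  Deterministic given the
    pilot fit.
    """
    est = additive_estimate
    if sample_reduced is None:
        Z, T, Y = est.Z_train, est.T_train, est.Y_train
    else:
        Z, T, Y = (np.asarray(a, dtype=float) for a in sample_reduced)
        if Z.ndim == 1:
            Z = Z[:, None]
    h5 = est.bandwidths.h1 if h5 is None else h5
    h6 = est.bandwidths.h4 if h6 is None else h6
    alpha = est.alpha_hat
    g_vals = np.asarray(est.g_star(Z), dtype=float)
    f_vals = np.asarray(est.f_star(T), dtype=float)
    Y_minus_g, Y_minus_f = pseudo_responses(Y, alpha, g_vals, f_vals)

    def g_star_refined(z):
        z_arr = np.asarray(z, dtype=float)
        scalar = z_arr.ndim == 0 or (z_arr.ndim == 1 and Z.shape[1] > 1)
        if z_arr.ndim == 0:
            z_arr = z_arr[None, None]
        elif z_arr.ndim == 1:
            z_arr = z_arr[None, :] if Z.shape[1] > 1 else z_arr[:, None]
        out = np.array([local_poly_fit(z0, Z, Y_minus_f, h5, degree) for z0 in z_arr])
        return float(out[0]) if scalar else out

    def f_star_refined(t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        scalar = np.asarray(t).ndim == 0
        out = np.array([local_poly_fit(t0, T, Y_minus_g, h6, degree) for t0 in t_arr])
        return float(out[0]) if scalar else out

    return OracleFit(
        degree=degree,
        h5=float(h5),
        h6=float(h6),
        g_star_refined=g_star_refined,
        f_star_refined=f_star_refined,
        g_refined=lambda z: g_star_refined(z) - alpha,
        f_refined=lambda t: f_star_refined(t) - alpha,
    )
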