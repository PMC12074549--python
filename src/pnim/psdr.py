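"""Partial sufficient dimension reduction for a continuous conditioning covariate.

The partial central subspace S_{Y|X}(T) is the smallest subspace of the
X-space such that Y is independent of X given (the projection of X onto it,
T).  With a continuous T it is estimated by partial discretization
expectation estimation (PDEE):

1. dichotomize T at a threshold s, giving strata {T <= s} and {T > s};
2. run sliced inverse regression (SIR) within each stratum, select each
   stratum's direction count with the BIC-type rank criterion, and pool the
   per-stratum projections weighted by stratum proportion into the candidate
   matrix M_n(s);
3. average M_n(s) over thresholds s drawn from the observed T values;
4. eigendecompose the average, select the structural dimension d with the
   same BIC-type criterion (penalty constant C_n = n^(1/3) p^(2/3)), and map
   the leading eigenvectors back to the original X scale.

All SIR computations happen in the standardized scale
Z = Sigma_X^{-1/2}(X - mean); the final basis is back-transformed through
Sigma_X^{-1/2} and column-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import RegressionSample

__all__ = [
    "CandidateMatrix",
    "SpectralResult",
    "ReductionEstimate",
    "slice_labels",
    "sir_matrix",
    "partial_candidate_matrix",
    "pdee_average",
    "select_dimension",
    "estimate_basis",
    "fit_psdr",
    "bic_scores",
    "DegenerateSpectrumError",
    "StratumTooSmallError",
]


class DegenerateSpectrumError(ValueError):
    """All candidate-matrix eigenvalues vanish; no dimension can be selected."""


class StratumTooSmallError(ValueError):
    """A discretization threshold left one stratum with too few observations."""


@dataclass(frozen=True)
class CandidateMatrix:
    """Symmetric PSD p-by-p candidate matrix whose span estimates the subspace."""

    M: np.ndarray
    n_strata_used: int = 1

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if np.abs(M - M.T).max() > 1e-8:
            raise ValueError("M must be symmetric")
        object.__setattr__(self, "M", (M + M.T) / 2.0)

    @property
    def p(self) -> int:
        return self.M.shape[0]

    def eigendecomposition(self) -> "SpectralResult":
        vals, vecs = np.linalg.eigh(self.M)
        order = np.argsort(vals)[::-1]
        return SpectralResult(eigenvalues=vals[order], eigenvectors=vecs[:, order])


@dataclass(frozen=True)
class SpectralResult:
    """Eigenvalues sorted descending with matching orthonormal eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass(frozen=True)
class ReductionEstimate:
    """Output of the full reduction: selected dimension, basis, spectrum."""

    d_hat: int
    B_hat: np.ndarray
    eigenvalues: np.ndarray
    K: int
    l: int
    C_n: float
    n_strata_used: int = 0


def slice_labels(Y: np.ndarray, K: int) -> np.ndarray:
    """Assign each observation to one of K response slices of near-equal size.

    Observations are ranked by Y with stable tie-breaking by original index,
    then the ranks are chunked into K contiguous groups whose sizes differ by
    at most one.  Returns integer labels in 1..K.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("cannot form more slices than observations")
    order = np.argsort(Y, kind="stable")
    # slice k (0-based) gets sorted rows ceil(n*k/K) .. ceil(n*(k+1)/K)-1, so
    # any size remainder goes to the earlier slices
    bounds = -((-n * np.arange(K + 1)) // K)
    labels = np.empty(n, dtype=int)
    for k in range(K):
        labels[order[bounds[k]:bounds[k + 1]]] = k + 1
    return labels


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center X and whiten with the ridge-guarded inverse square root of cov."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    S = np.cov(Xc, rowvar=False, bias=False)
    S = np.atleast_2d(S)
    p = S.shape[0]
    ridge = 1e-8 * np.trace(S) / p
    S = S + ridge * np.eye(p)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite beyond ridge guard")
    inv_sqrt = (vecs / np.sqrt(vals)) @ vecs.T
    return Xc @ inv_sqrt, mean, inv_sqrt


def sir_matrix(X: np.ndarray, Y: np.ndarray, K: int) -> tuple[CandidateMatrix, np.ndarray]:
    """Sliced-inverse-regression kernel matrix in the standardized scale.

    Standardizes Z = Sigma^{-1/2}(X - mean) on the given sample and returns
    V = sum_k p_k m_k m_k', where p_k is the proportion of slice k and m_k the
    slice mean of Z.  V is symmetric PSD with rank at most K - 1.  The
    per-slice means are returned alongside (rows = slices).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(Y).shape[0] != 1:
        X = X.T
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 2 * K:
        raise ValueError("need at least 2K observations for K slices")
    Z, _, _ = _standardize(X)
    labels = slice_labels(Y, K)
    p = Z.shape[1]
    V = np.zeros((p, p))
    means = np.zeros((K, p))
    for k in range(1, K + 1):
        idx = labels == k
        pk = idx.mean()
        mk = Z[idx].mean(axis=0)
        means[k - 1] = mk
        V += pk * np.outer(mk, mk)
    V = (V + V.T) / 2.0
    return CandidateMatrix(M=V, n_strata_used=1), means


def bic_scores(eigenvalues: np.ndarray, n: int, p: int) -> np.ndarray:
    """G(k) for k = 1..p of the BIC-type rank criterion.

    G(k) = n * sum_{j<=k} phi(l_j) / (2 * sum_{j<=p} phi(l_j))
           - 2 * C_n * k(k+1) / (2p),
    with phi(l) = log(l + 1) - l (non-positive) and C_n = n^(1/3) p^(2/3).
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    phi = np.log1p(lam) - lam
    total = phi.sum()
    if total >= 0.0:
        raise DegenerateSpectrumError("eigenvalue spectrum is degenerate (all zero)")
    C_n = n ** (1.0 / 3.0) * p ** (2.0 / 3.0)
    k = np.arange(1, p + 1)
    return n * np.cumsum(phi) / (2.0 * total) - 2.0 * C_n * k * (k + 1) / (2.0 * p)


def select_dimension(eigenvalues: np.ndarray, n: int, p: int) -> int:
    """Structural dimension maximizing the BIC-type criterion; ties go low."""
    scores = bic_scores(eigenvalues, n, p)
    return int(np.argmax(scores)) + 1


def _stratum_directions(X: np.ndarray, Y: np.ndarray, K: int) -> np.ndarray:
    """Top-q SIR eigenvectors of one stratum, q chosen by the BIC criterion."""
    V, _ = sir_matrix(X, Y, K)
    spec = V.eigendecomposition()
    q = select_dimension(spec.eigenvalues, X.shape[0], X.shape[1])
    return spec.eigenvectors[:, :q]


def partial_candidate_matrix(
    X: np.ndarray, Y: np.ndarray, T: np.ndarray, s: float, K: int
) -> CandidateMatrix:
    """Candidate matrix M_n(s) from dichotomizing T at threshold s.

    Runs SIR within {T <= s} and {T > s}, picks each stratum's direction
    count with the BIC criterion, and pools the per-stratum projections
    weighted by stratum proportion:

        M_n(s) = (n1/n) B1 B1' + (n2/n) B2 B2'.

    Each B_j holds orthonormal SIR eigenvectors, so M_n(s) is a convex
    combination of projections: symmetric with eigenvalues in [0, 1] and
    trace q1*n1/n + q2*n2/n >= 1.  Raises :class:`StratumTooSmallError` when
    either stratum has fewer than 2K observations, which callers treat as
    "skip this s".
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T, dtype=float)
    low = T <= s
    if low.sum() < 2 * K or (~low).sum() < 2 * K:
        raise StratumTooSmallError(f"threshold s={s} leaves an undersized stratum")
    w1 = low.mean()
    B1 = _stratum_directions(X[low], Y[low], K)
    B2 = _stratum_directions(X[~low], Y[~low], K)
    M = w1 * (B1 @ B1.T) + (1.0 - w1) * (B2 @ B2.T)
    return CandidateMatrix(M=(M + M.T) / 2.0, n_strata_used=1)


def pdee_average(
    X: np.ndarray,
    Y: np.ndarray,
    T: np.ndarray,
    K: int,
    l: int,
    seed: int | None = None,
) -> CandidateMatrix:
    """Average M_n(s) over l thresholds drawn from the observed T values.

    Thresholds are sampled without replacement from the central 80% of the
    empirical T distribution (guarding against degenerate strata); thresholds
    that still leave an undersized stratum are skipped and counted out of
    ``n_strata_used``.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if n < 4 * K:
        raise ValueError("need at least 4K observations")
    lo, hi = np.quantile(T, [0.1, 0.9])
    pool = T[(T >= lo) & (T <= hi)]
    rng = np.random.default_rng(seed)
    m = min(l, pool.shape[0])
    thresholds = rng.choice(pool, size=m, replace=False)
    acc = None
    used = 0
    for s in thresholds:
        try:
            Ms = partial_candidate_matrix(X, Y, T, float(s), K)
        except StratumTooSmallError:
            continue
        acc = Ms.M if acc is None else acc + Ms.M
        used += 1
    if used == 0:
        raise StratumTooSmallError("no valid discretization threshold found")
    return CandidateMatrix(M=acc / used, n_strata_used=used)


def estimate_basis(M_hat: CandidateMatrix, d_hat: int, X: np.ndarray) -> np.ndarray:
    """Top-d eigenvectors of M_hat mapped back to the original X scale.

    The candidate matrix lives in the standardized Z scale; directions are
    back-transformed via Sigma_X^{-1/2} and rescaled to unit norm.  A tiny
    eigen-gap between d and d+1 triggers a warning (unstable basis).
    """
    spec = M_hat.eigendecomposition()
    p = M_hat.p
    if not (1 <= d_hat <= p):
        raise ValueError("d_hat must lie in 1..p")
    if d_hat < p and spec.eigenvalues[d_hat - 1] - spec.eigenvalues[d_hat] < 1e-12:
        warnings.warn("eigen-gap below 1e-12 at the selected dimension; basis unstable",
                      RuntimeWarning, stacklevel=2)
    _, _, inv_sqrt = _standardize(np.asarray(X, dtype=float))
    B = inv_sqrt @ spec.eigenvectors[:, :d_hat]
    return B / np.linalg.norm(B, axis=0)


def fit_psdr(
    sample: RegressionSample,
    K: int = 5,
    l: int = 10,
    seed: int | None = None,
) -> ReductionEstimate:
    """Full reduction: PDEE average, spectrum, BIC dimension, basis.

    Parameters
    ----------
    sample : the observed (Y, X, T) triples.
    K : number of response slices per stratum SIR (>= 2).
    l : number of discretization thresholds for the PDEE average.
    seed : seed for the threshold draw; same inputs and seed reproduce the
        estimate exactly.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    M_hat = pdee_average(sample.X, sample.Y, sample.T, K, l, seed)
    spec = M_hat.eigendecomposition()
    n, p = sample.n, sample.p
    d_hat = select_dimension(spec.eigenvalues, n, p)
    B_hat = estimate_basis(M_hat, d_hat, sample.X)
    C_n = n ** (1.0 / 3.0) * p ** (2.0 / 3.0)
    return ReductionEstimate(
        d_hat=d_hat,
        B_hat=B_hat,
        eigenvalues=spec.eigenvalues,
        K=K,
        l=l,
        C_n=C_n,
        n_strata_used=M_hat.n_strata_used,
    )
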