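"""Subspace-recovery metric and the replicate study runner.

The squared trace correlation between the true and estimated index vectors
U = X'B_true and V = X'B_hat is

    r^2 = tr(A) / dim(A),
    A   = Sigma_V^{-1/2} Sigma_VU Sigma_U^{-1} Sigma_UV Sigma_V^{-1/2},

the mean of the squared canonical correlations: 1 when the two spans agree,
0 when they are uncorrelated, and invariant to any invertible
reparameterization of either basis.  Covariances are sample covariances on
the replicate's own X.

``run_study`` regenerates one benchmark cell — simulate, reduce, score —
over seeded replicates and aggregates the r^2 mean/sd and the fraction of
replicates whose BIC-selected dimension matches the truth.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .psdr import fit_psdr
from .simulate import SimulationConfig, generate

__all__ = ["StudyResult", "trace_correlation", "run_study", "run_table", "TABLE_GRIDS"]


def _inv_sqrt_psd(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("singular covariance in trace correlation")
    return (vecs / np.sqrt(vals)) @ vecs.T


def trace_correlation(X: np.ndarray, B_true: np.ndarray, B_hat: np.ndarray) -> float:
    """Squared trace correlation r^2 between X B_true and X B_hat.

    Handles rectangular comparisons (column counts need not match): A is
    square of size dim(V) = columns of ``B_hat``.  Returns a value in
    [0, 1 + 1e-8].
    """
    X = np.asarray(X, dtype=float)
    Bt = np.atleast_2d(np.asarray(B_true, dtype=float).T).T
    Bh = np.atleast_2d(np.asarray(B_hat, dtype=float).T).T
    U = X @ Bt
    V = X @ Bh
    qu, qv = U.shape[1], V.shape[1]
    C = np.cov(np.hstack([U, V]), rowvar=False)
    Su = C[:qu, :qu]
    Sv = C[qu:, qu:]
    Suv = C[:qu, qu:]
    Sv_m = _inv_sqrt_psd(Sv)
    A = Sv_m @ Suv.T @ np.linalg.inv(Su) @ Suv @ Sv_m
    r2 = float(np.trace(A) / A.shape[0])
    if not (-1e-8 <= r2 <= 1.0 + 1e-8):
        raise ValueError(f"trace correlation {r2} outside [0, 1]")
    return min(max(r2, 0.0), 1.0 + 1e-8)


@dataclass(frozen=True)
class StudyResult:
    """Replicate-aggregated benchmark cell."""

    model_id: str
    n: int
    K: int
    l: int
    reps: int
    r2_mean: float
    r2_sd: float
    dim_correct_prop: float
    elapsed_seconds: float
    seed: int
    gamma: Optional[float] = None
    failures: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 <= self.dim_correct_prop <= 1.0):
            raise ValueError("dim_correct_prop must lie in [0, 1]")


def _child_seed(study_seed: int, rep: int) -> np.random.SeedSequence:
    # counter-based derivation: replicate r of a study is reproducible alone
    return np.random.SeedSequence(entropy=study_seed, spawn_key=(rep,))


def run_study(
    model_id: str,
    n: int,
    K: int = 5,
    l: int = 10,
    reps: int = 100,
    seed: int = 0,
    gamma: float = 0.2,
) -> StudyResult:
    """One benchmark cell: simulate, reduce, score, over seeded replicates.

    Each replicate draws fresh data from ``model_id`` with a counter-derived
    child seed, runs the full reduction at (K, l), and records the trace
    correlation against the true basis and whether d_hat equals the true
    structural dimension.  Replicate-level numerical failures are excluded
    and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    t0 = time.perf_counter()
    r2s: list[float] = []
    correct = 0
    failures = 0
    for rep in range(reps):
        ss = _child_seed(seed, rep)
        data_seed, fit_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        config = SimulationConfig(model_id=model_id, n=n, seed=data_seed, gamma=gamma)
        sample, truth = generate(config)
        try:
            red = fit_psdr(sample, K=K, l=l, seed=fit_seed)
            r2s.append(trace_correlation(sample.X, truth.B_true, red.B_hat))
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
            continue
        correct += int(red.d_hat == truth.q_true)
    if not r2s:
        raise RuntimeError("every replicate failed")
    done = len(r2s)
    return StudyResult(
        model_id=model_id,
        n=n,
        K=K,
        l=l,
        reps=reps,
        r2_mean=float(np.mean(r2s)),
        r2_sd=float(np.std(r2s, ddof=1)) if done > 1 else float("nan"),
        dim_correct_prop=correct / done,
        elapsed_seconds=time.perf_counter() - t0,
        seed=seed,
        gamma=gamma if model_id == "II" else None,
        failures=failures,
    )


#: the benchmark grids: (model_id, n, gamma) per table row, all at K = 5
TABLE_GRIDS = {
    "table1": [
        *[("I-A", n, None) for n in (500, 1000, 2000)],
        *[("I-B", n, None) for n in (500, 1000, 2000)],
        *[("II", n, g) for g in (0.2, 0.4, 0.6) for n in (500, 1000, 2000)],
    ],
    "table2": [
        *[("III-A", n, None) for n in (500, 1000, 2000)],
        *[("III-B", n, None) for n in (500, 1000, 2000)],
    ],
}


def run_table(
    table_id: str,
    reps: int = 100,
    seed: int = 0,
    K: int = 5,
    l: int = 10,
) -> list[StudyResult]:
    """Sweep one benchmark table's (model, n, gamma) grid at K = 5."""
    if table_id not in TABLE_GRIDS:
        raise ValueError("table_id must be 'table1' or 'table2'")
    results = []
    for i, (model_id, n, gamma) in enumerate(TABLE_GRIDS[table_id]):
        results.append(
            run_study(
                model_id,
                n,
                K=K,
                l=l,
                reps=reps,
                seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2**31)),
                gamma=gamma if gamma is not None else 0.2,
            )
        )
    return results
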