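"""Statsmodels-style front end: a model object fitted to data.

`PartiallyNonlinearIndexModel(y, X, t)` holds the data and fitting options;
`fit()` runs the two-stage procedure (partial sufficient dimension reduction,
then density-ratio weighted kernel estimation of the additive components,
optionally the oracle local-polynomial refinement) and returns a
:class:`PNIMResults` carrying the estimates, diagnostics, evaluators and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import additive as _additive
from . import oracle as _oracle
from . import psdr as _psdr
from .simulate import RegressionSample

__all__ = ["PartiallyNonlinearIndexModel", "PNIMResults"]


class PartiallyNonlinearIndexModel:
    """Partially nonlinear index model Y = a + g(X'B) + f(T) + e.

    Parameters
    ----------
    endog : length-n response vector Y.
    exog : (n, p) covariate block X entering through linear indices only.
    nonlinear : length-n conditioning covariate T with unrestricted effect f.
    exog_names : optional column names for X (defaults to x1..xp).

    Examples
    --------
    >>> from pnim import generate_model_I, PartiallyNonlinearIndexModel
    >>> sample, truth = generate_model_I(400, "B", seed=7)
    >>> res = PartiallyNonlinearIndexModel(sample.Y, sample.X, sample.T).fit(
    ...     slices=5, n_thresholds=10, seed=1, bandwidths="cv")
    >>> res.d_hat
    1
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        nonlinear: np.ndarray,
        exog_names: Optional[list[str]] = None,
    ) -> None:
        self.sample = RegressionSample(
            Y=np.asarray(endog, dtype=float),
            X=np.asarray(exog, dtype=float),
            T=np.asarray(nonlinear, dtype=float),
        )
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j + 1}" for j in range(self.sample.p)]
        )
        if len(self.exog_names) != self.sample.p:
            raise ValueError("exog_names length must equal the number of columns of X")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        y: str = "y",
        t: str = "t",
        x: Optional[list[str]] = None,
    ) -> "PartiallyNonlinearIndexModel":
        """Build from a DataFrame with a response, conditioning and X columns.

        ``x`` defaults to every column other than ``y`` and ``t``.
        """
        if y not in data.columns or t not in data.columns:
            raise ValueError(f"data must contain columns {y!r} and {t!r}")
        x_cols = x if x is not None else [c for c in data.columns if c not in (y, t)]
        return cls(
            data[y].to_numpy(float),
            data[x_cols].to_numpy(float),
            data[t].to_numpy(float),
            exog_names=list(x_cols),
        )

    @classmethod
    def from_sample(cls, sample: RegressionSample) -> "PartiallyNonlinearIndexModel":
        return cls(sample.Y, sample.X, sample.T)

    def fit(
        self,
        slices: int = 5,
        n_thresholds: int = 10,
        seed: Optional[int] = None,
        bandwidths: "str | _additive.Bandwidths" = "cv",
        refine: bool = False,
    ) -> "PNIMResults":
        """Run both estimation stages and return the results object.

        Parameters
        ----------
        slices : response slices K per stratum SIR.
        n_thresholds : discretization thresholds l averaged in the reduction.
        seed : seed for the threshold draw (reduction stage).
        bandwidths : 'cv' for leave-one-out selection, or fixed Bandwidths.
        refine : also run the oracle-efficient local-polynomial second stage.
        """
        reduction = _psdr.fit_psdr(self.sample, K=slices, l=n_thresholds, seed=seed)
        pilot = _additive.fit_additive(self.sample, reduction, bandwidths)
        refined = _oracle.refine(pilot) if refine else None
        return PNIMResults(self, reduction, pilot, refined)


class PNIMResults:
    """Fitted PNIM: reduction estimate, additive components, evaluators."""

    def __init__(self, model, reduction, pilot, refined=None) -> None:
        self.model = model
        self.reduction = reduction
        self.pilot = pilot
        self.refined = refined

    # -- primary estimates -------------------------------------------------
    @property
    def d_hat(self) -> int:
        """Selected structural dimension of the partial central subspace."""
        return self.reduction.d_hat

    @property
    def basis(self) -> np.ndarray:
        """(p, d_hat) estimated index directions, unit-norm columns."""
        return self.reduction.B_hat

    @property
    def params(self) -> pd.DataFrame:
        """Basis directions as a named DataFrame (rows = covariates)."""
        return pd.DataFrame(
            self.basis,
            index=self.model.exog_names,
            columns=[f"direction_{j + 1}" for j in range(self.d_hat)],
        )

    @property
    def alpha(self) -> float:
        return self.pilot.alpha_hat

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.reduction.eigenvalues

    # -- evaluators --------------------------------------------------------
    def g(self, z):
        """Centered index component g~ at reduced coordinates z."""
        return self.pilot.g_tilde(z)

    def f(self, t):
        """Centered nonlinear component f~ at t."""
        return self.pilot.f_tilde(t)

    def predict(self, x_new: np.ndarray, t_new: float) -> float:
        """alpha + g~(x'B) + f~(t) for a new observation."""
        return _additive.predict(self.pilot, self.basis, x_new, t_new)

    def fittedvalues(self) -> np.ndarray:
        Z = self.pilot.Z_train
        return self.alpha + np.asarray(self.g(Z)) + np.asarray(self.f(self.pilot.T_train))

    def resid(self) -> np.ndarray:
        return self.model.sample.Y - self.fittedvalues()

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of both stages."""
        sam = self.model.sample
        ev = np.array2string(self.eigenvalues[: min(6, sam.p)], precision=4)
        bw = self.pilot.bandwidths
        lines = [
            "Partially Nonlinear Index Model",
            "=" * 46,
            f"No. observations: {sam.n:>8d}    covariates p: {sam.p}",
            f"slices K: {self.reduction.K:>3d}   thresholds l: {self.reduction.l}"
            f"   C_n: {self.reduction.C_n:.2f}",
            f"structural dimension d_hat: {self.d_hat}",
            f"leading eigenvalues: {ev}",
            f"intercept alpha_hat: {self.alpha: .4f}",
            f"bandwidths: h1={bw.h1:.3f} h2={bw.h2:.3f} h3={bw.h3:.3f} h4={bw.h4:.3f}",
            f"trimmed fraction: {self.pilot.trimmed_fraction:.3%}",
            "",
            "Index directions (unit-norm columns):",
            self.params.round(4).to_string(),
        ]
        if self.refined is not None:
            lines.append(
                f"\noracle refinement: degree {self.refined.degree}, "
                f"h5={self.refined.h5:.3f} h6={self.refined.h6:.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PNIMResults d_hat={self.d_hat} n={self.model.sample.n}>"
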