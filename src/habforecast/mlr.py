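"""Multivariate linear regression from sensor channels to phytoplankton.

The dependent lab count Y is modelled as an affine function of the channel
vector X:  Y = β0 + β1·CHL470 + β2·Turbidity + β3·CHL530 + ε.  The
coefficients are the ordinary least-squares solution; once fitted, future
channel forecasts X_f map to a phytoplankton forecast Y_f = X_f β.

The solver uses an orthogonal decomposition (SVD via ``lstsq``) rather than
forming (X'X)^{-1} explicitly; on well-conditioned problems the two agree to
machine precision and the normal-equations form survives only as a test
oracle.  Coefficient standard errors are reported so downstream checks can
state recovery in units of estimated uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import align_dependent
from .preprocess import MultiChannelDataset

__all__ = [
    "ChannelRegression",
    "ChannelRegressionResults",
    "fit_mlr",
    "predict_mlr",
]


class RankDeficientDesignError(ValueError):
    """Raised when the intercept-augmented design is not full column rank."""


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(len(X)), X])


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # name the columns whose removal restores full rank (QR pivot heuristic)
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if (diag < tol).any() else piv[np.linalg.matrix_rank(design):]
    return [names[i] for i in sorted(bad)]


class ChannelRegression:
    """OLS model of a dependent series on channel values plus an intercept."""

    def __init__(self, endog: np.ndarray, exog: np.ndarray, channel_names: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != len(self.endog):
            raise ValueError(
                f"{exog.shape[0]} design rows but {len(self.endog)} dependent values"
            )
        self.exog = exog
        self.channel_names = list(channel_names) if channel_names else [
            f"x{i + 1}" for i in range(exog.shape[1])
        ]
        if len(self.channel_names) != exog.shape[1]:
            raise ValueError("channel_names length does not match the design width")

    @classmethod
    def from_dataset(
        cls, dataset: MultiChannelDataset, max_gap: pd.Timedelta | str = "30min"
    ) -> "ChannelRegression":
        """Build the design by nearest-timestamp alignment of the sparse
        dependent series to the channel grid (same rule as the correlation
        analysis)."""
        rows, y = align_dependent(dataset, max_gap)
        return cls(y, rows.to_numpy(dtype=float), list(rows.columns))

    def fit(self) -> "ChannelRegressionResults":
        X = _design(self.exog)
        n, p = X.shape
        if n < p:
            raise ValueError(f"need at least {p} rows for {p} coefficients, got {n}")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            names = ["intercept", *self.channel_names]
            bad = _collinear_columns(X, names)
            raise RankDeficientDesignError(
                f"design is rank deficient (rank {rank} < {p}); "
                f"collinear columns: {', '.join(bad)}"
            )
        beta, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        fitted = X @ beta
        resid = self.endog - fitted
        dof = n - p
        scale = float(resid @ resid / dof) if dof > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.maximum(scale, 0) * np.diag(xtx_inv)) if dof > 0 else np.full(p, np.nan)
        tss = float(((self.endog - self.endog.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
        return ChannelRegressionResults(
            model=self,
            params=beta,
            resid=resid,
            fittedvalues=fitted,
            bse=bse,
            scale=scale,
            rsquared=r2,
        )


@dataclass
class ChannelRegressionResults:
    """Fitted coefficients with uncertainties and fit diagnostics."""

    model: ChannelRegression
    params: np.ndarray
    resid: np.ndarray
    fittedvalues: np.ndarray
    bse: np.ndarray
    scale: float
    rsquared: float

    @property
    def nobs(self) -> int:
        return len(self.resid)

    @property
    def param_names(self) -> list[str]:
        return ["intercept", *self.model.channel_names]

    def predict(self, X_f: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Ŷ = β0 + Σ βi·xi per row of the future design ``X_f``.

        A DataFrame is checked (and reordered) against the training channel
        names; a bare array is trusted to be in design order.
        """
        if isinstance(X_f, pd.DataFrame):
            missing = [c for c in self.model.channel_names if c not in X_f.columns]
            if missing:
                raise ValueError(f"missing channel columns: {', '.join(missing)}")
            X_f = X_f[self.model.channel_names].to_numpy(dtype=float)
        X_f = np.atleast_2d(np.asarray(X_f, dtype=float))
        if X_f.shape[1] != len(self.model.channel_names):
            raise ValueError(
                f"expected {len(self.model.channel_names)} channels, got {X_f.shape[1]}"
            )
        return _design(X_f) @ self.params

    def summary(self) -> str:
        lines = [
            "Channel regression (OLS)",
            f"  observations: {self.nobs}    R^2: {self.rsquared:.4f}"
            f"    residual variance: {self.scale:.6g}",
            f"  {'term':<12}{'coef':>14}{'std err':>14}",
        ]
        for name, b, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<12}{b:>14.6g}{se:>14.6g}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        lines = [f"n\t{self.nobs}", f"r_squared\t{self.rsquared!r}"]
        for name, b in zip(self.param_names, self.params):
            lines.append(f"beta\t{name}\t{b!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def fit_mlr(
    X: np.ndarray, Y: np.ndarray, channel_names: list[str] | None = None
) -> ChannelRegressionResults:
    """Least-squares fit of Y on channel rows X (intercept added)."""
    return ChannelRegression(Y, X, channel_names).fit()


def predict_mlr(results: ChannelRegressionResults, X_f: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Map future channel values through the fitted coefficients."""
    return results.predict(X_f)
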