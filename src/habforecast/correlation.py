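"""Pearson correlation analysis among sensor channels and the lab counts.

The two fluorescence excitations track the same biomass, and turbidity rises
with suspended biomass, so cross-channel correlations are expected to be
strongly positive while the sparse laboratory phytoplankton counts correlate
more weakly (lab sampling noise, patchiness).  The correlation matrix is the
screening step that justifies the linear channel→phytoplankton regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MultiChannelDataset

__all__ = ["pearson", "correlation_matrix", "CorrelationMatrix", "align_dependent"]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's r: the covariance of x and y over the product of their
    standard deviations (sample, n−1 convention — the n's cancel anyway)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1-d vectors, got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        which = "x" if sx == 0 else "y"
        raise ValueError(f"constant vector {which}: standard deviation is zero")
    return float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))


@dataclass
class CorrelationMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names),) * 2:
            raise ValueError("matrix shape does not match the variable names")
        if not np.allclose(v, v.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12) or not np.allclose(np.diag(v), 1.0):
            raise ValueError("entries must lie in [-1, 1] with a unit diagonal")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.names.index(k) for k in pair)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.6f")


def align_dependent(
    dataset: MultiChannelDataset, max_gap: pd.Timedelta | str = "30min"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pair each sparse dependent observation with the nearest grid sample.

    Lab counts arrive at irregular instants; each is matched to the nearest
    channel timestamp within ``max_gap`` (default ±30 min), otherwise the
    pair is dropped.  Returns the matched channel rows and dependent values.
    """
    if dataset.dependent is None or dataset.dependent.empty:
        raise ValueError("dataset has no dependent series to align")
    max_gap = pd.Timedelta(max_gap)
    grid = dataset.grid
    dep = dataset.dependent
    pos = grid.get_indexer(dep.index, method="nearest")
    gaps = np.abs(grid[pos].asi8 - dep.index.asi8)
    keep = gaps <= max_gap.value
    if not keep.any():
        raise ValueError("no dependent observation lies within max_gap of the grid")
    rows = dataset.frame().iloc[pos[keep]]
    return rows, dep.to_numpy(dtype=float)[keep]


def correlation_matrix(
    dataset: MultiChannelDataset,
    max_gap: pd.Timedelta | str = "30min",
    dependent_name: str = "phytoplankton",
) -> CorrelationMatrix:
    """Full symmetric Pearson matrix over the channels (and, when present,
    the nearest-timestamp-aligned dependent series)."""
    frame = dataset.frame()
    names = list(frame.columns)
    blocks: dict[str, np.ndarray] = {n: frame[n].to_numpy(dtype=float) for n in names}
    if dataset.dependent is not None and not dataset.dependent.empty:
        rows, dep_vals = align_dependent(dataset, max_gap)
        names_all = names + [dependent_name]
        k = len(names_all)
        out = np.eye(k)
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                out[i, j] = out[j, i] = pearson(blocks[a], blocks[names[j]])
            r = pearson(rows[a].to_numpy(dtype=float), dep_vals)
            out[i, k - 1] = out[k - 1, i] = r
        return CorrelationMatrix(names_all, out)
    k = len(names)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pearson(blocks[names[i]], blocks[names[j]])
    return CorrelationMatrix(names, out)
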