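"""Loading, validation and cleaning of multichannel sensor time series.

A moored multi-wavelength fluorometer reports chlorophyll-a fluorescence at
two excitations (CHL470, CHL530, both in µg/L) plus turbidity on a fixed
10-minute grid.  Raw records carry the usual field-deployment defects:
missing intervals from telemetry dropouts, and spike/drift outliers from
biofouling of the optical windows.  This module provides the containers for
such series and the cleaning pipeline applied before decomposition and
forecasting: linear gap imputation, robust (rolling median/MAD) outlier
removal, a centred moving average, and the chronological train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "MultiChannelDataset",
    "CleaningReport",
    "read_sensor_csv",
    "write_sensor_csv",
    "impute_linear",
    "remove_outliers",
    "centred_moving_average",
    "chronological_split",
    "split_index",
    "clean_dataset",
]

DEFAULT_CADENCE = pd.Timedelta(minutes=10)

#: column name holding the sparse dependent (lab phytoplankton count) series
DEPENDENT_COLUMN = "phytoplankton"


class GridError(ValueError):
    """Raised when a timestamp grid violates the uniform-spacing contract."""


@dataclass
class SensorSeries:
    """One channel's uniformly sampled, possibly-gappy time series.

    Missing observations are encoded as NaN in ``values``.  Timestamps must
    be strictly increasing with constant spacing.
    """

    name: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError(
                f"channel {self.name!r}: {len(self.timestamps)} timestamps "
                f"vs {len(self.values)} values"
            )
        _validate_grid(self.timestamps)
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(finite)):
            raise ValueError(f"channel {self.name!r}: non-finite values present")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def cadence(self) -> pd.Timedelta:
        return pd.Timedelta(self.timestamps[1] - self.timestamps[0])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "SensorSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name=self.name)


@dataclass
class MultiChannelDataset:
    """A set of sensor channels on one shared timestamp grid.

    ``dependent`` is the sparse laboratory phytoplankton count (cells/mL),
    indexed by its own (irregular) timestamps, which must lie within the
    span of the channel grid.
    """

    channels: dict[str, SensorSeries]
    dependent: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("dataset needs at least one channel")
        grids = [s.timestamps for s in self.channels.values()]
        for g in grids[1:]:
            if not g.equals(grids[0]):
                raise GridError("all channels must share an identical grid")
        if self.dependent is not None and len(self.dependent) > 0:
            self.dependent = self.dependent.sort_index()
            lo, hi = grids[0][0], grids[0][-1]
            if self.dependent.index[0] < lo or self.dependent.index[-1] > hi:
                raise GridError("dependent timestamps fall outside the channel grid span")

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def grid(self) -> pd.DatetimeIndex:
        return next(iter(self.channels.values())).timestamps

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: s.values for n, s in self.channels.items()}, index=self.grid)

    def with_channels(self, channels: dict[str, SensorSeries]) -> "MultiChannelDataset":
        return MultiChannelDataset(channels=channels, dependent=self.dependent)


@dataclass
class CleaningReport:
    """Bookkeeping for what cleaning changed: indices imputed / flagged."""

    imputed_indices: dict[str, np.ndarray] = field(default_factory=dict)
    outlier_indices: dict[str, np.ndarray] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        out = CleaningReport(parameters={**self.parameters, **other.parameters})
        for attr in ("imputed_indices", "outlier_indices"):
            mine, theirs = getattr(self, attr), getattr(other, attr)
            merged = dict(mine)
            for k, v in theirs.items():
                merged[k] = np.union1d(merged.get(k, np.array([], dtype=int)), v)
            setattr(out, attr, merged)
        return out


def _validate_grid(index: pd.DatetimeIndex) -> None:
    if len(index) < 2:
        return
    dup = index[index.duplicated()]
    if len(dup):
        raise GridError(f"duplicated timestamp: {dup[0]}")
    diffs = np.diff(index.asi8)
    bad = np.where(diffs <= 0)[0]
    if len(bad):
        raise GridError(f"non-monotone timestamps at row {bad[0] + 1} ({index[bad[0] + 1]})")
    step = diffs[0]
    off = np.where(diffs != step)[0]
    if len(off):
        i = off[0] + 1
        raise GridError(
            f"irregular spacing at row {i} ({index[i]}): "
            f"expected {pd.Timedelta(step, 'ns')}, got {pd.Timedelta(diffs[off[0]], 'ns')}"
        )


# ---------------------------------------------------------------------------
# CSV I/O (RFC-4180; empty field = missing; ISO-8601 timestamps)
# ---------------------------------------------------------------------------

def read_sensor_csv(
    path: str | Path,
    dependent_column: str = DEPENDENT_COLUMN,
    units: dict[str, str] | None = None,
) -> MultiChannelDataset:
    """Read a multichannel sensor CSV into a validated dataset.

    The first column must be named ``timestamp`` (ISO-8601); every other
    column is a channel except ``dependent_column``, which is read as the
    sparse dependent series (rows with an empty cell are simply absent
    observations, not missing values to impute).
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: no 'timestamp' column in header {list(df.columns)}")
    index = pd.DatetimeIndex(pd.to_datetime(df.pop("timestamp")))
    _validate_grid(index)
    units = units or {}
    dependent = None
    if dependent_column in df.columns:
        dep = pd.Series(df.pop(dependent_column).to_numpy(dtype=float), index=index)
        dependent = dep.dropna()
        if dependent.empty:
            dependent = None
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no channel columns found")
    channels = {
        name: SensorSeries(name, index, df[name].to_numpy(dtype=float), units.get(name, ""))
        for name in df.columns
    }
    return MultiChannelDataset(channels=channels, dependent=dependent)


def write_sensor_csv(dataset: MultiChannelDataset, path: str | Path) -> None:
    """Write a dataset in the exact dialect :func:`read_sensor_csv` accepts."""
    df = dataset.frame()
    if dataset.dependent is not None:
        dep = dataset.dependent.reindex(df.index)
        df[DEPENDENT_COLUMN] = dep
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.12g", date_format="%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_linear(series: SensorSeries) -> tuple[SensorSeries, CleaningReport]:
    """Fill missing values by linear interpolation between bracketing points.

    Interior gaps are filled on the straight line through the nearest
    non-missing neighbours; leading/trailing gaps, which have no bracketing
    pair, are filled with the nearest observed value.  Observed values are
    never altered, so the operation is idempotent.
    """
    values = series.values
    missing = np.isnan(values)
    report = CleaningReport(parameters={"method": "linear"})
    if not missing.any():
        report.imputed_indices[series.name] = np.array([], dtype=int)
        return series, report
    n_known = int((~missing).sum())
    if n_known == 0:
        raise ValueError(f"channel {series.name!r}: all values missing, cannot impute")
    if n_known == 1:
        filled = np.full_like(values, values[~missing][0])
    else:
        t = series.timestamps.asi8.astype(float)
        known = ~missing
        # np.interp is exactly the two-point line of the bracketing pair on
        # interior gaps and constant (nearest-value) extension at the edges.
        filled = np.interp(t, t[known], values[known])
        filled[known] = values[known]
    report.imputed_indices[series.name] = np.where(missing)[0]
    return series.with_values(filled), report


# ---------------------------------------------------------------------------
# Outlier removal
# ---------------------------------------------------------------------------

def remove_outliers(
    series: SensorSeries, window: int = 145, k: float = 5.0
) -> tuple[SensorSeries, CleaningReport]:
    """Flag points far from a rolling median and blank them to NaN.

    A point is an outlier when ``|x - med| > k * 1.4826 * MAD`` with the
    median and MAD taken over a centred window of ``window`` samples
    (default 145 ≈ one day of 10-minute data).  Windows whose MAD is zero
    flag nothing — a locally constant record is taken at face value.
    Flagged points become missing and can be re-imputed afterwards.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    s = pd.Series(series.values)
    roll = s.rolling(window, center=True, min_periods=1)
    med = roll.median()
    # true rolling MAD: median over the window of |x - window median|
    mad = roll.apply(lambda seg: np.nanmedian(np.abs(seg - np.nanmedian(seg))), raw=True)
    scale = 1.4826 * mad
    dev = (s - med).abs()
    flagged = (dev > k * scale) & (scale > 0) & s.notna()
    out = series.values.copy()
    out[flagged.to_numpy()] = np.nan
    report = CleaningReport(
        outlier_indices={series.name: np.where(flagged.to_numpy())[0]},
        parameters={"window": window, "k": k},
    )
    return series.with_values(out), report


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _cma_kernel(width: int) -> np.ndarray:
    # Even orders use the classic half-weight end kernel (width+1 points),
    # keeping the window symmetric so linear trends pass through unchanged.
    if width % 2 == 1:
        return np.full(width, 1.0 / width)
    w = np.ones(width + 1)
    w[0] = w[-1] = 0.5
    return w / width


def centred_moving_average(series: SensorSeries, width: int = 6) -> SensorSeries:
    """Centred moving average of ``width`` samples (default 6 = one hour).

    Near the boundaries the window shrinks symmetrically (a uniform window
    of ``2r+1`` points with ``r`` the distance to the edge), so the output
    grid has the same length as the input and constant or linear signals
    are reproduced exactly everywhere.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if series.missing_mask.any():
        raise ValueError(
            f"channel {series.name!r} has missing values; run impute_linear first"
        )
    x = series.values
    n = len(x)
    kernel = _cma_kernel(width)
    half = len(kernel) // 2
    full = np.convolve(x, kernel, mode="full")  # kernel is symmetric
    out = np.empty(n)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        if r == half:
            out[i] = full[i + half]
        else:
            out[i] = x[i - r : i + r + 1].mean()
    return series.with_values(out)


def decimate(dataset: MultiChannelDataset, stride: int) -> MultiChannelDataset:
    """Keep every ``stride``-th sample (e.g. 6 turns a 10-min grid hourly)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return dataset
    channels = {
        n: SensorSeries(n, s.timestamps[::stride], s.values[::stride], s.units)
        for n, s in dataset.channels.items()
    }
    dependent = dataset.dependent
    if dependent is not None:
        # the thinned grid can end earlier; drop observations past its span
        grid = next(iter(channels.values())).timestamps
        dependent = dependent[(dependent.index >= grid[0]) & (dependent.index <= grid[-1])]
        if dependent.empty:
            dependent = None
    return MultiChannelDataset(channels=channels, dependent=dependent)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_index(n: int, train_fraction: float = 0.75) -> int:
    """Boundary index of the chronological split: first ⌊n·f⌋ samples train."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    boundary = int(np.floor(n * train_fraction))
    if boundary == 0 or boundary == n:
        raise ValueError(
            f"split leaves one side empty (n={n}, train_fraction={train_fraction})"
        )
    return boundary


def chronological_split(
    dataset: MultiChannelDataset, train_fraction: float = 0.75
) -> tuple[MultiChannelDataset, MultiChannelDataset]:
    """Split without shuffling: the first 75 % (by default) trains the model.

    The sparse dependent series is divided at the boundary timestamp.
    """
    n = len(dataset)
    boundary = split_index(n, train_fraction)
    grid = dataset.grid

    def _slice(sl: slice) -> dict[str, SensorSeries]:
        return {
            name: SensorSeries(name, s.timestamps[sl], s.values[sl], s.units)
            for name, s in dataset.channels.items()
        }

    dep_train = dep_test = None
    if dataset.dependent is not None:
        dep = dataset.dependent
        # observations falling strictly between the last training sample and
        # the first test sample belong to neither span and are dropped
        dep_train = dep[dep.index <= grid[boundary - 1]]
        dep_test = dep[dep.index >= grid[boundary]]
        dep_train = dep_train if len(dep_train) else None
        dep_test = dep_test if len(dep_test) else None
    train = MultiChannelDataset(_slice(slice(0, boundary)), dep_train)
    test = MultiChannelDataset(_slice(slice(boundary, n)), dep_test)
    return train, test


# ---------------------------------------------------------------------------
# Whole-dataset cleaning
# ---------------------------------------------------------------------------

def clean_dataset(
    dataset: MultiChannelDataset,
    outlier_window: int = 145,
    outlier_k: float = 5.0,
    smooth_width: int = 6,
) -> tuple[MultiChannelDataset, CleaningReport]:
    """Run the full cleaning order: impute → de-outlier → re-impute → smooth.

    Filling first gives the rolling statistics a full grid to work with;
    points the robust rule blanks are then re-filled from their clean
    neighbours before the centred moving average.
    """
    report = CleaningReport()
    cleaned: dict[str, SensorSeries] = {}
    for name, series in dataset.channels.items():
        s, r1 = impute_linear(series)
        s, r2 = remove_outliers(s, window=outlier_window, k=outlier_k)
        s, r3 = impute_linear(s)
        if smooth_width > 1:
            s = centred_moving_average(s, width=smooth_width)
        cleaned[name] = s
        report = report.merge(r1).merge(r2)
        # points re-imputed after outlier blanking are outliers, not gaps, so
        # keep the two index sets disjoint in the merged report
        gap_idx = report.imputed_indices.get(name, np.array([], dtype=int))
        out_idx = report.outlier_indices.get(name, np.array([], dtype=int))
        report.imputed_indices[name] = np.setdiff1d(gap_idx, out_idx)
    report.parameters.update(
        {"outlier_window": outlier_window, "outlier_k": outlier_k, "smooth_width": smooth_width}
    )
    return dataset.with_channels(cleaned), report
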