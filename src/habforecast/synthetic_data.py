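"""Synthetic multichannel fluorometer data with known ground truth.

The generator emulates the statistical regime of a moored 3-channel
fluorometer at a sea-loch salmon farm: 10-minute cadence over roughly a
growing season (22,708 samples by default), strongly cross-correlated
channels driven by shared diurnal (24 h) and principal-lunar tidal (12.42 h)
oscillations over a slow seasonal trend, channel-specific AR(1) sensor
noise, a sparse (default 50-point) laboratory phytoplankton count that is a
noisy linear function of the channels, telemetry-dropout missing cells, and
biofouling-like spike/drift outliers.  Every injected defect and every
latent quantity is recorded in :class:`GroundTruth`, so cleaning,
decomposition, regression and forecasting can all be scored against truth.

What it does *not* emulate: mechanistic bloom dynamics (nutrients, light),
storm events, or sensor recalibration jumps; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MultiChannelDataset, SensorSeries

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "inject_biofouling"]

CHANNELS = ("chl470", "chl530", "turbidity")
UNITS = {"chl470": "µg/L", "chl530": "µg/L", "turbidity": "NTU"}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the deployment regime.

    Channels are built as  offset + loading·(latent oscillations + trend)
    + AR(1) noise, which makes any two channels share most of their variance
    (cross-correlation ≳ 0.9).  The dependent count is β_true·[1, X] plus
    Gaussian noise sized so its correlation with any single channel sits in
    the weak-positive band seen for lab counts against in-situ optics.
    """

    n_samples: int = 22708
    cadence_minutes: int = 10
    start: str = "2020-05-01"
    # latent structure shared by all channels
    periods_hours: tuple[float, ...] = (24.0, 12.42)
    amplitudes: tuple[float, ...] = (1.5, 0.8)
    phases: tuple[float, ...] = (0.0, 1.1)
    trend_slope_per_day: float = 0.01
    # per-channel construction
    offsets: dict[str, float] = field(
        default_factory=lambda: {"chl470": 6.0, "chl530": 4.0, "turbidity": 9.0}
    )
    loadings: dict[str, float] = field(
        default_factory=lambda: {"chl470": 1.0, "chl530": 0.75, "turbidity": 1.2}
    )
    ar_coefficient: float = 0.8
    ar_sigma: float = 0.2
    # dependent (lab phytoplankton count, cells/mL)
    beta_true: tuple[float, ...] = (50.0, 60.0, 25.0, 40.0)  # intercept + one per channel
    dependent_noise_sigma: float = 370.0
    n_dependent: int = 50
    # defects
    missing_rate: float = 0.01
    outlier_rate: float = 0.002
    # spike size in units of the AR noise sd; biofouling glints are gross
    # (order-of-baseline) excursions, far beyond the diurnal swing
    outlier_scale: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("missing_rate", self.missing_rate), ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if any(p <= 0 for p in self.periods_hours):
            raise ValueError("periods must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.beta_true) != len(CHANNELS) + 1:
            raise ValueError("beta_true must have one intercept plus one slope per channel")

    @classmethod
    def scenario(cls, seed: int, days: float = 40.0, **kw) -> "SyntheticConfig":
        """A shorter benchmark scenario (default 40 days ≈ 5,760 samples)."""
        n = int(round(days * 24 * 60 / kw.get("cadence_minutes", 10)))
        return cls(n_samples=n, seed=seed, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    clean: pd.DataFrame
    latents: pd.DataFrame
    beta_true: np.ndarray
    dependent_clean: pd.Series
    missing_indices: dict[str, np.ndarray]
    outlier_indices: dict[str, np.ndarray]
    biofouling_episodes: list[dict] = field(default_factory=list)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n) * sigma
    out = np.empty(n)
    stationary_sd = sigma / np.sqrt(1.0 - phi * phi) if abs(phi) < 1 else sigma
    out[0] = rng.standard_normal() * stationary_sd
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def generate(config: SyntheticConfig) -> tuple[MultiChannelDataset, GroundTruth]:
    """Draw one dataset plus its ground truth, deterministically from the seed."""
    n = config.n_samples
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    grid = pd.date_range(
        config.start, periods=n, freq=pd.Timedelta(minutes=config.cadence_minutes)
    )
    t_hours = np.arange(n) * (config.cadence_minutes / 60.0)

    osc = np.zeros(n)
    latent_cols = {}
    for period, amp, phase in zip(config.periods_hours, config.amplitudes, config.phases):
        comp = amp * np.sin(2 * np.pi * t_hours / period + phase)
        latent_cols[f"osc_{period:g}h"] = comp
        osc += comp
    trend = config.trend_slope_per_day * (t_hours / 24.0)
    latent_cols["trend"] = trend
    latent = osc + trend

    clean_cols = {}
    for name in CHANNELS:
        noise = _ar1(n, config.ar_coefficient, config.ar_sigma, rng)
        clean_cols[name] = config.offsets[name] + config.loadings[name] * latent + noise
    clean = pd.DataFrame(clean_cols, index=grid)
    if (clean.min() <= 0).any():
        bad = clean.min().idxmin()
        raise ValueError(
            f"configuration produced non-positive values on channel {bad!r}; "
            "raise its offset (percentage errors need positive measurements)"
        )

    # sparse dependent series at uniformly drawn grid instants
    dep_idx = np.sort(rng.choice(n, size=min(config.n_dependent, n), replace=False))
    beta = np.asarray(config.beta_true, dtype=float)
    X_dep = clean.iloc[dep_idx].to_numpy()
    dep_mean = beta[0] + X_dep @ beta[1:]
    dep_vals = dep_mean + rng.standard_normal(len(dep_idx)) * config.dependent_noise_sigma
    dependent = pd.Series(dep_vals, index=grid[dep_idx], name="phytoplankton")
    dependent_clean = pd.Series(dep_mean, index=grid[dep_idx], name="phytoplankton")

    # inject defects channel-wise
    observed = {}
    missing_idx: dict[str, np.ndarray] = {}
    outlier_idx: dict[str, np.ndarray] = {}
    noise_sd = config.ar_sigma / np.sqrt(1 - config.ar_coefficient**2)
    for name in CHANNELS:
        vals = clean[name].to_numpy().copy()
        n_out = int(np.ceil(config.outlier_rate * n)) if config.outlier_rate > 0 else 0
        o_idx = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.array([], int)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        vals[o_idx] += signs * config.outlier_scale * noise_sd * (1 + rng.random(n_out))
        n_miss = int(np.ceil(config.missing_rate * n)) if config.missing_rate > 0 else 0
        pool = np.setdiff1d(np.arange(n), o_idx)
        m_idx = (
            np.sort(rng.choice(pool, size=n_miss, replace=False)) if n_miss else np.array([], int)
        )
        vals[m_idx] = np.nan
        observed[name] = SensorSeries(name, grid, vals, UNITS[name])
        missing_idx[name] = m_idx
        outlier_idx[name] = o_idx

    dataset = MultiChannelDataset(channels=observed, dependent=dependent)
    truth = GroundTruth(
        clean=clean,
        latents=pd.DataFrame(latent_cols, index=grid),
        beta_true=beta,
        dependent_clean=dependent_clean,
        missing_indices=missing_idx,
        outlier_indices=outlier_idx,
    )
    return dataset, truth


def inject_biofouling(
    dataset: MultiChannelDataset,
    channel: str,
    start: int,
    length: int,
    drift_rate: float,
    seed: int,
    spike_rate: float = 0.05,
    spike_scale: float = 12.0,
    truth: GroundTruth | None = None,
) -> tuple[MultiChannelDataset, dict]:
    """Overlay a biofouling-like episode: additive drift ramp plus spikes.

    ``drift_rate`` is the ramp increment per sample over the episode;
    spikes hit a ``spike_rate`` fraction of episode samples with magnitude
    ``spike_scale`` times the channel's robust scale.  The affected indices
    are returned (and appended to ``truth`` when given).
    """
    n = len(dataset)
    if start < 0 or length < 0 or start + length > n:
        raise ValueError(f"episode [{start}, {start + length}) outside grid of length {n}")
    series = dataset.channels[channel]
    vals = series.values.copy()
    rng = np.random.default_rng(seed)
    idx = np.arange(start, start + length)
    vals[idx] += drift_rate * np.arange(length)
    finite = vals[np.isfinite(vals)]
    robust_sd = 1.4826 * np.median(np.abs(finite - np.median(finite)))
    n_spikes = int(round(spike_rate * length))
    spike_idx = (
        np.sort(rng.choice(idx, size=n_spikes, replace=False)) if n_spikes else np.array([], int)
    )
    vals[spike_idx] += spike_scale * robust_sd * rng.choice([-1.0, 1.0], size=n_spikes)
    episode = {
        "channel": channel,
        "start": int(start),
        "length": int(length),
        "drift_rate": float(drift_rate),
        "drift_indices": idx if drift_rate else np.array([], int),
        "spike_indices": spike_idx,
    }
    channels = dict(dataset.channels)
    channels[channel] = series.with_values(vals)
    out = MultiChannelDataset(channels=channels, dependent=dataset.dependent)
    if truth is not None:
        truth.biofouling_episodes.append(episode)
    return out, episode
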