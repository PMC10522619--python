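"""End-to-end hybrid EEMD–MLR–LSTM forecasting pipeline.

Four stages, mirroring how the forecaster is deployed:

1. **Clean** — impute, robust-de-outlier, re-impute, hourly centred moving
   average, then decimate to the hourly forecasting grid; split
   chronologically (first 75 % trains).
2. **Decompose** — EEMD of each channel's training series into IMFs plus a
   residue.
3. **Forecast** — one stacked-LSTM forecaster per component, trained on the
   min-max-normalized component; multi-step forecasts are recursive and the
   de-normalized component forecasts are summed back into a channel
   forecast (the reassembly is an exact arithmetic identity).
4. **Regress** — ordinary least squares maps the three channels to the
   sparse lab phytoplankton count on the training split; channel forecasts
   pass through the fitted coefficients to give the phytoplankton forecast.

Evaluation is rolling-origin over the held-out 25 %: from each origin the
model forecasts the next ``horizon`` samples and the per-step errors are
pooled into MAE / MSE / RMSE / MAPE.  Two reference forecasters share the
identical split, lookback, horizon and training budget: a plain LSTM on the
undecomposed channel, and last-value persistence.

Decomposition leakage is controlled by ``mode``: ``"honest"`` (default)
re-runs EEMD on the data available up to each forecast origin with the same
seed and ensemble size, while ``"static"`` decomposes the full series once
(faster, but test observations influence the components).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .eemd import eemd as _eemd
from .lstm_forecaster import (
    ComponentForecaster,
    ConstantForecaster,
    ForecastConfig,
    NormalizationParams,
    denormalize,
    fit_normalization,
    minmax_normalize,
    train_component_forecaster,
)
from .mlr import ChannelRegression, ChannelRegressionResults
from .preprocess import (
    MultiChannelDataset,
    chronological_split,
    clean_dataset,
    decimate,
)

__all__ = [
    "PipelineConfig",
    "MetricsBundle",
    "HybridForecast",
    "HybridEEMDLSTM",
    "HybridEEMDLSTMResults",
    "evaluate",
    "run_pipeline",
    "baseline_plain_lstm",
    "baseline_persistence",
    "PipelineStageError",
]


class PipelineStageError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class MetricsBundle:
    """MAE / MSE / RMSE / MAPE of a forecast (MAPE as a fraction)."""

    mae: float
    mse: float
    rmse: float
    mape: float

    def __post_init__(self) -> None:
        if min(self.mae, self.mse, self.rmse, self.mape) < 0:
            raise ValueError("metrics cannot be negative")

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse, "mape": self.mape}


def evaluate(
    measured: np.ndarray, forecast: np.ndarray, mape_epsilon: float | None = None
) -> MetricsBundle:
    """Literal forecast-error metrics over paired samples.

    MAPE divides by the measured value and is undefined at zero; by default
    a zero measurement is a hard error, or pass ``mape_epsilon`` to floor
    the denominator magnitude.
    """
    m = np.asarray(measured, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if m.shape != f.shape or m.ndim != 1 or len(m) < 1:
        raise ValueError(f"need equal-length vectors, got {m.shape} and {f.shape}")
    err = m - f
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    denom = np.abs(m)
    if mape_epsilon is None:
        if np.any(m == 0):
            raise ValueError("MAPE undefined: measured value equals zero (set mape_epsilon)")
    else:
        denom = np.maximum(denom, mape_epsilon)
    mape = float(np.mean(np.abs(err) / denom))
    return MetricsBundle(mae=mae, mse=mse, rmse=rmse, mape=mape)


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place (see docs/methods.md for rationale)."""

    train_fraction: float = 0.75
    outlier_window: int = 145
    outlier_k: float = 5.0
    smooth_width: int = 6
    decimate_stride: int = 6
    ensemble_size: int = 100
    noise_amplitude: float = 0.2
    max_imf: int | None = None
    mode: str = "honest"
    decompose: bool = True
    max_origins: int | None = None
    mape_epsilon: float | None = None
    align_max_gap: str = "30min"
    forecast: ForecastConfig = field(default_factory=ForecastConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("honest", "static"):
            raise ValueError(f"mode must be 'honest' or 'static', got {self.mode!r}")

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "PipelineConfig":
        """Reduced single-CPU configuration: 2×16-unit LSTM, 20 epochs,
        16-trial ensemble, at most 6 IMFs and 24 evaluation origins."""
        base = dict(
            ensemble_size=16,
            max_imf=6,
            max_origins=24,
            forecast=ForecastConfig.reduced(seed=seed),
            seed=seed,
        )
        base.update(kw)
        return cls(**base)

    def provenance(self) -> dict:
        d = asdict(self)
        digest = hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()
        return {"config": d, "config_hash": digest[:16]}


@dataclass
class HybridForecast:
    """Pooled rolling-origin forecasts plus provenance."""

    channel_forecasts: pd.DataFrame
    component_forecasts: dict[str, pd.DataFrame]
    dependent_forecast: pd.Series | None
    horizon: int
    origins: np.ndarray
    provenance: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


class HybridEEMDLSTM:
    """The hybrid forecasting model, statsmodels-style: build from a
    dataset and a config, then :meth:`fit` to obtain results."""

    def __init__(self, dataset: MultiChannelDataset, config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()

    # -- internal stages ---------------------------------------------------

    def _prepare(self):
        cfg = self.config
        cleaned, report = clean_dataset(
            self.dataset,
            outlier_window=cfg.outlier_window,
            outlier_k=cfg.outlier_k,
            smooth_width=cfg.smooth_width,
        )
        cleaned = decimate(cleaned, cfg.decimate_stride)
        train, test = chronological_split(cleaned, cfg.train_fraction)
        return cleaned, report, train, len(train)

    def _origins(self, n_total: int, boundary: int) -> np.ndarray:
        H = self.config.forecast.horizon
        origins = np.arange(boundary - 1, n_total - H, H)
        if self.config.max_origins is not None and len(origins) > self.config.max_origins:
            pick = np.linspace(0, len(origins) - 1, self.config.max_origins).round().astype(int)
            origins = origins[np.unique(pick)]
        return origins

    def fit(self) -> "HybridEEMDLSTMResults":
        cfg = self.config
        H = cfg.forecast.horizon
        try:
            cleaned, report, train, boundary = self._prepare()
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("preprocess", e) from e
        frame = cleaned.frame()
        names = list(frame.columns)
        n_total = len(frame)

        mlr_results: ChannelRegressionResults | None = None
        if train.dependent is not None and len(train.dependent) >= len(names) + 2:
            try:
                mlr_results = ChannelRegression.from_dataset(train, cfg.align_max_gap).fit()
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("mlr", e) from e
        else:
            warnings.warn("no (or too few) dependent observations in the training split; "
                          "producing channel forecasts only")

        eemd_seeds = dict(zip(names, _child_seeds(cfg.seed, len(names))))
        models: dict[str, list[ComponentForecaster]] = {}
        norms: dict[str, list[NormalizationParams]] = {}
        static_decomps: dict[str, list[np.ndarray]] = {}
        try:
            for name in names:
                train_vals = frame[name].to_numpy()[:boundary]
                if cfg.decompose:
                    decomp = _eemd(
                        train_vals,
                        ensemble_size=cfg.ensemble_size,
                        noise_amplitude=cfg.noise_amplitude,
                        seed=eemd_seeds[name],
                        max_imf=cfg.max_imf,
                    )
                    comps = decomp.components()
                else:
                    comps = [train_vals]
                comp_seeds = _child_seeds(eemd_seeds[name] + 1, len(comps))
                ms, ns = [], []
                for comp, cs in zip(comps, comp_seeds):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")  # degenerate-component note
                        norm = fit_normalization(comp)
                    if norm.degenerate:
                        model = ConstantForecaster()
                    else:
                        model = train_component_forecaster(
                            minmax_normalize(comp, norm), cfg.forecast.replace(seed=cs)
                        )
                    ms.append(model)
                    ns.append(norm)
                models[name] = ms
                norms[name] = ns
                if cfg.decompose and cfg.mode == "static":
                    full = _eemd(
                        frame[name].to_numpy(),
                        ensemble_size=cfg.ensemble_size,
                        noise_amplitude=cfg.noise_amplitude,
                        seed=eemd_seeds[name],
                        max_imf=cfg.max_imf,
                    )
                    static_decomps[name] = full.components()
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("decompose/train", e) from e

        origins = self._origins(n_total, boundary)
        try:
            forecast = self._rolling_forecast(
                frame, names, origins, models, norms, static_decomps, eemd_seeds, mlr_results
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("forecast", e) from e

        metrics = self._score(frame, forecast, cleaned)
        return HybridEEMDLSTMResults(
            model=self,
            forecast=forecast,
            metrics=metrics,
            mlr_results=mlr_results,
            cleaning_report=report,
            boundary=boundary,
            cleaned=cleaned,
        )

    def _components_at(
        self,
        name: str,
        values: np.ndarray,
        origin: int,
        n_models: int,
        static_decomps: dict,
        eemd_seeds: dict,
    ) -> list[np.ndarray]:
        cfg = self.config
        if not cfg.decompose:
            return [values[: origin + 1]]
        if cfg.mode == "static":
            return [c[: origin + 1] for c in static_decomps[name]]
        decomp = _eemd(
            values[: origin + 1],
            ensemble_size=cfg.ensemble_size,
            noise_amplitude=cfg.noise_amplitude,
            seed=eemd_seeds[name],
            max_imf=cfg.max_imf,
        )
        imfs, residue = list(decomp.imfs), decomp.residue
        n_imf_models = n_models - 1
        if len(imfs) > n_imf_models:
            # fold surplus low-frequency modes into the residue channel
            for extra in imfs[n_imf_models:]:
                residue = residue + extra
            imfs = imfs[:n_imf_models]
        while len(imfs) < n_imf_models:
            imfs.append(np.zeros(origin + 1))
        return [*imfs, residue]

    def _rolling_forecast(
        self, frame, names, origins, models, norms, static_decomps, eemd_seeds, mlr_results
    ) -> HybridForecast:
        cfg = self.config
        H = cfg.forecast.horizon
        grid = frame.index
        target_idx = np.concatenate([np.arange(o + 1, o + 1 + H) for o in origins])
        chan_pred: dict[str, np.ndarray] = {}
        comp_pred: dict[str, pd.DataFrame] = {}
        for name in names:
            values = frame[name].to_numpy()
            ms, ns = models[name], norms[name]
            per_comp = [[] for _ in ms]
            total = []
            for o in origins:
                comps = self._components_at(
                    name, values, int(o), len(ms), static_decomps, eemd_seeds
                )
                step_sum = np.zeros(H)
                for ci, (comp, model, norm) in enumerate(zip(comps, ms, ns)):
                    hist = minmax_normalize(comp, norm)
                    pred = denormalize(model.forecast(hist, H), norm)
                    per_comp[ci].append(pred)
                    step_sum = step_sum + pred
                total.append(step_sum)
            chan_pred[name] = np.concatenate(total)
            comp_cols = {
                (f"imf{ci + 1}" if ci < len(ms) - 1 else "residue")
                if (cfg.decompose and len(ms) > 1)
                else "channel": np.concatenate(p)
                for ci, p in enumerate(per_comp)
            }
            comp_pred[name] = pd.DataFrame(comp_cols, index=grid[target_idx])
        channel_forecasts = pd.DataFrame(chan_pred, index=grid[target_idx])
        dependent_forecast = None
        if mlr_results is not None:
            dependent_forecast = pd.Series(
                mlr_results.predict(channel_forecasts),
                index=channel_forecasts.index,
                name="phytoplankton",
            )
        return HybridForecast(
            channel_forecasts=channel_forecasts,
            component_forecasts=comp_pred,
            dependent_forecast=dependent_forecast,
            horizon=H,
            origins=np.asarray(origins, dtype=int),
            provenance=self.config.provenance(),
        )

    def _score(
        self, frame: pd.DataFrame, forecast: HybridForecast, cleaned: MultiChannelDataset
    ) -> dict[str, MetricsBundle]:
        cfg = self.config
        metrics: dict[str, MetricsBundle] = {}
        all_m, all_f = [], []
        for name in frame.columns:
            measured = frame[name].reindex(forecast.channel_forecasts.index).to_numpy()
            predicted = forecast.channel_forecasts[name].to_numpy()
            metrics[name] = evaluate(measured, predicted, cfg.mape_epsilon)
            all_m.append(measured)
            all_f.append(predicted)
        metrics["pooled"] = evaluate(
            np.concatenate(all_m), np.concatenate(all_f), cfg.mape_epsilon
        )
        if forecast.dependent_forecast is not None and cleaned.dependent is not None:
            dep = cleaned.dependent
            fidx = forecast.dependent_forecast.index
            pos = fidx.get_indexer(dep.index, method="nearest")
            ok = pos >= 0
            if ok.any():
                gaps = np.abs(fidx[pos[ok]].asi8 - dep.index.asi8[ok])
                near = gaps <= pd.Timedelta(cfg.align_max_gap).value
                if near.sum() >= 1:
                    m = dep.to_numpy()[ok][near]
                    f = forecast.dependent_forecast.to_numpy()[pos[ok]][near]
                    if np.all(m != 0) or cfg.mape_epsilon is not None:
                        metrics["dependent"] = evaluate(m, f, cfg.mape_epsilon)
        return metrics


@dataclass
class HybridEEMDLSTMResults:
    """Fit products: forecasts, error metrics, the fitted regression and
    cleaning bookkeeping."""

    model: HybridEEMDLSTM
    forecast: HybridForecast
    metrics: dict[str, MetricsBundle]
    mlr_results: ChannelRegressionResults | None
    cleaning_report: object
    boundary: int
    cleaned: MultiChannelDataset

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Hybrid EEMD-MLR-LSTM forecast results",
            f"  mode: {cfg.mode}   decompose: {cfg.decompose}   "
            f"horizon: {cfg.forecast.horizon} steps   origins: {len(self.forecast.origins)}",
            f"  train/test boundary: sample {self.boundary}",
            f"  {'series':<12}{'MAE':>12}{'MSE':>14}{'RMSE':>12}{'MAPE':>10}",
        ]
        for name, mb in self.metrics.items():
            lines.append(
                f"  {name:<12}{mb.mae:>12.5g}{mb.mse:>14.6g}{mb.rmse:>12.5g}{mb.mape:>10.4f}"
            )
        if self.mlr_results is not None:
            lines.append("")
            lines.append(self.mlr_results.summary())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Library-level convenience operations
# ---------------------------------------------------------------------------

def run_pipeline(
    dataset: MultiChannelDataset, config: PipelineConfig | None = None
) -> tuple[HybridForecast, MetricsBundle]:
    """Fit the hybrid model end-to-end; returns the pooled test metrics."""
    results = HybridEEMDLSTM(dataset, config).fit()
    return results.forecast, results.metrics["pooled"]


def baseline_plain_lstm(
    dataset: MultiChannelDataset, config: PipelineConfig | None = None
) -> MetricsBundle:
    """Identical machinery and budget with decomposition disabled: one LSTM
    per undecomposed channel."""
    cfg = config or PipelineConfig()
    from dataclasses import replace

    cfg = replace(cfg, decompose=False)
    results = HybridEEMDLSTM(dataset, cfg).fit()
    return results.metrics["pooled"]


def baseline_persistence(
    dataset: MultiChannelDataset, config: PipelineConfig | None = None
) -> MetricsBundle:
    """Last-value-carried-forward reference on the same split and origins."""
    model = HybridEEMDLSTM(dataset, config or PipelineConfig())
    cfg = model.config
    H = cfg.forecast.horizon
    cleaned, _, _, boundary = model._prepare()
    frame = cleaned.frame()
    origins = model._origins(len(frame), boundary)
    all_m, all_f = [], []
    for name in frame.columns:
        values = frame[name].to_numpy()
        for o in origins:
            all_m.append(values[o + 1 : o + 1 + H])
            all_f.append(np.full(H, values[o]))
    return evaluate(np.concatenate(all_m), np.concatenate(all_f), cfg.mape_epsilon)
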