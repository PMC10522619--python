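"""Stacked LSTM regression for one decomposition component.

Each IMF (and the residue) gets its own small stacked-LSTM forecaster.  The
cell follows the standard gate algebra on the concatenation [h_{t-1}, x_t]:

    F_t = sigma(W_f [h,x] + b_f)            forget gate
    I_t = sigma(W_i [h,x] + b_i)            input gate
    G_t = tanh (W_c [h,x] + b_c)            candidate
    O_t = sigma(W_o [h,x] + b_o)            output gate
    C_t = F_t * C_{t-1} + I_t * G_t         cell state
    h_t = O_t * tanh(C_t)                   hidden state

A ``tied_candidate`` switch reuses (W_i, b_i) for the candidate pre-
activation, i.e. G_t = tanh(W_i [h,x] + b_i); the default keeps separate
candidate parameters.  Training is full backpropagation-through-time on
squared error with Adam; every source of randomness (weight init, batch
shuffling) flows from the config seed, so runs are bit-reproducible.

Components are min-max normalized to [0, 1] using the training split only,
and forecasts are de-normalized by the caller; multi-step forecasts are
recursive one-step predictions fed back into the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForecastConfig",
    "LayerParams",
    "LSTMParameters",
    "NormalizationParams",
    "lstm_cell_step",
    "fit_normalization",
    "minmax_normalize",
    "denormalize",
    "make_supervised",
    "ComponentForecaster",
    "train_component_forecaster",
    "forecast_component",
    "TrainingDivergedError",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ForecastConfig:
    """Training hyperparameters for the per-component forecasters.

    ``lookback`` is in samples of the forecasting grid (24 = one day of
    hourly data), ``horizon`` likewise (6 = a six-hour forecast).
    """

    lookback: int = 24
    horizon: int = 6
    hidden_sizes: tuple[int, ...] = (32, 32)
    epochs: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    normalization: str = "minmax"
    tied_candidate: bool = False

    def __post_init__(self) -> None:
        if self.lookback < 1 or self.horizon < 1:
            raise ValueError("lookback and horizon must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def replace(self, **kw) -> "ForecastConfig":
        from dataclasses import replace as _r

        return _r(self, **kw)

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "ForecastConfig":
        """Small configuration for quick single-CPU experiments."""
        base = dict(hidden_sizes=(16, 16), epochs=20, batch_size=64, seed=seed)
        base.update(kw)
        return cls(**base)


@dataclass
class LayerParams:
    """Gate weights of one layer, acting on the concatenation [h, x].

    Internally the four gate blocks live in one stacked matrix ``W`` of
    shape (4·hidden, hidden+input), row-blocks ordered forget / input /
    candidate / output (one matmul per step instead of four); the per-gate
    matrices ``W_f`` … ``b_o`` are live views into it.
    """

    W: np.ndarray
    b: np.ndarray
    tied_candidate: bool = False

    @classmethod
    def from_gates(
        cls,
        W_f: np.ndarray, W_i: np.ndarray, W_c: np.ndarray, W_o: np.ndarray,
        b_f: np.ndarray, b_i: np.ndarray, b_c: np.ndarray, b_o: np.ndarray,
        tied_candidate: bool = False,
    ) -> "LayerParams":
        return cls(
            W=np.vstack([W_f, W_i, W_c, W_o]).astype(float),
            b=np.concatenate([b_f, b_i, b_c, b_o]).astype(float),
            tied_candidate=tied_candidate,
        )

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0] // 4

    @property
    def input_size(self) -> int:
        return self.W.shape[1] - self.hidden_size

    def _block(self, k: int) -> np.ndarray:
        H = self.hidden_size
        return self.W[k * H : (k + 1) * H]

    def _bias(self, k: int) -> np.ndarray:
        H = self.hidden_size
        return self.b[k * H : (k + 1) * H]

    W_f = property(lambda self: self._block(0))
    W_i = property(lambda self: self._block(1))
    W_c = property(lambda self: self._block(2))
    W_o = property(lambda self: self._block(3))
    b_f = property(lambda self: self._bias(0))
    b_i = property(lambda self: self._bias(1))
    b_c = property(lambda self: self._bias(2))
    b_o = property(lambda self: self._bias(3))

    def arrays(self) -> list[np.ndarray]:
        return [self.W, self.b]


@dataclass
class LSTMParameters:
    """Whole-network parameters: stacked layers plus the linear readout."""

    layers: list[LayerParams]
    W_out: np.ndarray
    b_out: np.ndarray

    def arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.arrays())
        out += [self.W_out, self.b_out]
        return out


def init_parameters(
    input_size: int,
    hidden_sizes: tuple[int, ...],
    rng: np.random.Generator,
    tied_candidate: bool = False,
) -> LSTMParameters:
    """Uniform init scaled by fan-in; forget-gate bias starts at 1 so early
    training does not wash out the cell state."""
    layers = []
    in_size = input_size
    for h in hidden_sizes:
        fan = h + in_size
        bound = 1.0 / np.sqrt(fan)
        W = rng.uniform(-bound, bound, size=(4 * h, fan))
        b = np.zeros(4 * h)
        b[:h] = 1.0  # forget-gate bias
        layers.append(LayerParams(W=W, b=b, tied_candidate=tied_candidate))
        in_size = h
    bound = 1.0 / np.sqrt(in_size)
    W_out = rng.uniform(-bound, bound, size=(1, in_size))
    return LSTMParameters(layers=layers, W_out=W_out, b_out=np.zeros(1))


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update (h_t, c_t) for a single layer.

    Accepts 1-d vectors or (batch, dim) arrays; shapes must agree with the
    layer's weight matrices.
    """
    was_1d = np.asarray(x_t).ndim == 1
    x_t, h_prev, c_prev = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (x_t, h_prev, c_prev))
    H, I = params.hidden_size, params.input_size
    if x_t.shape[1] != I or h_prev.shape[1] != H or c_prev.shape[1] != H:
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for layer with hidden={H}, input={I}"
        )
    z = np.concatenate([h_prev, x_t], axis=1)
    f = _sigmoid(z @ params.W_f.T + params.b_f)
    i = _sigmoid(z @ params.W_i.T + params.b_i)
    if params.tied_candidate:
        g = np.tanh(z @ params.W_i.T + params.b_i)
    else:
        g = np.tanh(z @ params.W_c.T + params.b_c)
    o = _sigmoid(z @ params.W_o.T + params.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    if was_1d:
        return h_t[0], c_t[0]
    return h_t, c_t


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-component min/max fitted on the training split only."""

    vmin: float
    vmax: float

    @property
    def degenerate(self) -> bool:
        return self.vmax <= self.vmin


def fit_normalization(train_values: np.ndarray) -> NormalizationParams:
    v = np.asarray(train_values, dtype=float)
    p = NormalizationParams(vmin=float(v.min()), vmax=float(v.max()))
    if p.degenerate:
        warnings.warn("degenerate component (max == min): normalization is a passthrough")
    return p


def minmax_normalize(vector: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Affine map sending the train range to [0, 1]; values outside the
    train range map outside [0, 1] without clipping."""
    v = np.asarray(vector, dtype=float)
    if params.degenerate:
        return v.copy()
    return (v - params.vmin) / (params.vmax - params.vmin)


def denormalize(vector: np.ndarray, params: NormalizationParams) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if params.degenerate:
        return v.copy()
    return v * (params.vmax - params.vmin) + params.vmin


# ---------------------------------------------------------------------------
# Supervised windowing
# ---------------------------------------------------------------------------

def make_supervised(
    component: np.ndarray, lookback: int, horizon: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding windows of length ``lookback`` paired with the value
    ``horizon`` steps beyond the window end; count = N − L − H + 1."""
    x = np.asarray(component, dtype=float)
    n = len(x)
    count = n - lookback - horizon + 1
    if count < 1:
        raise ValueError(
            f"series of length {n} too short for lookback={lookback}, horizon={horizon}"
        )
    idx = np.arange(lookback)[None, :] + np.arange(count)[:, None]
    windows = x[idx]
    targets = x[np.arange(count) + lookback + horizon - 1]
    return windows, targets


# ---------------------------------------------------------------------------
# Network forward/backward
# ---------------------------------------------------------------------------

def _forward(params: LSTMParameters, X: np.ndarray, cache: list | None = None) -> np.ndarray:
    """Run the stacked network over windows X (batch, L); return (batch,) output."""
    B, L = X.shape
    states = [
        (np.zeros((B, p.hidden_size)), np.zeros((B, p.hidden_size))) for p in params.layers
    ]
    h_top = None
    for t in range(L):
        inp = X[:, t : t + 1]
        for li, p in enumerate(params.layers):
            h_prev, c_prev = states[li]
            H = p.hidden_size
            z = np.concatenate([h_prev, inp], axis=1)
            A = z @ p.W.T + p.b
            f = _sigmoid(A[:, :H])
            i = _sigmoid(A[:, H : 2 * H])
            g = np.tanh(A[:, H : 2 * H] if p.tied_candidate else A[:, 2 * H : 3 * H])
            o = _sigmoid(A[:, 3 * H :])
            c_t = f * c_prev + i * g
            hc = np.tanh(c_t)
            h_t = o * hc
            if cache is not None:
                cache.append((t, li, z, f, i, g, o, c_prev, hc))
            states[li] = (h_t, c_t)
            inp = h_t
        h_top = inp
    return (h_top @ params.W_out.T + params.b_out).ravel()


def _backward(
    params: LSTMParameters,
    X: np.ndarray,
    cache: list,
    dy: np.ndarray,
    h_top_last: np.ndarray,
) -> list[np.ndarray]:
    """Gradients of the loss w.r.t. every array in ``params.arrays()`` order."""
    B, L = X.shape
    n_layers = len(params.layers)
    grads = {id(a): np.zeros_like(a) for a in params.arrays()}
    dW_out = dy[:, None].T @ h_top_last
    db_out = np.array([dy.sum()])
    grads[id(params.W_out)] += dW_out
    grads[id(params.b_out)] += db_out

    dh_next = [np.zeros((B, p.hidden_size)) for p in params.layers]
    dc_next = [np.zeros((B, p.hidden_size)) for p in params.layers]
    # gradient entering the top layer's hidden state at the last step
    d_from_above: dict[tuple[int, int], np.ndarray] = {
        (L - 1, n_layers - 1): dy[:, None] @ params.W_out
    }
    steps = {(c[0], c[1]): c[2:] for c in cache}
    for t in range(L - 1, -1, -1):
        for li in range(n_layers - 1, -1, -1):
            p = params.layers[li]
            z, f, i, g, o, c_prev, hc = steps[(t, li)]
            dh = dh_next[li] + d_from_above.pop((t, li), 0.0)
            dc = dc_next[li] + dh * o * (1.0 - hc * hc)
            da_o = dh * hc * o * (1.0 - o)
            df = dc * c_prev
            da_f = df * f * (1.0 - f)
            di = dc * g
            da_i = di * i * (1.0 - i)
            dg = dc * i
            da_c = dg * (1.0 - g * g)
            if p.tied_candidate:
                da_i = da_i + da_c
                da_c = np.zeros_like(da_c)
            dA = np.concatenate([da_f, da_i, da_c, da_o], axis=1)
            dz = dA @ p.W
            grads[id(p.W)] += dA.T @ z
            grads[id(p.b)] += dA.sum(axis=0)
            H = p.hidden_size
            dh_next[li] = dz[:, :H]
            dc_next[li] = dc * f
            d_in = dz[:, H:]
            if li > 0:
                key = (t, li - 1)
                d_from_above[key] = d_from_above.get(key, 0.0) + d_in
    return [grads[id(a)] for a in params.arrays()]


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class ComponentForecaster:
    """A trained per-component forecaster with its loss trace."""

    params: LSTMParameters
    config: ForecastConfig
    loss_trace: list[float] = field(default_factory=list)

    def predict_one(self, window: np.ndarray) -> float:
        """One-step prediction from the last ``lookback`` (normalized) values."""
        window = np.asarray(window, dtype=float)
        if len(window) < self.config.lookback:
            raise ValueError(
                f"history of length {len(window)} shorter than lookback "
                f"{self.config.lookback}"
            )
        X = window[-self.config.lookback :][None, :]
        return float(_forward(self.params, X)[0])

    def forecast(self, history: np.ndarray, horizon: int) -> np.ndarray:
        """Recursive multi-step forecast: each one-step prediction is fed
        back into the window for the next step."""
        buf = list(np.asarray(history, dtype=float)[-self.config.lookback :])
        if len(buf) < self.config.lookback:
            raise ValueError(
                f"history of length {len(buf)} shorter than lookback "
                f"{self.config.lookback}"
            )
        out = []
        for _ in range(horizon):
            y = self.predict_one(np.asarray(buf))
            out.append(y)
            buf = buf[1:] + [y]
        return np.asarray(out)

    def architecture(self) -> dict:
        return {
            "hidden_sizes": [p.hidden_size for p in self.params.layers],
            "lookback": self.config.lookback,
            "tied_candidate": self.config.tied_candidate,
            "epochs": self.config.epochs,
            "learning_rate": self.config.learning_rate,
        }


@dataclass
class ConstantForecaster:
    """Trivial forecaster for a degenerate (constant) component: repeats the
    last history value.  Used where min-max normalization is a passthrough
    because the component carries no variation to learn."""

    loss_trace: list[float] = field(default_factory=lambda: [0.0])

    def predict_one(self, window: np.ndarray) -> float:
        return float(np.asarray(window)[-1])

    def forecast(self, history: np.ndarray, horizon: int) -> np.ndarray:
        return np.full(horizon, float(np.asarray(history)[-1]))


def train_component_forecaster(
    component: np.ndarray, config: ForecastConfig
) -> ComponentForecaster:
    """Train one forecaster on a (normalized) component by BPTT + Adam.

    Supervised pairs use one-step targets; multi-step forecasting is
    recursive.  Deterministic for a fixed config seed.
    """
    x = np.asarray(component, dtype=float)
    windows, targets = make_supervised(x, config.lookback, 1)
    rng = np.random.default_rng(config.seed)
    params = init_parameters(1, tuple(config.hidden_sizes), rng, config.tied_candidate)
    arrays = params.arrays()
    opt = _Adam(arrays, config.learning_rate)
    n = len(windows)
    trace: list[float] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            X, y = windows[sel], targets[sel]
            cache: list = []
            pred = _forward(params, X, cache)
            err = pred - y
            loss = float(np.mean(err**2))
            total += loss * len(sel)
            dy = 2.0 * err / len(sel)
            # last cache entry is the top layer at the final step: h = o*tanh(c)
            *_, o_last, _c_prev, hc_last = cache[-1]
            h_top_last = o_last * hc_last
            grads = _backward(params, X, cache, dy, h_top_last)
            opt.step(arrays, grads)
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(epoch)
        trace.append(epoch_loss)
    return ComponentForecaster(params=params, config=config, loss_trace=trace)


def forecast_component(
    model: ComponentForecaster, history: np.ndarray, horizon: int
) -> np.ndarray:
    """Recursive ``horizon``-step forecast from the end of ``history``."""
    return model.forecast(history, horizon)
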