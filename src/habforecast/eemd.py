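"""Empirical mode decomposition (EMD) and its noise-assisted ensemble (EEMD).

EMD adaptively splits a non-stationary signal into intrinsic mode functions
(IMFs) — oscillatory components whose extrema and zero-crossing counts differ
by at most one and whose upper/lower spline envelopes have near-zero mean —
plus a slowly varying residue.  Sifting extracts each IMF by repeatedly
subtracting the mean of the cubic-spline envelopes through the local maxima
and minima.

EEMD runs EMD on many noise-perturbed copies of the signal (white Gaussian
noise at a fixed fraction of the signal's standard deviation) and averages
the resulting IMFs component-wise.  The noise populates the whole
time–frequency plane, curing the mode-mixing artefacts of plain EMD, and
cancels in the ensemble mean at the usual 1/sqrt(M) rate.

Conventions (documented in docs/methods.md):

* extrema are strict interior sign changes of the first difference; on a
  plateau the first point after the rise (fall) is taken;
* before spline fitting, up to two nearest extrema are mirrored across each
  endpoint to suppress end swings; splines are natural cubics;
* a signal is *sift-terminal* when it has fewer than two interior extrema
  (equivalently: no full oscillation left), which guarantees the residue has
  at most one interior extremum;
* sifting stops when the interior envelope-mean amplitude ratio drops below
  ``threshold`` (default 0.05) and the zero-crossing/extrema count test
  passes, or after ``max_iterations`` (default 30); the outermost 5 % of
  samples at each end are excluded from the ratio because spline envelopes
  are extrapolation-dominated there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "find_extrema",
    "envelopes",
    "sift",
    "emd",
    "eemd",
    "validate_imf",
    "Decomposition",
    "IMFReport",
    "is_sift_terminal",
]

#: sifting envelope-mean tolerance: interior max|m(t)| / half peak-to-peak
DEFAULT_ENV_TOL = 0.05
DEFAULT_MAX_SIFT = 30
#: validation tolerance on the same ratio for emitted IMFs
DEFAULT_VALIDATE_TOL = 0.05


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Plateaus are collapsed by carrying the last non-zero slope sign forward,
    so a flat-topped peak is reported once, at the end of the rise.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.sign(np.diff(x))
    # propagate the previous non-zero slope through flat segments
    nz = d != 0
    if not nz.all():
        idx = np.where(nz, np.arange(len(d)), -1)
        np.maximum.accumulate(idx, out=idx)
        d = np.where(idx >= 0, d[np.maximum(idx, 0)], 0.0)
    change = d[1:] - d[:-1]
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def zero_crossings(signal: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros between them."""
    x = np.asarray(signal, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def is_sift_terminal(signal: np.ndarray) -> bool:
    """True when no full oscillation remains (fewer than 2 interior extrema)."""
    maxima, minima = find_extrema(signal)
    return len(maxima) + len(minima) < 2


def _mirror_knots(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    # Reflect up to two nearest extrema across each endpoint (t=0 and t=n-1).
    left_i = (-idx[:2])[::-1]
    left_v = vals[:2][::-1]
    right_i = (2 * (n - 1) - idx[-2:])[::-1]
    right_v = vals[-2:][::-1]
    knots_i = np.concatenate([left_i, idx, right_i])
    knots_v = np.concatenate([left_v, vals, right_v])
    # drop any coincident knots produced by extrema at/near the ends
    keep = np.concatenate([[True], np.diff(knots_i) > 0])
    return knots_i[keep], knots_v[keep]


def envelopes(
    signal: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Natural-cubic-spline upper/lower envelopes on the full sample grid.

    Returns ``None`` for a sift-terminal signal (no envelope pair exists);
    callers treat that as "stop", not as an error.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if len(maxima) + len(minima) < 2 or len(maxima) == 0 or len(minima) == 0:
        return None
    t = np.arange(n, dtype=float)

    def _fit(idx: np.ndarray) -> np.ndarray:
        ki, kv = _mirror_knots(idx, x[idx], n)
        if len(ki) < 2:
            return np.full(n, kv[0])
        if len(ki) < 4:
            # too few knots for a cubic: fall back to an exact lower-order fit
            return CubicSpline(ki, kv, bc_type="natural")(t) if len(ki) >= 3 else np.interp(t, ki, kv)
        return CubicSpline(ki, kv, bc_type="natural")(t)

    return _fit(maxima), _fit(minima)


#: fraction of samples at each end excluded from the envelope-mean ratio —
#: spline envelopes are extrapolation-dominated there
EDGE_MARGIN = 0.05


def _envelope_mean_ratio(m: np.ndarray, amp: float) -> float:
    """max |envelope mean| over the interior, relative to the amplitude."""
    n = len(m)
    k = max(1, int(EDGE_MARGIN * n))
    interior = m[k : n - k] if n > 2 * k else m
    if amp <= 0:
        return 0.0
    return float(np.max(np.abs(interior)) / amp)


@dataclass
class IMFReport:
    """Diagnostics of the two defining IMF properties."""

    passed: bool
    n_extrema: int
    n_zero_crossings: int
    envelope_mean_ratio: float


def validate_imf(component: np.ndarray, tol: float = DEFAULT_VALIDATE_TOL) -> IMFReport:
    """Check the IMF properties: extrema and zero-crossing counts equal or
    differing by one, and envelope mean small relative to the amplitude."""
    x = np.asarray(component, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = len(maxima) + len(minima)
    n_zc = zero_crossings(x)
    env = envelopes(x, maxima, minima)
    amp = 0.5 * (x.max() - x.min())
    if env is None or amp == 0:
        ratio = np.inf if amp else 0.0
    else:
        upper, lower = env
        ratio = _envelope_mean_ratio(0.5 * (upper + lower), amp)
    passed = abs(n_ext - n_zc) <= 1 and n_ext >= 2 and ratio <= tol
    return IMFReport(passed, n_ext, n_zc, ratio)


@dataclass
class SiftResult:
    imf: np.ndarray
    iterations: int
    converged: bool


def sift(
    signal: np.ndarray,
    max_iterations: int = DEFAULT_MAX_SIFT,
    threshold: float = DEFAULT_ENV_TOL,
) -> SiftResult:
    """Extract one IMF: repeatedly subtract the envelope mean ``h ← h − m``.

    Stops when the envelope-mean ratio falls below ``threshold`` and the
    zero-crossing/extrema test passes, or at the iteration cap (in which
    case ``converged`` is False and the current refinement is returned).
    """
    h = np.asarray(signal, dtype=float).copy()
    if is_sift_terminal(h):
        raise ValueError("signal is sift-terminal: no oscillation to extract")
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        maxima, minima = find_extrema(h)
        env = envelopes(h, maxima, minima)
        if env is None:
            converged = True  # over-sifted to terminal; accept as-is
            break
        upper, lower = env
        m = 0.5 * (upper + lower)
        amp = 0.5 * (h.max() - h.min())
        n_ext = len(maxima) + len(minima)
        n_zc = zero_crossings(h)
        if amp > 0 and _envelope_mean_ratio(m, amp) < threshold and abs(n_ext - n_zc) <= 1:
            converged = True
            break
        h = h - m
    return SiftResult(imf=h, iterations=it, converged=converged)


@dataclass
class Decomposition:
    """Ordered IMFs (highest frequency first) plus the residue trend."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    ensemble_size: int = 1
    noise_amplitude: float = 0.0
    seed: int | None = None
    sift_warnings: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.residue)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruction(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def components(self) -> list[np.ndarray]:
        """IMFs followed by the residue, in forecasting order."""
        return [*self.imfs, self.residue]

    def write_csv(self, path: str | Path) -> None:
        import pandas as pd

        cols = {f"imf{i + 1}": c for i, c in enumerate(self.imfs)}
        cols["residue"] = self.residue
        df = pd.DataFrame(cols)
        df.index.name = "t"
        df.to_csv(path, float_format="%.12g")
        meta = {
            "ensemble_size": self.ensemble_size,
            "noise_amplitude": self.noise_amplitude,
            "seed": self.seed,
            "n_imfs": self.n_imfs,
            "n_samples": self.n_samples,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


#: residue stop: peak-to-peak below this fraction of the input's is "spent"
RESIDUE_FLOOR = 1e-10


def emd(
    signal: np.ndarray,
    max_imf: int | None = None,
    max_iterations: int = DEFAULT_MAX_SIFT,
    threshold: float = DEFAULT_ENV_TOL,
) -> Decomposition:
    """Plain EMD: sift out IMFs until the residue cannot oscillate.

    Two stopping rules, both from the sifting procedure's definition: the
    residue is monotone-or-single-hump (no full oscillation left), or its
    amplitude has dropped below a predetermined floor (peak-to-peak under
    ``RESIDUE_FLOOR`` of the input's — without this, rounding noise in an
    exactly-decomposed signal reads as endless spurious extrema).

    Completeness is structural: the residue is literally what is left after
    subtracting each extracted IMF, so IMFs + residue re-sum to the input to
    rounding error.  ``max_imf`` caps the expansion; anything beyond the cap
    stays in the residue.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 4:
        raise ValueError(f"signal too short for EMD (n={len(x)})")
    imfs: list[np.ndarray] = []
    warnings: list[int] = []
    residue = x.copy()
    floor = RESIDUE_FLOOR * float(np.ptp(x))
    while not is_sift_terminal(residue) and np.ptp(residue) > floor:
        if max_imf is not None and len(imfs) >= max_imf:
            break
        result = sift(residue, max_iterations=max_iterations, threshold=threshold)
        imfs.append(result.imf)
        if not result.converged:
            warnings.append(len(imfs))
        residue = residue - result.imf
    return Decomposition(imfs=imfs, residue=residue, sift_warnings=warnings)


def eemd(
    signal: np.ndarray,
    ensemble_size: int = 100,
    noise_amplitude: float = 0.2,
    seed: int | None = None,
    max_imf: int | None = None,
    max_iterations: int = DEFAULT_MAX_SIFT,
    threshold: float = DEFAULT_ENV_TOL,
) -> Decomposition:
    """Ensemble EMD: average the IMFs of ``ensemble_size`` noisy trials.

    ``noise_amplitude`` is the white-noise standard deviation as a fraction
    of the signal's (default 0.2).  Each trial draws its noise from an
    independent substream spawned from ``seed``, so the output is a pure
    function of (signal, ensemble_size, noise_amplitude, seed).  Trials can
    yield different IMF counts; shorter trials are padded with zero
    components at the low-frequency end before averaging, and the residues
    are averaged over all trials.
    """
    x = np.asarray(signal, dtype=float)
    if ensemble_size < 1:
        raise ValueError(f"ensemble_size must be >= 1, got {ensemble_size}")
    if noise_amplitude < 0:
        raise ValueError(f"noise_amplitude must be >= 0, got {noise_amplitude}")
    sigma = noise_amplitude * float(np.std(x))
    streams = np.random.SeedSequence(seed).spawn(ensemble_size)
    trials: list[Decomposition] = []
    for ss in streams:
        if sigma > 0:
            noise = np.random.default_rng(ss).standard_normal(len(x)) * sigma
            xm = x + noise
        else:
            xm = x
        trials.append(
            emd(xm, max_imf=max_imf, max_iterations=max_iterations, threshold=threshold)
        )
    n_imfs = max(t.n_imfs for t in trials)
    mean_imfs = [np.zeros(len(x)) for _ in range(n_imfs)]
    mean_residue = np.zeros(len(x))
    for t in trials:
        for i, c in enumerate(t.imfs):
            mean_imfs[i] += c
        mean_residue += t.residue
    mean_imfs = [c / ensemble_size for c in mean_imfs]
    mean_residue /= ensemble_size
    warnings = sorted({w for t in trials for w in t.sift_warnings})
    return Decomposition(
        imfs=mean_imfs,
        residue=mean_residue,
        ensemble_size=ensemble_size,
        noise_amplitude=noise_amplitude,
        seed=seed,
        sift_warnings=warnings,
    )
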