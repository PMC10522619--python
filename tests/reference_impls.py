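"""Slow, literal reference implementations used only as test oracles.

Each function re-derives a quantity from its definition with plain loops,
independently of the package's vectorized code paths (only generic
primitives such as cubic-spline interpolation are shared).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


# ---------------------------------------------------------------------------
# EMD: literal staged transcription (find extrema -> spline envelopes ->
# envelope-mean subtraction -> residue separation), plain loops throughout.
# Shares the package's documented conventions: plateau slope carry-forward,
# two mirrored extrema per end, natural splines, interior envelope-mean
# stopping ratio with a 5 % edge margin, residue amplitude floor.
# ---------------------------------------------------------------------------

def ref_find_extrema(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    maxima, minima = [], []
    if n < 3:
        return maxima, minima
    slopes = []
    last = 0.0
    for i in range(1, n):
        d = x[i] - x[i - 1]
        s = 1.0 if d > 0 else (-1.0 if d < 0 else last)
        slopes.append(s)
        if s != 0:
            last = s
    for i in range(1, len(slopes)):
        if slopes[i] < slopes[i - 1]:
            maxima.append(i)
        elif slopes[i] > slopes[i - 1]:
            minima.append(i)
    return maxima, minima


def ref_zero_crossings(x):
    signs = [1 if v > 0 else (-1 if v < 0 else 0) for v in x]
    signs = [s for s in signs if s != 0]
    count = 0
    for a, b in zip(signs, signs[1:]):
        if a != b:
            count += 1
    return count


def _ref_envelope(idx, vals, n):
    idx = list(idx)
    vals = list(vals)
    left_i = [-i for i in idx[:2]][::-1]
    left_v = vals[:2][::-1]
    right_i = [2 * (n - 1) - i for i in idx[-2:]][::-1]
    right_v = vals[-2:][::-1]
    ki = left_i + idx + right_i
    kv = left_v + vals + right_v
    keep_i, keep_v = [ki[0]], [kv[0]]
    for a, b in zip(ki[1:], kv[1:]):
        if a > keep_i[-1]:
            keep_i.append(a)
            keep_v.append(b)
    t = np.arange(n, dtype=float)
    if len(keep_i) < 2:
        return np.full(n, keep_v[0])
    if len(keep_i) == 2:
        return np.interp(t, keep_i, keep_v)
    return CubicSpline(np.asarray(keep_i, float), np.asarray(keep_v, float),
                       bc_type="natural")(t)


def ref_env_ratio(m, amp, margin=0.05):
    n = len(m)
    k = max(1, int(margin * n))
    interior = m[k : n - k] if n > 2 * k else m
    if amp <= 0:
        return 0.0
    return max(abs(v) for v in interior) / amp


def ref_sift(x, max_iterations=30, threshold=0.05):
    h = np.asarray(x, dtype=float).copy()
    for _ in range(max_iterations):
        maxima, minima = ref_find_extrema(h)
        if len(maxima) + len(minima) < 2 or not maxima or not minima:
            break
        upper = _ref_envelope(maxima, [h[i] for i in maxima], len(h))
        lower = _ref_envelope(minima, [h[i] for i in minima], len(h))
        m = 0.5 * (upper + lower)
        amp = 0.5 * (max(h) - min(h))
        n_ext = len(maxima) + len(minima)
        n_zc = ref_zero_crossings(h)
        if amp > 0 and ref_env_ratio(m, amp) < threshold and abs(n_ext - n_zc) <= 1:
            break
        h = h - m
    return h


def ref_emd(x, max_imf=None, max_iterations=30, threshold=0.05, residue_floor=1e-10):
    x = np.asarray(x, dtype=float)
    imfs = []
    residue = x.copy()
    floor = residue_floor * (max(x) - min(x))
    while True:
        maxima, minima = ref_find_extrema(residue)
        if len(maxima) + len(minima) < 2:
            break
        if (max(residue) - min(residue)) <= floor:
            break
        if max_imf is not None and len(imfs) >= max_imf:
            break
        c = ref_sift(residue, max_iterations, threshold)
        imfs.append(c)
        residue = residue - c
    return imfs, residue


# ---------------------------------------------------------------------------
# LSTM cell: one-step literal transcription of the gate equations.
# ---------------------------------------------------------------------------

def ref_lstm_cell(x_t, h_prev, c_prev, W_f, W_i, W_c, W_o, b_f, b_i, b_c, b_o,
                  tied_candidate=False):
    x_t = np.asarray(x_t, float)
    h_prev = np.asarray(h_prev, float)
    c_prev = np.asarray(c_prev, float)
    hx = np.concatenate([h_prev, x_t])

    def sigma(v):
        return 1.0 / (1.0 + np.exp(-v))

    F = sigma(W_f @ hx + b_f)
    I = sigma(W_i @ hx + b_i)
    if tied_candidate:
        G = np.tanh(W_i @ hx + b_i)
    else:
        G = np.tanh(W_c @ hx + b_c)
    O = sigma(W_o @ hx + b_o)
    C = F * c_prev + I * G
    h = O * np.tanh(C)
    return h, C


# ---------------------------------------------------------------------------
# MLR: normal equations, explicit.
# ---------------------------------------------------------------------------

def ref_mlr_beta(X, Y):
    X = np.atleast_2d(np.asarray(X, float))
    Xd = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(Xd.T @ Xd) @ Xd.T @ np.asarray(Y, float)


# ---------------------------------------------------------------------------
# Rolling-median/MAD outlier rule and centred moving average, brute force.
# ---------------------------------------------------------------------------

def ref_outlier_flags(values, window, k):
    values = np.asarray(values, float)
    n = len(values)
    half = window // 2
    flags = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = values[lo:hi]
        seg = seg[~np.isnan(seg)]
        if len(seg) == 0 or np.isnan(values[i]):
            continue
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        scale = 1.4826 * mad
        if scale > 0 and abs(values[i] - med) > k * scale:
            flags.append(i)
    return flags


def ref_centred_moving_average(values, width):
    values = np.asarray(values, float)
    n = len(values)
    out = np.empty(n)
    if width % 2 == 1:
        kernel = np.full(width, 1.0 / width)
    else:
        kernel = np.ones(width + 1)
        kernel[0] = kernel[-1] = 0.5
        kernel /= width
    half = len(kernel) // 2
    for i in range(n):
        r = min(half, i, n - 1 - i)
        if r == half:
            out[i] = float(np.dot(values[i - half : i + half + 1], kernel))
        else:
            out[i] = values[i - r : i + r + 1].mean()
    return out
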