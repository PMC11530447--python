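"""Vectorised sliding-window Pearson correlation primitives.

These back both the observed inter-subject correlations and the
circular-shuffle permutation nulls, so they are written to be fast for
stacked inputs: correlating one series against many partner series (or many
shifted copies of itself) in a single pass of rolling cumulative sums.

Windows where either series is (numerically) constant have no defined
Pearson correlation and are returned as NaN; downstream summaries use
NaN-aware reductions.
"""

from __future__ import annotations

import numpy as np

# Relative tolerance deciding that a window's variance is numerically zero.
_VAR_RTOL = 1e-10


def rolling_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Rolling sum of the trailing axis over windows of length ``w``."""
    c = np.cumsum(a, axis=-1, dtype=np.float64)
    out = c[..., w - 1 :].copy()
    out[..., 1:] -= c[..., :-w]
    return out


def sliding_pearson(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Pearson r of ``x`` vs ``y`` over every length-``window`` window.

    ``x`` has shape (T,) or (..., T); ``y`` has shape (..., T); the leading
    shapes must broadcast.  Returns an array of shape broadcast(...) x
    (T - window + 1) with NaN where either window is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("x and y must share the time axis length")
    T = x.shape[-1]
    if window < 2 or window > T:
        raise ValueError(f"window must be in [2, {T}], got {window}")
    # Pearson is translation-invariant: removing each full-series mean keeps
    # the rolling-cumsum algebra well conditioned for large-offset signals.
    x = x - x.mean(axis=-1, keepdims=True)
    y = y - y.mean(axis=-1, keepdims=True)

    sx, sxx = rolling_sum(x, window), rolling_sum(x * x, window)
    sy, syy = rolling_sum(y, window), rolling_sum(y * y, window)
    sxy = rolling_sum(np.multiply(x, y), window)

    vx = sxx - sx * sx / window
    vy = syy - sy * sy / window
    cov = sxy - sx * sy / window
    bad = (vx <= _VAR_RTOL * np.maximum(sxx, 0)) | (vy <= _VAR_RTOL * np.maximum(syy, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    r = np.clip(r, -1.0, 1.0)
    r = np.where(bad, np.nan, r)
    return r


def circularly_shifted_matrix(x: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Stack circular shifts of ``x``: row k is ``np.roll(x, offsets[k])``."""
    x = np.asarray(x, dtype=float)
    offsets = np.asarray(offsets, dtype=int)
    T = len(x)
    idx = (np.arange(T)[None, :] - offsets[:, None]) % T
    return x[idx]


def pair_mean_over_windows(r: np.ndarray) -> np.ndarray:
    """Collapse window correlations to one scalar per pair (NaN-aware mean)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(r, axis=-1)


def shifted_pair_scalars(
    XS: np.ndarray, Y: np.ndarray, window: int, dtype=np.float32
) -> np.ndarray:
    """Pair scalars (mean over windows of Pearson r) for many shifted copies.

    ``XS`` (n_shift, T) stacks rotated copies of one target series; ``Y``
    (P, T) the partner series.  Returns (P, n_shift).  This is the
    permutation-null workhorse: a loop over partners with preallocated
    rolling sums, run in float32 by default — null ISCs are compared at
    decision level, where ~1e-7 relative error is immaterial.  Falls back
    to the NaN-aware float64 path when any window is constant.
    """
    XS = np.ascontiguousarray(XS)
    Y = np.atleast_2d(np.ascontiguousarray(Y))
    T = XS.shape[1]
    w = window
    tol = _VAR_RTOL

    XS0 = (XS - XS.mean(axis=1, keepdims=True)).astype(dtype)
    Y0 = (Y - Y.mean(axis=1, keepdims=True)).astype(dtype)
    sx, sxx = rolling_sum(XS0, w), rolling_sum(XS0 * XS0, w)
    vx = sxx - sx * sx / w
    sy, syy = rolling_sum(Y0, w), rolling_sum(Y0 * Y0, w)
    vy = syy - sy * sy / w
    if np.any(vx <= tol * np.maximum(sxx, 0)) or np.any(vy <= tol * np.maximum(syy, 0)):
        # degenerate windows: take the exact NaN-aware route
        r = sliding_pearson(XS[None, :, :], Y[:, None, :], w)
        return pair_mean_over_windows(r)
    ivx = 1.0 / np.sqrt(vx)
    ivy = 1.0 / np.sqrt(vy)
    sy_w = sy / w
    out = np.empty((Y.shape[0], XS.shape[0]), dtype=np.float64)
    for p in range(Y.shape[0]):
        sxy = rolling_sum(XS0 * Y0[p], w)
        r = (sxy - sx * sy_w[p]) * ivx
        r *= ivy[p]
        out[p] = r.mean(axis=1)
    return out
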