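"""Local quadratic-regression smoothing and differentiation.

Tracked marker trajectories are smoothed by fitting a quadratic
polynomial over a moving time window (25 ms for body landmarks, 5 ms for
the faster legs, at 1000 fps) and evaluating the fit at the window
centre; derivatives are the slope of the same local fit.  The robust
variant iteratively zero-weights samples lying more than 6 mean absolute
deviations from the local fit, which suppresses isolated tracking
glitches.  Quadratics are a fixed point of the smoother and are
differentiated exactly.

NaN samples are treated as absent: they get zero weight and the output
is NaN only where too few valid samples remain in the window.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["smooth_series", "derivative", "window_samples"]

_MAD_CUTOFF = 6.0
_ROBUST_ITER = 2


def window_samples(window_ms: float, frame_rate: float) -> int:
    """Convert a window length in ms to an odd sample count.

    Raises ``ValueError`` if the window spans fewer than 3 samples.
    """
    n = int(round(window_ms * 1e-3 * frame_rate))
    if n % 2 == 0:
        n += 1
    if n < 3:
        raise ValueError(
            f"window of {window_ms} ms spans {n} sample(s) at "
            f"{frame_rate} fps; need >= 3"
        )
    return n


def _local_fit(t, x, w):
    """Weighted quadratic LS fit; returns (value, slope) at t=0 or None."""
    valid = w > 0
    if valid.sum() < 3:
        return None
    tv, xv, wv = t[valid], x[valid], w[valid]
    # Vandermonde in centred time; normal equations are well conditioned
    # because |t| <= window/2 is small.
    A = np.stack([np.ones_like(tv), tv, tv * tv], axis=1)
    Aw = A * wv[:, None]
    coef, *_ = np.linalg.lstsq(Aw, xv * wv, rcond=None)
    return coef


def _fit_series_at(x, times, half, deriv, robust, indices, out):
    """Exact local-fit evaluation at selected indices (slow path)."""
    n = x.size
    for i in indices:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = times[lo:hi] - times[i]
        xi = x[lo:hi]
        w = np.isfinite(xi).astype(float)
        xi = np.where(np.isfinite(xi), xi, 0.0)
        coef = _local_fit(t, xi, w)
        if coef is None:
            continue
        if robust:
            for _ in range(_ROBUST_ITER):
                resid = np.abs(xi - (coef[0] + coef[1] * t + coef[2] * t * t))
                mad = np.mean(resid[w > 0])
                if mad <= 0:
                    break
                w_new = (
                    np.isfinite(x[lo:hi]) & (resid <= _MAD_CUTOFF * mad)
                ).astype(float)
                coef_new = _local_fit(t, xi, w_new)
                if coef_new is None:
                    break
                coef, w = coef_new, w_new
        out[i] = coef[1] if deriv else coef[0]
    return out


def _column(x, times, frame_rate, nwin, deriv, robust):
    """One scalar series: Savitzky-Golay fast path, exact local fits
    where NaNs or robust-flagged outliers make the shared-stencil
    convolution invalid."""
    n = x.size
    half = nwin // 2
    finite = np.isfinite(x)
    if n < nwin or not finite.any():
        out = np.full(n, np.nan)
        return _fit_series_at(x, times, half, deriv, robust,
                              range(n), out)
    if finite.all():
        fast = savgol_filter(
            x, nwin, 2, deriv=int(deriv), delta=times[1] - times[0],
            mode="interp",
        )
        dirty = np.zeros(n, bool)
        if robust:
            smooth0 = fast if not deriv else savgol_filter(
                x, nwin, 2, delta=times[1] - times[0], mode="interp"
            )
            resid = np.abs(x - smooth0)
            local_mad = np.convolve(resid, np.ones(nwin) / nwin, mode="same")
            # conservative superset of the 6-MAD rule; flagged windows
            # are re-fit exactly below
            dirty = resid > 4.0 * np.maximum(local_mad, 1e-300)
        if not dirty.any():
            return fast
        affected = np.convolve(dirty.astype(float), np.ones(2 * half + 1),
                               mode="same") > 0
        out = fast.copy()
        return _fit_series_at(x, times, half, deriv, robust,
                              np.flatnonzero(affected), out)
    # NaNs present: exact fits where a window touches one, fast elsewhere
    out = np.full(n, np.nan)
    bad = ~finite
    affected = np.convolve(bad.astype(float), np.ones(2 * half + 1),
                           mode="same") > 0
    if (~affected).any():
        fast = savgol_filter(
            np.where(finite, x, 0.0), nwin, 2, deriv=int(deriv),
            delta=times[1] - times[0], mode="interp",
        )
        out[~affected] = fast[~affected]
    return _fit_series_at(x, times, half, deriv, robust,
                          np.flatnonzero(affected), out)


def _apply(x, times, frame_rate, window_ms, deriv, robust):
    x = np.asarray(x, dtype=float)
    nwin = window_samples(window_ms, frame_rate)
    if x.ndim == 1:
        return _column(x, times, frame_rate, nwin, deriv, robust)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _column(x[:, j], times, frame_rate, nwin, deriv, robust)
    return out


def smooth_series(
    x,
    frame_rate: float,
    window_ms: float = 25.0,
    robust: bool = False,
    times=None,
) -> np.ndarray:
    """Smooth a (possibly multi-column) time series.

    Each sample is replaced by the value of a local quadratic
    least-squares fit over a ``window_ms`` window; one-sided windows are
    used at the ends.  With ``robust=True``, samples more than 6 mean
    absolute deviations from the local fit are excluded and the fit
    repeated (twice).
    """
    x = np.asarray(x, dtype=float)
    if times is None:
        times = np.arange(x.shape[0]) / frame_rate
    return _apply(x, np.asarray(times, float), frame_rate, window_ms, False, robust)


def derivative(
    x,
    frame_rate: float,
    window_ms: float = 25.0,
    robust: bool = False,
    times=None,
) -> np.ndarray:
    """First time-derivative via the slope of the local quadratic fit."""
    x = np.asarray(x, dtype=float)
    if times is None:
        times = np.arange(x.shape[0]) / frame_rate
    return _apply(x, np.asarray(times, float), frame_rate, window_ms, True, robust)
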