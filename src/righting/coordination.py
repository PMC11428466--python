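"""Leg coordination via normalized cross-correlation of tarsus heights.

Foot motion is summarized by z_tarsus, the tarsus z-position in the body
frame (positive dorsal).  Coordination between legs j and k is the
discrete-time normalized cross-correlation of the zero-mean series,

    (z_j * z_k)(t_lag) = 1 / (n rms(z_j) rms(z_k)) * sum_i z_j(t_i) z_k(t_i + t_lag),

a biased (1/n over the full window) estimator normalized so every
autocorrelation equals 1 at zero lag.  The peak similarity and its lag
quantify phase offsets between swinging legs; hindlegs are excluded from
pairwise analysis because they serve mostly static roles.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .kinematics import Attitude

__all__ = [
    "tarsus_body_z",
    "normalized_xcorr",
    "coordination_summary",
    "CorrelationResult",
]


def tarsus_body_z(
    tarsus_positions: np.ndarray, attitudes: list[Attitude | None]
) -> np.ndarray:
    """Body-frame z-coordinate of a tarsus trajectory (positive dorsal).

    Each spatial-frame position is mapped into the body frame with the
    inverse attitude; frames with missing attitude give NaN.
    """
    pos = np.atleast_2d(np.asarray(tarsus_positions, float))
    out = np.full(pos.shape[0], np.nan)
    for i, att in enumerate(attitudes):
        if att is None or not np.all(np.isfinite(pos[i])):
            continue
        body = att.rotation.inv().apply(pos[i] - att.translation)
        out[i] = body[2]
    return out


@dataclasses.dataclass
class CorrelationResult:
    pair: tuple[str, str]
    lags: np.ndarray  # s, symmetric around 0
    values: np.ndarray  # dimensionless, in [-1, 1]
    peak_similarity: float
    peak_lag: float  # s


def _local_peaks(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima (sign change of the discrete derivative)."""
    d = np.diff(values)
    idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    return idx


def normalized_xcorr(
    z_j: np.ndarray,
    z_k: np.ndarray,
    frame_rate: float,
    max_lag_s: float | None = None,
    pair: tuple[str, str] = ("j", "k"),
    auto: bool | None = None,
) -> CorrelationResult:
    """Normalized cross-correlation over a symmetric lag sweep.

    Both series are mean-subtracted; the normalization is 1/(n rms_j
    rms_k) with n the series length, so the zero-lag autocorrelation is
    exactly 1.  ``max_lag_s`` defaults to half the window length.

    The peak similarity is the signed maximum over nonzero-lag local
    peaks for cross-pairs, and the maximum absolute value at nonzero lag
    for an autocorrelation (ties broken toward smaller |lag|).
    """
    z_j = np.asarray(z_j, float)
    z_k = np.asarray(z_k, float)
    if z_j.size != z_k.size:
        raise ValueError("series must have equal length")
    n = z_j.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    if auto is None:
        auto = z_j is z_k
    z_j = z_j - np.nanmean(z_j)
    z_k = z_k - np.nanmean(z_k)
    z_j = np.nan_to_num(z_j)
    z_k = np.nan_to_num(z_k)
    rms_j = np.sqrt(np.mean(z_j**2))
    rms_k = np.sqrt(np.mean(z_k**2))
    if rms_j <= 0 or rms_k <= 0:
        raise ValueError("constant (zero-variance) series: correlation undefined")
    max_lag = n // 2 if max_lag_s is None else int(round(max_lag_s * frame_rate))
    max_lag = min(max_lag, n - 1)
    full = np.correlate(z_k, z_j, mode="full")  # index n-1+L = sum z_j(i) z_k(i+L)
    lags_i = np.arange(-max_lag, max_lag + 1)
    values = full[n - 1 + lags_i] / (n * rms_j * rms_k)
    lags = lags_i / frame_rate

    center = max_lag  # index of zero lag
    if auto:
        cand = _local_peaks(np.abs(values))
        cand = cand[cand != center]
        if cand.size == 0:
            cand = np.array([int(np.argmax(np.where(lags_i == 0, -np.inf, np.abs(values))))])
        order = np.lexsort((np.abs(lags_i[cand]), -np.abs(values[cand])))
        best = cand[order[0]]
        peak_sim = float(abs(values[best]))
    else:
        cand = _local_peaks(values)
        if cand.size == 0:
            cand = np.array([int(np.argmax(values))])
        order = np.lexsort((np.abs(lags_i[cand]), -values[cand]))
        best = cand[order[0]]
        peak_sim = float(values[best])
    return CorrelationResult(
        pair=pair,
        lags=lags,
        values=values,
        peak_similarity=peak_sim,
        peak_lag=float(lags[best]),
    )


def coordination_summary(
    z_series: dict[str, np.ndarray],
    frame_rate: float,
    legs: tuple[str, ...] = ("L1", "R1", "L2", "R2"),
) -> dict:
    """Pairwise cross-correlation peaks among fore/mid legs.

    Returns ``{'pairs': [CorrelationResult...], 'auto': {leg: CorrelationResult}}``
    for all leg pairs with valid (non-constant) series.
    """
    present = [leg for leg in legs if leg in z_series]
    if len(present) < 2:
        raise ValueError("need at least two legs with series")
    pairs = []
    for a, b in itertools.combinations(present, 2):
        try:
            pairs.append(
                normalized_xcorr(
                    z_series[a], z_series[b], frame_rate, pair=(a, b),
                    auto=False,
                )
            )
        except ValueError:
            continue
    autos = {}
    for leg in present:
        try:
            autos[leg] = normalized_xcorr(
                z_series[leg], z_series[leg], frame_rate, pair=(leg, leg),
                auto=True,
            )
        except ValueError:
            continue
    return {"pairs": pairs, "auto": autos}
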