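"""Multiscale entropy (MSE): sample entropy on coarse-grained time series.

Sample entropy of a series x of length N with template length m and
tolerance r counts, over template start points i < j in [0, N-m-1],

    B = #{ (i, j) : max_{k<m}   |x[i+k] - x[j+k]| <= r }
    A = #{ (i, j) : max_{k<=m}  |x[i+k] - x[j+k]| <= r }

(self-matches excluded) and returns -ln(A/B); it is undefined (masked) when
A or B is zero.  Multiscale entropy evaluates this at progressively coarser
timescales, where scale tau averages non-overlapping blocks of tau samples.
The tolerance r is fixed per (epoch, channel) as a fraction of the SD of the
original, scale-1 series and reused at every scale (the convention of the
physionet reference algorithm).

White noise shows a rapid fall of sample entropy with scale; signals with
long-range temporal structure (1/f noise, EEG) decline more gradually and
exceed white noise at coarse scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MSEParams",
    "MSEMatrix",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "mse_for_recording",
]


@dataclass(frozen=True)
class MSEParams:
    """m: template length; r_fraction: tolerance as a fraction of the scale-1
    SD; max_scale: coarsest timescale; min_points: minimum coarse-grained
    length accepted for the entropy estimate."""

    m: int = 2
    r_fraction: float = 0.5
    max_scale: int = 20
    min_points: int = 50

    def __post_init__(self):
        if self.m < 1 or self.r_fraction <= 0 or self.max_scale < 1:
            raise ValueError("invalid MSE parameters")
        if self.min_points < self.m + 2:
            raise ValueError("min_points must be >= m + 2")


@dataclass
class MSEMatrix:
    """Sample entropy on a channel x scale grid."""

    values: np.ndarray  # (n_channels, n_scales)
    undefined: np.ndarray  # bool mask, True where entropy was undefined
    channel_labels: tuple
    scales: np.ndarray
    meta: dict = field(default_factory=dict)


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Average non-overlapping blocks of ``scale`` samples; scale 1 returns
    the series itself.  Trailing remainder samples are discarded."""
    series = np.asarray(series, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = series.shape[-1]
    if scale > n:
        raise ValueError("scale exceeds series length")
    if scale == 1:
        return series.copy()
    k = n // scale
    return series[..., : k * scale].reshape(*series.shape[:-1], k, scale).mean(axis=-1)


@njit(cache=True)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    n = x.shape[0]
    nt = n - m  # template start points 0 .. nt-1
    b = 0
    a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B); NaN when undefined (A = 0 or B = 0).

    ``r`` is the absolute tolerance; if None it defaults to 0.5 x SD of the
    series (population SD).
    """
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if r is None:
        r = 0.5 * float(x.std())
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    if len(x) < m + 2:
        raise ValueError("series shorter than m + 2")
    b, a = _sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        return float("nan")
    return float(np.log(b / a))  # == -ln(A/B)


def mse_curve(series: np.ndarray, params: MSEParams, r: float | None = None) -> np.ndarray:
    """Sample entropy at scales 1..max_scale for one series; NaN where
    undefined.  r defaults to r_fraction x SD of the scale-1 series and is
    held fixed across scales."""
    x = np.asarray(series, dtype=float)
    if r is None:
        r = params.r_fraction * float(x.std())
    if len(x) // params.max_scale < params.min_points:
        raise ValueError(
            f"coarsest scale {params.max_scale} leaves fewer than "
            f"{params.min_points} points"
        )
    out = np.empty(params.max_scale)
    for s in range(1, params.max_scale + 1):
        out[s - 1] = sample_entropy(coarse_grain(x, s), params.m, r)
    return out


def mse_for_recording(recording, params: MSEParams | None = None
                      ) -> tuple[list[MSEMatrix], MSEMatrix]:
    """Per-epoch MSE matrices plus the epoch-average matrix.

    The average ignores masked (undefined) entries per element; an element is
    masked in the average only where it is undefined in every epoch.
    """
    params = params or MSEParams()
    n_ep, n_ch, _ = recording.data.shape
    scales = np.arange(1, params.max_scale + 1)
    per_epoch: list[MSEMatrix] = []
    for ep in range(n_ep):
        vals = np.empty((n_ch, params.max_scale))
        for ch in range(n_ch):
            vals[ch] = mse_curve(recording.data[ep, ch], params)
        meta = {"participant": recording.participant_id, "session": recording.session,
                "state": recording.state, "epoch": ep}
        per_epoch.append(MSEMatrix(vals, np.isnan(vals),
                                   tuple(recording.channel_labels), scales, meta))
    stack = np.array([m.values for m in per_epoch])
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(stack, axis=0)
    undefined = np.all(np.isnan(stack), axis=0)
    avg = np.where(undefined, 0.0, avg)
    meta = {"participant": recording.participant_id, "session": recording.session,
            "state": recording.state, "epoch": "averaged"}
    return per_epoch, MSEMatrix(avg, undefined, tuple(recording.channel_labels),
                                scales, meta)
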