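"""Weighted phase lag index (WPLI) connectivity.

Two estimation routes are provided:

* **Across-epoch** — complex Fourier coefficients per epoch (Hanning taper up
  to 30 Hz, 7-taper dpss multitaper with 2 Hz half-bandwidth from 31 Hz);
  each epoch (x taper) contributes one cross-spectral observation and WPLI
  measures phase-lag consistency over epochs.
* **Within-epoch** — Morlet wavelet coefficients per time point (wavelet
  length rising linearly from 3 cycles at 4 Hz to 7 cycles at 50 Hz); WPLI
  measures consistency over time points inside a single epoch, enabling
  per-epoch connectivity matrices for single-participant analyses.

The estimator is the magnitude-weighted WPLI

    WPLI = |sum_k Im(X_k)| / sum_k |Im(X_k)|

over observations k of the cross-spectrum X = c_i * conj(c_j).  Because only
the imaginary part of the cross-spectrum enters, zero-lag (volume-conducted)
coupling is disregarded, and the result lies in [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import dpss, hann

__all__ = [
    "FrequencyGrid",
    "fourier_grid",
    "morlet_grid",
    "morlet_cycles",
    "enumerate_pairs",
    "CrossSpectrumSet",
    "ConnectivityMatrix",
    "fourier_cross_spectra",
    "morlet_cross_spectra",
    "wpli_from_cross_spectra",
    "wpli_across_epochs",
    "wpli_single_epoch",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered analysis frequencies plus the estimation method."""

    freqs: np.ndarray
    method: str  # "fourier" | "morlet"
    cycles: np.ndarray | None = None  # morlet only

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or len(f) == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.method not in ("fourier", "morlet"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "morlet":
            c = np.asarray(self.cycles, dtype=float)
            object.__setattr__(self, "cycles", c)
            if c.shape != f.shape:
                raise ValueError("cycles must match frequencies")
            if np.any(c < 3) or np.any(c > 7):
                raise ValueError("morlet cycles must lie in [3, 7]")

    def __len__(self):
        return len(self.freqs)


def fourier_grid(fmin: float = 1.0, fmax: float = 50.0, step: float = 0.5) -> FrequencyGrid:
    """Default across-epoch grid: 1.0-50.0 Hz in 0.5-Hz bins (99 bins).

    The 0.5 Hz bin (a single cycle per 2-s epoch) is excluded by default.
    """
    n = int(round((fmax - fmin) / step)) + 1
    return FrequencyGrid(fmin + step * np.arange(n), "fourier")


def morlet_cycles(freqs: np.ndarray) -> np.ndarray:
    """Wavelet length in cycles, linear from 3 at 4 Hz to 7 at 50 Hz."""
    return 3.0 + 4.0 * (np.asarray(freqs, dtype=float) - 4.0) / 46.0


def morlet_grid(fmin: float = 4.0, fmax: float = 50.0, step: float = 0.5) -> FrequencyGrid:
    """Default within-epoch grid: 4.0-50.0 Hz in 0.5-Hz steps (93 bins)."""
    n = int(round((fmax - fmin) / step)) + 1
    f = fmin + step * np.arange(n)
    return FrequencyGrid(f, "morlet", morlet_cycles(f))


def enumerate_pairs(channel_labels: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered channel pairs, lexicographic by (first, second) index."""
    labels = list(channel_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 channels")
    return list(itertools.combinations(labels, 2))


@dataclass
class CrossSpectrumSet:
    """Complex cross-spectra on an (observation, frequency, pair) grid.

    Observations are epochs/tapers (across-epoch route) or within-epoch time
    points (Morlet route).  ``valid[obs, freq]`` marks usable observations;
    the Morlet route masks edge time points, and the multitaper route marks
    only taper 0 (Hanning) valid below the multitaper boundary.
    """

    values: np.ndarray  # complex, (n_obs, n_freq, n_pairs)
    valid: np.ndarray  # bool, (n_obs, n_freq)
    grid: FrequencyGrid
    pairs: list[tuple[str, str]]
    observation_kind: str  # "epoch-taper" | "time-point"


@dataclass
class ConnectivityMatrix:
    """WPLI values on a frequency x channel-pair grid."""

    values: np.ndarray  # (n_freq, n_pairs), in [0, 1]
    denominator_zero: np.ndarray  # bool, same shape
    grid: FrequencyGrid
    pairs: list[tuple[str, str]]
    meta: dict = field(default_factory=dict)


def _pair_indices(n_ch: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n_ch, k=1)
    return iu[0], iu[1]


def fourier_cross_spectra(
    data: np.ndarray,
    sampling_rate: float,
    grid: FrequencyGrid,
    channel_labels: Sequence[str],
    hann_max_freq: float = 30.0,
    mt_half_bandwidth: float = 2.0,
) -> CrossSpectrumSet:
    """Per-epoch tapered Fourier cross-spectra for an epochs x channels x
    samples array.

    Grid bins at or below ``hann_max_freq`` use a single Hanning taper; bins
    above use a dpss multitaper with ``mt_half_bandwidth`` Hz smoothing
    (2TW - 1 tapers), each taper contributing one observation.
    """
    if grid.method != "fourier":
        raise ValueError("grid method must be 'fourier'")
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be epochs x channels x samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input")
    n_ep, n_ch, n_t = data.shape
    df = sampling_rate / n_t
    bins = grid.freqs / df
    if np.any(np.abs(bins - np.round(bins)) > 1e-6):
        raise ValueError("epoch length does not support the grid spacing")
    bins = np.round(bins).astype(int)
    if np.any(grid.freqs >= sampling_rate / 2):
        raise ValueError("grid frequencies must lie below Nyquist")

    nw = (n_t / sampling_rate) * mt_half_bandwidth
    n_tap = max(1, int(2 * nw - 1))
    tapers = np.vstack([hann(n_t, sym=False),
                        dpss(n_t, NW=nw, Kmax=n_tap, sym=False)])
    # taper 0 = Hanning (low bins); tapers 1..n_tap = dpss (high bins)
    coef = np.fft.rfft(data[:, None, :, :] * tapers[None, :, None, :], axis=3)
    coef = coef[:, :, :, bins]  # (n_ep, n_tap+1, n_ch, n_freq)

    ii, jj = _pair_indices(n_ch)
    cs = coef[:, :, ii, :] * np.conj(coef[:, :, jj, :])  # (ep, tap, pair, freq)
    cs = np.transpose(cs, (0, 1, 3, 2))  # (ep, tap, freq, pair)
    cs = cs.reshape(n_ep * (n_tap + 1), len(grid), len(ii))

    low = grid.freqs <= hann_max_freq
    valid_per_taper = np.zeros((n_tap + 1, len(grid)), dtype=bool)
    valid_per_taper[0, low] = True
    valid_per_taper[1:, ~low] = True
    valid = np.tile(valid_per_taper, (n_ep, 1))
    pairs = [(channel_labels[a], channel_labels[b]) for a, b in zip(ii, jj)]
    return CrossSpectrumSet(cs, valid, grid, pairs, "epoch-taper")


def _morlet_wavelet(freq: float, cycles: float, sampling_rate: float) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian SD sigma_t = cycles/(2 pi f),
    truncated at +-3 sigma."""
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(3 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    return np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))


def morlet_cross_spectra(
    epoch: np.ndarray,
    sampling_rate: float,
    grid: FrequencyGrid,
    channel_labels: Sequence[str],
) -> CrossSpectrumSet:
    """Within-epoch Morlet cross-spectra for one channels x samples epoch.

    Observations are time points; points within half the wavelet support of
    either epoch edge are masked invalid (per frequency).
    """
    if grid.method != "morlet":
        raise ValueError("grid method must be 'morlet'")
    if np.any(grid.freqs < 4.0):
        raise ValueError("morlet frequencies below 4 Hz are not supported")
    if np.any(grid.freqs >= sampling_rate / 2):
        raise ValueError("grid frequencies must lie below Nyquist")
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    n_ch, n_t = epoch.shape

    coef = np.empty((len(grid), n_ch, n_t), dtype=complex)
    valid = np.zeros((n_t, len(grid)), dtype=bool)
    for k, (f, c) in enumerate(zip(grid.freqs, grid.cycles)):
        w = _morlet_wavelet(f, c, sampling_rate)
        if len(w) > n_t:
            raise ValueError(f"epoch shorter than the {f} Hz wavelet")
        coef[k] = fftconvolve(epoch, w[None, :], mode="same", axes=1)
        half = len(w) // 2
        valid[half:n_t - half, k] = True

    ii, jj = _pair_indices(n_ch)
    cs = coef[:, ii, :] * np.conj(coef[:, jj, :])  # (freq, pair, time)
    cs = np.transpose(cs, (2, 0, 1))  # (time, freq, pair)
    pairs = [(channel_labels[a], channel_labels[b]) for a, b in zip(ii, jj)]
    return CrossSpectrumSet(cs, valid, grid, pairs, "time-point")


def wpli_from_cross_spectra(cs: CrossSpectrumSet, meta: dict | None = None) -> ConnectivityMatrix:
    """WPLI(f, pair) = |sum_k Im X_k| / sum_k |Im X_k| over valid observations.

    A zero denominator (all observations purely real — zero-lag coupling)
    yields 0 with the ``denominator_zero`` flag set, never NaN.
    """
    if cs.values.shape[0] == 0:
        raise ValueError("empty observation set")
    if np.any(cs.valid.sum(axis=0) < 2):
        raise ValueError("need >= 2 valid observations per frequency")
    im = np.where(cs.valid[:, :, None], np.imag(cs.values), 0.0)
    num = np.abs(im.sum(axis=0))
    den = np.abs(im).sum(axis=0)
    flagged = den <= 0
    values = np.where(flagged, 0.0, num / np.where(flagged, 1.0, den))
    return ConnectivityMatrix(values, flagged, cs.grid, cs.pairs, meta or {})


def wpli_across_epochs(recording, grid: FrequencyGrid | None = None, **kw) -> ConnectivityMatrix:
    """Across-epoch WPLI for an :class:`~eegpls.cohort.EpochedRecording`."""
    grid = grid or fourier_grid()
    cs = fourier_cross_spectra(recording.data, recording.sampling_rate, grid,
                               recording.channel_labels, **kw)
    meta = {"participant": recording.participant_id, "session": recording.session,
            "state": recording.state, "estimator": "fourier-across-epoch"}
    return wpli_from_cross_spectra(cs, meta)


def wpli_single_epoch(
    recording, grid: FrequencyGrid | None = None
) -> tuple[list[ConnectivityMatrix], ConnectivityMatrix]:
    """Per-epoch within-epoch (Morlet) WPLI plus the across-epoch average.

    Returns one matrix per epoch and a matrix of the element-wise mean over
    epochs (used for Morlet-based group analyses).
    """
    grid = grid or morlet_grid()
    out: list[ConnectivityMatrix] = []
    for ep_idx in range(recording.data.shape[0]):
        cs = morlet_cross_spectra(recording.data[ep_idx], recording.sampling_rate,
                                  grid, recording.channel_labels)
        meta = {"participant": recording.participant_id, "session": recording.session,
                "state": recording.state, "estimator": "morlet-single-epoch",
                "epoch": ep_idx}
        out.append(wpli_from_cross_spectra(cs, meta))
    avg = np.mean([m.values for m in out], axis=0)
    flags = np.logical_and.reduce([m.denominator_zero for m in out])
    meta = {"participant": recording.participant_id, "session": recording.session,
            "state": recording.state, "estimator": "morlet-epoch-average"}
    return out, ConnectivityMatrix(avg, flags, grid, out[0].pairs, meta)
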