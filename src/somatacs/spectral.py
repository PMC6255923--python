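"""Time-frequency analysis: Morlet spectrograms, factors-of-median
normalization, individual peak-alpha identification and band power.

Spectrograms are computed by convolving each epoch with a complex Morlet
wavelet

    w(t, f0) = A * exp(-t^2 / (2 sigma_t^2)) * exp(2 i pi f0 t),

with sigma_t = m / (2 pi f0), normalization A = 1 / (sigma_t sqrt(2 pi)),
and a constant m = 7 cycles. Power is the squared magnitude of the
convolved signal. Power is normalized to factors of the median (FOM): each
time-frequency value is divided by the per-frequency median over all
pre-stimulus (-1000..0 ms) samples concatenated across the trials of the
normalization group, so the normalized pre-stimulus median is exactly 1 at
every frequency.

The individual alpha frequency is the maximum of the pre-stimulus spectrum
within 7-14 Hz; band power averages FOM values over that peak +/- 2 Hz and
the pre-stimulus window. The stimulation frequency used by the tACS
protocol is estimated from resting baseline EEG with a stationary Welch
periodogram over the same 7-14 Hz band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DegenerateDataError
from .preprocess import EpochSet

__all__ = [
    "TFR",
    "BandPowerResult",
    "morlet_wavelet",
    "morlet_tfr",
    "fom_normalize",
    "peak_frequency",
    "band_power",
    "welch_peak",
    "DEFAULT_FREQS_HZ",
    "ALPHA_BAND_HZ",
    "SECONDARY_BANDS_HZ",
]

# analysis grid: 1-50 Hz in 1 Hz steps
DEFAULT_FREQS_HZ = np.arange(1.0, 51.0)
ALPHA_BAND_HZ = (7.0, 14.0)
# bands for the reported null contrasts (theta / beta / gamma)
SECONDARY_BANDS_HZ = {
    "theta": (4.0, 7.0),
    "beta": (15.0, 29.0),
    "gamma": (30.0, 50.0),
}
M_CYCLES = 7
# wavelet truncated at +/- this many Gaussian SDs
_SUPPORT_SD = 5.0


@dataclass
class TFR:
    """Trials x frequencies x time power array.

    ``norm_state`` tracks whether values are raw (uV^2) or factors of
    median; ``edge_mask`` flags (freq, time) samples where the truncated
    wavelet overruns the epoch (cone of influence)."""

    power: np.ndarray
    freqs_hz: np.ndarray
    t_ms: np.ndarray
    norm_state: Literal["raw", "fom"]
    m_cycles: int = M_CYCLES
    edge_mask: np.ndarray | None = None
    fom_median: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]


def morlet_wavelet(f0_hz: float, fs_hz: float, m: int = M_CYCLES) -> np.ndarray:
    """Sampled complex Morlet wavelet at centre frequency ``f0_hz``.

    sigma_t = m / (2 pi f0); support truncated at +/- 5 sigma_t."""
    sigma_t = m / (2.0 * np.pi * f0_hz)
    half = int(np.ceil(_SUPPORT_SD * sigma_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    a = 1.0 / (sigma_t * np.sqrt(2.0 * np.pi))
    return a * np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f0_hz * t)


def morlet_tfr(
    epochs: EpochSet,
    freqs_hz: np.ndarray | None = None,
    m: int = M_CYCLES,
    allow_short: bool = False,
) -> TFR:
    """Raw Morlet-wavelet power for every trial, frequency and time point.

    Power is the squared magnitude of the same-length complex convolution
    of each epoch with the wavelet. Samples closer to an epoch edge than
    the truncated wavelet half-support are flagged in ``edge_mask``.

    By default an epoch shorter than the wavelet support at the lowest
    requested frequency is an error; ``allow_short=True`` computes anyway
    (every sample of such frequencies is edge-flagged), which is how a
    full 1-50 Hz grid can be applied to 2 s epochs.
    """
    freqs = np.asarray(DEFAULT_FREQS_HZ if freqs_hz is None else freqs_hz, dtype=float)
    nyq = epochs.fs_hz / 2.0
    if freqs.min() <= 0 or freqs.max() >= nyq:
        raise ConfigError(f"analysis frequencies must lie in (0, {nyq}) Hz")
    n_samp = epochs.data.shape[1]
    lowest = freqs.min()
    min_len = 2 * int(np.ceil(_SUPPORT_SD * m / (2 * np.pi * lowest) * epochs.fs_hz)) + 1
    if n_samp < min_len and not allow_short:
        raise ConfigError(
            f"epoch of {n_samp} samples is shorter than the wavelet support at "
            f"{lowest} Hz; need at least {min_len} samples"
        )
    power = np.empty((epochs.n_trials, freqs.size, n_samp))
    edge = np.zeros((freqs.size, n_samp), dtype=bool)
    for i, f0 in enumerate(freqs):
        w = morlet_wavelet(f0, epochs.fs_hz, m)
        conv = sps.fftconvolve(epochs.data, w[np.newaxis, :], mode="same", axes=1)
        power[:, i, :] = np.abs(conv) ** 2
        half = (w.size - 1) // 2
        if half > 0:
            edge[i, :half] = True
            edge[i, -half:] = True
    return TFR(power=power, freqs_hz=freqs, t_ms=epochs.t_ms.copy(), norm_state="raw", m_cycles=m, edge_mask=edge)


def _prestim_mask(
    tfr: TFR, window_ms: tuple[float, float], exclude_edges: bool
) -> np.ndarray:
    t0, t1 = window_ms
    in_win = (tfr.t_ms >= t0) & (tfr.t_ms <= t1)
    if not in_win.any():
        raise ConfigError(f"window {window_ms} ms lies outside the epoch time axis")
    mask = np.broadcast_to(in_win, (tfr.freqs_hz.size, tfr.t_ms.size)).copy()
    if exclude_edges and tfr.edge_mask is not None:
        mask &= ~tfr.edge_mask
    return mask


def fom_normalize(
    tfr: TFR,
    prestim_window_ms: tuple[float, float] = (-1000.0, 0.0),
    exclude_edges: bool = False,
) -> TFR:
    """Normalize raw power to factors of the pre-stimulus median.

    The median is computed for each frequency over the pre-stimulus samples
    of all trials concatenated; every power value is divided by it, making
    the pre-stimulus median exactly 1. Edge-flagged samples are included by
    default (configurable)."""
    if tfr.norm_state != "raw":
        raise ConfigError("input TFR is already normalized")
    mask = _prestim_mask(tfr, prestim_window_ms, exclude_edges)
    med = np.empty(tfr.freqs_hz.size)
    for i in range(tfr.freqs_hz.size):
        med[i] = np.median(tfr.power[:, i, mask[i]])
    if np.any(med <= 0):
        bad = tfr.freqs_hz[med <= 0]
        raise DegenerateDataError(
            f"zero pre-stimulus median power at {bad} Hz; cannot normalize"
        )
    return replace(
        tfr,
        power=tfr.power / med[np.newaxis, :, np.newaxis],
        norm_state="fom",
        fom_median=med,
    )


def peak_frequency(
    tfr: TFR,
    band_hz: tuple[float, float] = ALPHA_BAND_HZ,
    prestim_window_ms: tuple[float, float] = (-1000.0, 0.0),
) -> float:
    """Individual peak frequency: maximum of the trial- and time-averaged
    pre-stimulus spectrum within ``band_hz``; ties break to the lowest
    frequency."""
    lo, hi = band_hz
    sel = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
    if not sel.any():
        raise ConfigError(f"band {band_hz} Hz lies outside the analysis grid")
    in_win = (tfr.t_ms >= prestim_window_ms[0]) & (tfr.t_ms <= prestim_window_ms[1])
    spectrum = tfr.power[:, :, in_win].mean(axis=(0, 2))
    idx = np.flatnonzero(sel)
    return float(tfr.freqs_hz[idx[np.argmax(spectrum[idx])]])


@dataclass
class BandPowerResult:
    """Per-trial mean normalized power over peak +/- halfwidth and the
    pre-stimulus window."""

    per_trial: np.ndarray
    band_hz: tuple[float, float]
    peak_hz: float
    window_ms: tuple[float, float]


def band_power(
    tfr: TFR,
    peak_hz: float,
    halfwidth_hz: float = 2.0,
    window_ms: tuple[float, float] = (-1000.0, 0.0),
    exclude_edges: bool = False,
) -> BandPowerResult:
    """Per-trial mean FOM power in the band ``peak_hz +/- halfwidth`` over
    ``window_ms``, with the band clipped to the analysis grid (warning)."""
    if tfr.norm_state != "fom":
        raise ConfigError("band power is defined on FOM-normalized TFRs")
    lo, hi = peak_hz - halfwidth_hz, peak_hz + halfwidth_hz
    gmin, gmax = tfr.freqs_hz.min(), tfr.freqs_hz.max()
    if lo < gmin or hi > gmax:
        warnings.warn(
            f"band {lo}-{hi} Hz clipped to the {gmin}-{gmax} Hz analysis grid",
            stacklevel=2,
        )
        lo, hi = max(lo, gmin), min(hi, gmax)
    fsel = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
    mask = _prestim_mask(tfr, window_ms, exclude_edges)
    sub = tfr.power[:, fsel, :]
    submask = mask[fsel]
    vals = np.array([sub[k][submask].mean() for k in range(tfr.n_trials)])
    return BandPowerResult(
        per_trial=vals, band_hz=(lo, hi), peak_hz=peak_hz, window_ms=window_ms
    )


def welch_peak(
    baseline_uv: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = ALPHA_BAND_HZ,
    seg_s: float = 2.0,
) -> float:
    """Stimulation-frequency estimate from resting baseline EEG.

    Welch PSD with ``seg_s``-long Hann segments at 50 % overlap; returns
    the frequency of the in-band maximum (ties to the lowest frequency)."""
    baseline_uv = np.asarray(baseline_uv, dtype=float)
    nperseg = int(round(seg_s * fs_hz))
    if nperseg > baseline_uv.size:
        raise ConfigError(
            f"Welch segment of {seg_s} s exceeds the {baseline_uv.size / fs_hz:.2f} s signal"
        )
    f, pxx = sps.welch(baseline_uv, fs=fs_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    if not sel.any():
        raise ConfigError(f"band {band_hz} Hz outside Welch frequency grid")
    idx = np.flatnonzero(sel)
    return float(f[idx[np.argmax(pxx[idx])]])
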