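"""Evoked-response averaging and windowed feature extraction.

Epochs are baseline-corrected per trial (mean of -150..0 ms subtracted),
averaged across trials over 0..1000 ms, and summarized by the windowed
features used to compare perception and stimulation conditions:

* the late peak: extremum (minimum, in the raw sensor sign convention)
  within 92-108 ms post-stimulus, value and latency;
* the early peak: extremum (maximum) within 60-88 ms;
* the inter-peak slope (uV/ms) between the two;
* the mean voltage within 68-84 ms, the window bracketing the early
  component whose emergence after alpha tACS is the contrast of interest.

All features are computed in the raw sensor sign convention; plots can be
flipped for display (a presentation choice only). Peak latencies are
reported on the sample grid (no sub-sample interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigError
from .preprocess import EpochSet

__all__ = [
    "ERPWaveform",
    "ERPFeatures",
    "baseline_correct",
    "average_erp",
    "window_extremum",
    "slope_feature",
    "window_mean",
    "extract_features",
    "BASELINE_WINDOW_MS",
    "PEAK100_WINDOW_MS",
    "PEAK70_WINDOW_MS",
    "EMERGENT_WINDOW_MS",
]

BASELINE_WINDOW_MS = (-150.0, 0.0)
PEAK100_WINDOW_MS = (92.0, 108.0)
PEAK70_WINDOW_MS = (60.0, 88.0)
EMERGENT_WINDOW_MS = (68.0, 84.0)


@dataclass
class ERPWaveform:
    """Trial-averaged evoked response over 0..1000 ms post-stimulus."""

    v_uv: np.ndarray
    t_ms: np.ndarray
    n_trials: int
    sem_uv: np.ndarray
    convention: Literal["raw", "flipped"] = "raw"

    def flipped(self) -> "ERPWaveform":
        """Sign-flipped copy (display convention: late peak positive)."""
        return ERPWaveform(
            v_uv=-self.v_uv,
            t_ms=self.t_ms.copy(),
            n_trials=self.n_trials,
            sem_uv=self.sem_uv.copy(),
            convention="flipped" if self.convention == "raw" else "raw",
        )


@dataclass
class ERPFeatures:
    """Windowed features of one averaged waveform."""

    peak100_uv: float
    latency100_ms: float
    peak70_uv: float
    latency70_ms: float
    slope_uv_per_ms: float
    mean68_84_uv: float


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> EpochSet:
    """Subtract each trial's mean voltage over ``window_ms`` from that trial."""
    sel = (epochs.t_ms >= window_ms[0]) & (epochs.t_ms <= window_ms[1])
    if not sel.any():
        raise ConfigError(f"baseline window {window_ms} ms outside the epoch")
    base = epochs.data[:, sel].mean(axis=1, keepdims=True)
    return EpochSet(
        data=epochs.data - base,
        fs_hz=epochs.fs_hz,
        t_ms=epochs.t_ms.copy(),
        labels=epochs.labels.copy(),
    )


def average_erp(epochs: EpochSet, span_ms: tuple[float, float] = (0.0, 1000.0)) -> ERPWaveform:
    """Pointwise mean and SEM across trials, restricted to ``span_ms``."""
    if epochs.n_trials < 1:
        raise ConfigError("cannot average an empty epoch set")
    sel = (epochs.t_ms >= span_ms[0]) & (epochs.t_ms <= span_ms[1])
    data = epochs.data[:, sel]
    n = epochs.n_trials
    sem = data.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(data.shape[1])
    return ERPWaveform(
        v_uv=data.mean(axis=0), t_ms=epochs.t_ms[sel], n_trials=n, sem_uv=sem
    )


def window_extremum(
    wave: ERPWaveform, window_ms: tuple[float, float], mode: Literal["min", "max"]
) -> tuple[float, float]:
    """Sample-grid extremum of the waveform in a closed time window.

    Returns (value_uv, latency_ms); ties break to the earliest sample."""
    sel = (wave.t_ms >= window_ms[0]) & (wave.t_ms <= window_ms[1])
    if not sel.any():
        raise ConfigError(f"window {window_ms} ms contains no samples")
    seg, t = wave.v_uv[sel], wave.t_ms[sel]
    k = int(np.argmin(seg) if mode == "min" else np.argmax(seg))
    return float(seg[k]), float(t[k])


def slope_feature(wave: ERPWaveform) -> float:
    """Inter-peak slope (uV/ms) from the early (60-88 ms maximum) to the
    late (92-108 ms minimum) component."""
    v70, t70 = window_extremum(wave, PEAK70_WINDOW_MS, "max")
    v100, t100 = window_extremum(wave, PEAK100_WINDOW_MS, "min")
    if t100 == t70:
        raise ConfigError("identical peak latencies; slope undefined")
    return (v100 - v70) / (t100 - t70)


def window_mean(
    wave: ERPWaveform, window_ms: tuple[float, float] = EMERGENT_WINDOW_MS
) -> float:
    """Mean voltage over samples whose time lies in the closed window."""
    sel = (wave.t_ms >= window_ms[0]) & (wave.t_ms <= window_ms[1])
    if not sel.any():
        raise ConfigError(f"window {window_ms} ms contains no samples")
    return float(wave.v_uv[sel].mean())


def extract_features(wave: ERPWaveform) -> ERPFeatures:
    """All windowed features of one averaged waveform."""
    v100, t100 = window_extremum(wave, PEAK100_WINDOW_MS, "min")
    v70, t70 = window_extremum(wave, PEAK70_WINDOW_MS, "max")
    return ERPFeatures(
        peak100_uv=v100,
        latency100_ms=t100,
        peak70_uv=v70,
        latency70_ms=t70,
        slope_uv_per_ms=(v100 - v70) / (t100 - t70),
        mean68_84_uv=window_mean(wave, EMERGENT_WINDOW_MS),
    )
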