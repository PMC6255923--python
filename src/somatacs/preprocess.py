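"""Preprocessing: the analysis-ready epoch contract.

Raw or synthetic epochs are brought to the analysis contract used by the
spectral and evoked-response modules: single channel (C3), 250 Hz, 1-50 Hz
band, stimulus-locked -1000..+1000 ms time axis, one labelled trial per
row. Channel cleaning (re-referencing, ICA, visual rejection) is out of
scope; pre-cleaned data enters through the same containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, EmptySelectionError

__all__ = ["EpochSet", "TARGET_FS_HZ", "BAND_HZ", "resample_filter", "select_trials"]

TARGET_FS_HZ = 250.0
BAND_HZ = (1.0, 50.0)
CHANNEL = "C3"


@dataclass
class EpochSet:
    """Per-trial voltage time series with a stimulus-locked time axis.

    data: (n_trials, n_samples) array in uV; t_ms has t = 0 at stimulus
    onset; labels is the trial table aligned row-for-row with data.
    """

    data: np.ndarray
    fs_hz: float
    t_ms: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.data.shape[1] != self.t_ms.size:
            raise ConfigError("time axis length must match epoch sample count")
        if len(self.labels) != self.data.shape[0]:
            raise ConfigError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            fs_hz=self.fs_hz,
            t_ms=self.t_ms.copy(),
            labels=self.labels.copy(),
        )


def _butter_sos(fs_hz: float) -> np.ndarray:
    # separate 4th-order high- and low-pass sections, cascaded
    lo, hi = BAND_HZ
    hp = signal.butter(4, lo, btype="highpass", fs=fs_hz, output="sos")
    lp = signal.butter(4, hi, btype="lowpass", fs=fs_hz, output="sos")
    return np.vstack([hp, lp])


def resample_filter(
    x: np.ndarray | EpochSet, fs_in: float | None = None
) -> np.ndarray | EpochSet:
    """Band-pass to 1-50 Hz and resample to the 250 Hz analysis rate.

    Filtering is a 4th-order Butterworth applied forward-backward
    (zero-phase, so evoked-response latencies are not biased), followed by
    polyphase resampling with anti-aliasing. Accepts a raw (…, n_samples)
    array plus ``fs_in``, or an :class:`EpochSet` (rate taken from it, time
    axis rebuilt from its span).
    """
    if isinstance(x, EpochSet):
        out = resample_filter(x.data, x.fs_hz)
        n_out = out.shape[-1]
        t0 = x.t_ms[0]
        t_ms = t0 + np.arange(n_out) * (1000.0 / TARGET_FS_HZ)
        return EpochSet(data=out, fs_hz=TARGET_FS_HZ, t_ms=t_ms, labels=x.labels.copy())

    if fs_in is None:
        raise ConfigError("fs_in is required for plain-array input")
    if fs_in < TARGET_FS_HZ:
        raise ConfigError(f"input rate {fs_in} Hz is below the 250 Hz analysis rate")
    x = np.asarray(x, dtype=float)
    y = signal.sosfiltfilt(_butter_sos(fs_in), x, axis=-1)
    if fs_in == TARGET_FS_HZ:
        return y
    frac = Fraction(int(round(TARGET_FS_HZ * 1000)), int(round(fs_in * 1000)))
    return signal.resample_poly(y, frac.numerator, frac.denominator, axis=-1)


def select_trials(
    epochs: EpochSet,
    stim_type: str | None = None,
    block: str | None = None,
    outcome: str | None = None,
    group: str | None = None,
) -> EpochSet:
    """Subset an EpochSet by trial labels, preserving order.

    EEG statistics downstream operate on threshold trials only
    (supra-threshold and null trials are excluded by selecting
    ``stim_type="threshold"``). An empty selection raises
    :class:`~somatacs.errors.EmptySelectionError` rather than returning a
    silent empty set.
    """
    mask = np.ones(epochs.n_trials, dtype=bool)
    for col, want in (
        ("stim_type", stim_type),
        ("block", block),
        ("outcome", outcome),
        ("group", group),
    ):
        if want is not None:
            mask &= (epochs.labels[col].astype(str) == want).to_numpy()
    if not mask.any():
        raise EmptySelectionError(
            f"no trials match stim_type={stim_type}, block={block}, "
            f"outcome={outcome}, group={group}"
        )
    return EpochSet(
        data=epochs.data[mask],
        fs_hz=epochs.fs_hz,
        t_ms=epochs.t_ms.copy(),
        labels=epochs.labels.loc[mask].reset_index(drop=True),
    )
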