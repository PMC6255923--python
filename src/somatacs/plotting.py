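"""Figure helpers: averaged evoked responses and time-frequency power.

Thin matplotlib layer over the analysis containers; every function returns
the Axes so callers can compose panels, and accepts an output path for
direct PNG/SVG export.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .erp import ERPWaveform
from .spectral import TFR

__all__ = ["plot_erp", "plot_tfr", "save_figure"]


def save_figure(ax, path: str | Path) -> None:
    ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(ax.figure)


def plot_erp(
    waves: dict[str, ERPWaveform],
    flipped: bool = False,
    window_ms: tuple[float, float] | None = None,
    ax=None,
    out: str | Path | None = None,
):
    """Overlay labelled averaged waveforms with +/- SEM bands.

    ``flipped=True`` inverts the voltage axis (display convention in which
    the ~100 ms peak points upward); ``window_ms`` shades a feature window.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for label, w in waves.items():
        v = -w.v_uv if flipped else w.v_uv
        sem = w.sem_uv
        ax.plot(w.t_ms, v, label=f"{label} (n={w.n_trials})")
        ax.fill_between(w.t_ms, v - sem, v + sem, alpha=0.25, linewidth=0)
    if window_ms is not None:
        ax.axvspan(*window_ms, color="0.85", zorder=0)
    ax.axhline(0.0, color="0.5", lw=0.5)
    ax.set_xlabel("time from stimulus (ms)")
    ax.set_ylabel(("-" if flipped else "") + "voltage (uV)")
    ax.legend(frameon=False, fontsize=8)
    if out is not None:
        save_figure(ax, out)
    return ax


def plot_tfr(
    tfr: TFR,
    trial_mean: bool = True,
    ax=None,
    out: str | Path | None = None,
):
    """Spectrogram of (trial-averaged) power; FOM maps are centred at 1."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    p = tfr.power.mean(axis=0) if trial_mean else tfr.power[0]
    mesh = ax.pcolormesh(tfr.t_ms, tfr.freqs_hz, p, shading="nearest", cmap="RdBu_r")
    ax.set_xlabel("time from stimulus (ms)")
    ax.set_ylabel("frequency (Hz)")
    label = "power (FOM)" if tfr.norm_state == "fom" else "power (uV^2)"
    ax.figure.colorbar(mesh, ax=ax, label=label)
    if out is not None:
        save_figure(ax, out)
    return ax
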