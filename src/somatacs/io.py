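"""File interfaces: trial tables (CSV/TSV), epochs (HDF5, FIF/EDF via MNE),
and YAML configuration trees.

The internal fixture format for epochs is a small HDF5 file holding the
trials x samples voltage array, the sampling rate, the stimulus-locked
time axis, the channel name, and the trial table; real recordings can
enter as MNE-readable epoch files (FIF) or raw EDF+ plus a trial-table CSV
joined on the trial index.
"""

from __future__ import annotations

from dataclasses import asdict
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .preprocess import CHANNEL, EpochSet
from .synthdata import (
    EEGGenParams,
    ErpComponent,
    ObserverModel,
    TacsProtocol,
    TaskConfig,
)

__all__ = [
    "save_trials",
    "load_trials",
    "save_epochs_h5",
    "load_epochs_h5",
    "epochs_to_mne",
    "save_epochs_fif",
    "load_epochs_fif",
    "load_config",
    "save_config",
]

_TRIAL_COLUMNS = [
    "index", "block", "stim_type", "intensity_um", "onset_jitter_s",
    "tacs_on", "group", "outcome", "alpha_amp",
]


def save_trials(trials: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the trial table as CSV (or TSV with sep='\\t')."""
    trials.to_csv(path, sep=sep, index=False)


def load_trials(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a trial table; the separator is inferred from the extension."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    trials = pd.read_csv(path, sep=sep)
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConfigError(f"trial table {path} lacks columns {missing}")
    return trials


def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to the internal HDF5 fixture format."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("t_ms", data=epochs.t_ms)
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["channel"] = CHANNEL
        buf = StringIO()
        epochs.labels.to_csv(buf, index=False)
        f.create_dataset("labels_csv", data=buf.getvalue())


def load_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        labels = pd.read_csv(StringIO(f["labels_csv"][()].decode()))
        return EpochSet(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            t_ms=f["t_ms"][()],
            labels=labels,
        )


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "FIF/EDF input-output requires MNE-Python (pip install mne)"
        ) from exc
    return mne


def epochs_to_mne(epochs: EpochSet):
    """Convert to an mne.EpochsArray (single channel, volts)."""
    mne = _require_mne()
    info = mne.create_info([CHANNEL], sfreq=epochs.fs_hz, ch_types="eeg")
    data = epochs.data[:, np.newaxis, :] * 1e-6  # uV -> V
    return mne.EpochsArray(
        data, info, tmin=epochs.t_ms[0] / 1000.0, verbose="error"
    )


def save_epochs_fif(epochs: EpochSet, path: str | Path) -> None:
    """Export epochs as FIF plus a side-car trial table CSV."""
    path = Path(path)
    epochs_to_mne(epochs).save(path, overwrite=True, verbose="error")
    save_trials(epochs.labels, path.with_suffix(".csv"))


def load_epochs_fif(
    path: str | Path, trials: str | Path | None = None, channel: str = CHANNEL
) -> EpochSet:
    """Read a FIF epochs file and join its trial table on the trial index."""
    mne = _require_mne()
    path = Path(path)
    ep = mne.read_epochs(path, preload=True, verbose="error")
    if channel not in ep.ch_names:
        raise ConfigError(
            f"channel {channel!r} not present in {path}; pass the analysis channel"
        )
    data = ep.get_data(picks=[channel])[:, 0, :] * 1e6  # V -> uV
    table_path = Path(trials) if trials is not None else path.with_suffix(".csv")
    labels = load_trials(table_path)
    if len(labels) != data.shape[0]:
        raise ConfigError(
            f"trial table ({len(labels)} rows) does not match {data.shape[0]} epochs"
        )
    return EpochSet(data=data, fs_hz=ep.info["sfreq"], t_ms=ep.times * 1000.0, labels=labels)


_SECTIONS = {
    "task": TaskConfig,
    "observer": ObserverModel,
    "protocol": TacsProtocol,
    "eeg": EEGGenParams,
}


def save_config(configs: dict, path: str | Path) -> None:
    """Dump a {task, observer, protocol, eeg} configuration tree to YAML."""
    tree = {}
    for key, obj in configs.items():
        d = asdict(obj)
        tree[key] = d
    with open(path, "w") as f:
        yaml.safe_dump(tree, f, sort_keys=False)


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML configuration tree.

    Absent sections fall back to defaults; unknown sections or fields are
    configuration errors (caught up-front, before any computation).
    """
    with open(path) as f:
        tree = yaml.safe_load(f) or {}
    unknown = set(tree) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    out = {}
    for key, cls in _SECTIONS.items():
        raw = dict(tree.get(key) or {})
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - valid
        if bad:
            raise ConfigError(f"unknown fields in section {key!r}: {sorted(bad)}")
        for field_name in ("jitter_range_s", "epoch_window_ms"):
            if field_name in raw and isinstance(raw[field_name], list):
                raw[field_name] = tuple(raw[field_name])
        if key == "eeg" and "erp_components" in raw:
            raw["erp_components"] = tuple(
                ErpComponent(**c) if isinstance(c, dict) else ErpComponent(*c)
                for c in raw["erp_components"]
            )
        out[key] = cls(**raw)
    return out
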