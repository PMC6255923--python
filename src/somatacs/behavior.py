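"""Behavioral summaries: per-block detection rates, baseline-normalized
performance change, and stimulus-intensity tracking.

Percent hits counts threshold-level trials only: supra-threshold catch
trials and null trials never enter the numerator or denominator (null-trial
false alarms are reported separately). Block-level quantities are
normalized to the pre-stimulation block as percent change from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "BehaviorSummary",
    "percent_hits",
    "false_alarm_rate",
    "pct_change_from_baseline",
    "intensity_summary",
    "summarize_behavior",
]

_BLOCKS = ("pre", "during", "post")


@dataclass
class BehaviorSummary:
    """Per-session behavioral summary across the three task blocks."""

    pct_hits: dict[str, float]
    pct_change: dict[str, float]          # during/post performance vs pre (%)
    mean_intensity_um: dict[str, float]
    sem_intensity_um: dict[str, float]
    norm_intensity_change: dict[str, float]
    false_alarm_pct: float


def _threshold_trials(trials: pd.DataFrame, block: str | None) -> pd.DataFrame:
    sub = trials[trials["stim_type"].astype(str) == "threshold"]
    if block is not None:
        sub = sub[sub["block"].astype(str) == block]
    if len(sub) == 0:
        raise ConfigError(f"no threshold trials in block {block!r}")
    return sub


def percent_hits(trials: pd.DataFrame, block: str | None = None) -> float:
    """100 x hits / threshold trials (optionally within one block)."""
    sub = _threshold_trials(trials, block)
    return 100.0 * (sub["outcome"] == "hit").mean()


def false_alarm_rate(trials: pd.DataFrame) -> float:
    """Percent 'hit' responses on null trials (reported separately; never
    part of percent_hits)."""
    nulls = trials[trials["stim_type"].astype(str) == "null"]
    if len(nulls) == 0:
        return float("nan")
    return 100.0 * (nulls["outcome"] == "hit").mean()


def pct_change_from_baseline(x_block: float, x_pre: float) -> float:
    """100 * (x_block - x_pre) / x_pre; requires a positive baseline."""
    if x_pre <= 0:
        raise ConfigError("baseline value must be > 0 for percent change")
    return 100.0 * (x_block - x_pre) / x_pre


def intensity_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean/SEM of delivered threshold-trial intensity (um) and
    its percent change from the pre-stimulation block."""
    rows = []
    for block in _BLOCKS:
        sub = _threshold_trials(trials, block)
        x = sub["intensity_um"].to_numpy(dtype=float)
        rows.append(
            {
                "block": block,
                "mean_um": x.mean(),
                "sem_um": x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).set_index("block")
    pre = out.loc["pre", "mean_um"]
    out["pct_change"] = [pct_change_from_baseline(v, pre) for v in out["mean_um"]]
    return out


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Full behavioral summary of one session."""
    hits = {b: percent_hits(trials, b) for b in _BLOCKS}
    change = {b: pct_change_from_baseline(hits[b], hits["pre"]) for b in ("during", "post")}
    intens = intensity_summary(trials)
    return BehaviorSummary(
        pct_hits=hits,
        pct_change=change,
        mean_intensity_um=intens["mean_um"].to_dict(),
        sem_intensity_um=intens["sem_um"].to_dict(),
        norm_intensity_change={
            b: intens.loc[b, "pct_change"] for b in ("during", "post")
        },
        false_alarm_pct=false_alarm_rate(trials),
    )
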