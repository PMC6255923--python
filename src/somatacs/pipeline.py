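"""End-to-end cohort simulation and analysis.

A cohort is a set of simulated subjects split into sham and alpha-tACS
groups, each with its own seed. For every subject the pipeline simulates a
session, brings the epochs to the 250 Hz / 1-50 Hz analysis contract,
restricts EEG analyses to threshold-level trials, and derives:

* pre-stimulus alpha power (factors of median, individual peak +/- 2 Hz)
  split by perception (hit/miss, pre-stimulation block) and by block
  (pre vs post stimulation);
* evoked-response features (late ~100 ms peak, early-to-late slope, and
  the 68-84 ms window mean that indexes the early component emerging
  after alpha tACS);
* behavioral summaries (percent hits per block, percent change from
  baseline, stimulus-intensity tracking).

The cohort-level statistical battery mirrors the study contrasts: paired
signed-rank tests for hit/miss and pre/post comparisons, Mann-Whitney U
tests between stimulation groups, Friedman tests across blocks with
Bonferroni-corrected post hocs, a Kolmogorov-Smirnov check of baseline
comparability, and the regression of alpha-power change on baseline power.

Everything is deterministic given the cohort seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import erp as erpmod
from . import spectral as spec
from .errors import ConfigError, DegenerateDataError, EmptySelectionError
from .preprocess import EpochSet, TARGET_FS_HZ, resample_filter, select_trials
from .stats import (
    RegressionResult,
    StatsResult,
    friedman_posthoc,
    ks_two_sample,
    linregress_baseline,
    mann_whitney_u,
    wilcoxon_sr,
)
from .synthdata import (
    EEGGenParams,
    ObserverModel,
    TacsProtocol,
    TaskConfig,
    run_session,
)

__all__ = ["CohortSpec", "CohortResult", "analyze_session", "run_cohort", "render_report"]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, per-subject seeds and shared configs.

    Subject seeds default to ``seed, seed+1, ...`` across the cohort
    (alpha-group subjects first, then sham), so a cohort is fully
    reproducible from one base seed. ``freqs_hz=None`` uses the full
    1-50 Hz analysis grid.
    """

    n_alpha: int = 6
    n_sham: int = 6
    seed: int = 1
    seeds: tuple[int, ...] | None = None
    task: TaskConfig = field(default_factory=TaskConfig)
    observer: ObserverModel = field(default_factory=ObserverModel)
    eeg: EEGGenParams = field(default_factory=EEGGenParams)
    freqs_hz: tuple[float, ...] | None = None
    with_eeg: bool = True

    def __post_init__(self) -> None:
        if self.n_alpha < 0 or self.n_sham < 0 or self.n_alpha + self.n_sham == 0:
            raise ConfigError("cohort must contain at least one subject")
        if self.seeds is not None:
            if len(self.seeds) != self.n_alpha + self.n_sham:
                raise ConfigError("need exactly one seed per subject")
            if len(set(self.seeds)) != len(self.seeds):
                raise ConfigError("subject seeds must be unique")

    def subject_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        n = self.n_alpha + self.n_sham
        return [self.seed + i for i in range(n)]

    def subject_groups(self) -> list[str]:
        return ["alpha"] * self.n_alpha + ["sham"] * self.n_sham


@dataclass
class CohortResult:
    """Per-subject summary table, raw trial tables, and the cohort stats."""

    subjects: pd.DataFrame
    trials: dict[str, pd.DataFrame]
    stats: dict[str, StatsResult]
    regressions: dict[str, RegressionResult]


def _alpha_band_power_by(
    epochs: EpochSet, freqs: np.ndarray
) -> tuple[float, pd.Series]:
    """FOM alpha band power per trial of one normalization group.

    Returns (peak frequency, per-trial FOM alpha power indexed like the
    epoch labels)."""
    tfr = spec.morlet_tfr(epochs, freqs_hz=freqs, allow_short=True)
    # peak identified on raw power (FOM pins every per-frequency median to 1,
    # so the raw spectrum is where an individual alpha peak is visible)
    peak = spec.peak_frequency(tfr)
    fom = spec.fom_normalize(tfr)
    bp = spec.band_power(fom, peak)
    return peak, pd.Series(bp.per_trial, index=epochs.labels.index)


def analyze_session(
    trials: pd.DataFrame,
    epochs: EpochSet | None,
    freqs_hz: np.ndarray | None = None,
) -> dict[str, float]:
    """Analyze one session into the per-subject summary row.

    EEG quantities are computed on threshold trials only. The spectral
    normalization (median) and the individual peak frequency are computed
    separately for the pre- and post-stimulation blocks of the session.
    """
    row: dict[str, float] = {}
    summary = beh.summarize_behavior(trials)
    for b in ("pre", "during", "post"):
        row[f"pct_hits_{b}"] = summary.pct_hits[b]
        row[f"intensity_{b}_um"] = summary.mean_intensity_um[b]
    for b in ("during", "post"):
        row[f"pct_change_{b}"] = summary.pct_change[b]
        row[f"intensity_change_{b}"] = summary.norm_intensity_change[b]
    row["false_alarm_pct"] = summary.false_alarm_pct

    if epochs is None:
        return row

    if epochs.fs_hz != TARGET_FS_HZ:
        epochs = resample_filter(epochs)
    freqs = np.asarray(spec.DEFAULT_FREQS_HZ if freqs_hz is None else freqs_hz)

    for block in ("pre", "post"):
        thr = select_trials(epochs, stim_type="threshold", block=block)
        peak, per_trial = _alpha_band_power_by(thr, freqs)
        row[f"peak_hz_{block}"] = peak
        row[f"alpha_{block}"] = per_trial.mean()
        outcomes = thr.labels["outcome"].to_numpy()
        for outcome in ("hit", "miss"):
            vals = per_trial[outcomes == outcome]
            row[f"alpha_{outcome}_{block}"] = vals.mean() if len(vals) else np.nan

        corrected = erpmod.baseline_correct(thr)
        feats = erpmod.extract_features(erpmod.average_erp(corrected))
        row[f"erp_mean68_84_{block}"] = feats.mean68_84_uv
        row[f"erp_peak100_{block}"] = feats.peak100_uv
        row[f"erp_slope_{block}"] = feats.slope_uv_per_ms
        if block == "pre":
            for outcome in ("hit", "miss"):
                try:
                    sub = select_trials(corrected, outcome=outcome)
                except EmptySelectionError:
                    row[f"erp_peak100_{outcome}"] = np.nan
                    row[f"erp_slope_{outcome}"] = np.nan
                    continue
                f = erpmod.extract_features(erpmod.average_erp(sub))
                row[f"erp_peak100_{outcome}"] = f.peak100_uv
                row[f"erp_slope_{outcome}"] = f.slope_uv_per_ms
    row["alpha_delta"] = row["alpha_post"] - row["alpha_pre"]
    return row


def run_cohort(spec_: CohortSpec) -> CohortResult:
    """Simulate and analyze a full cohort; deterministic given its seeds."""
    freqs = None if spec_.freqs_hz is None else np.asarray(spec_.freqs_hz)
    rows = []
    trial_tables: dict[str, pd.DataFrame] = {}
    for sid, (seed, group) in enumerate(
        zip(spec_.subject_seeds(), spec_.subject_groups())
    ):
        protocol = TacsProtocol(mode=group) if group == "alpha" else TacsProtocol(
            mode="sham", freq_hz=1.0
        )
        trials, epochs = run_session(
            spec_.task,
            spec_.observer,
            protocol,
            spec_.eeg,
            rng=seed,
            with_epochs=spec_.with_eeg,
        )
        name = f"{group}_{sid:02d}"
        trial_tables[name] = trials
        row = {"subject": name, "group": group, "seed": seed}
        row.update(analyze_session(trials, epochs, freqs_hz=freqs))
        rows.append(row)
    subjects = pd.DataFrame(rows).set_index("subject")
    stats, regressions = _cohort_stats(subjects, with_eeg=spec_.with_eeg)
    return CohortResult(
        subjects=subjects, trials=trial_tables, stats=stats, regressions=regressions
    )


def _cohort_stats(
    subjects: pd.DataFrame, with_eeg: bool = True
) -> tuple[dict[str, StatsResult], dict[str, RegressionResult]]:
    """The study's statistical battery over the per-subject summary table."""
    stats: dict[str, StatsResult] = {}
    regs: dict[str, RegressionResult] = {}
    alpha_grp = subjects[subjects["group"] == "alpha"]
    sham_grp = subjects[subjects["group"] == "sham"]

    def _safe(key, fn, *args, **kwargs):
        try:
            stats[key] = fn(*args, **kwargs)
        except (DegenerateDataError, ConfigError):
            pass

    # behavior: performance over time per group, and between groups
    for gname, grp in (("sham", sham_grp), ("alpha", alpha_grp)):
        if len(grp) >= 2:
            blocks = np.vstack(
                [grp[f"pct_hits_{b}"].to_numpy() for b in ("pre", "during", "post")]
            )
            _safe(f"friedman_pct_hits_{gname}", friedman_posthoc, blocks)
            iblocks = np.vstack(
                [grp[f"intensity_{b}_um"].to_numpy() for b in ("pre", "during", "post")]
            )
            _safe(f"friedman_intensity_{gname}", friedman_posthoc, iblocks)
    if len(alpha_grp) and len(sham_grp):
        _safe(
            "baseline_pct_hits_mwu",
            mann_whitney_u,
            sham_grp["pct_hits_pre"], alpha_grp["pct_hits_pre"],
            label_a="sham", label_b="alpha",
        )
        _safe(
            "baseline_pct_hits_ks",
            ks_two_sample,
            sham_grp["pct_hits_pre"], alpha_grp["pct_hits_pre"],
            label_a="sham", label_b="alpha",
        )
        for b in ("during", "post"):
            _safe(
                f"pct_change_{b}_mwu",
                mann_whitney_u,
                sham_grp[f"pct_change_{b}"], alpha_grp[f"pct_change_{b}"],
                label_a="sham", label_b="alpha",
            )
            _safe(
                f"intensity_change_{b}_mwu",
                mann_whitney_u,
                sham_grp[f"intensity_change_{b}"], alpha_grp[f"intensity_change_{b}"],
                label_a="sham", label_b="alpha",
            )

    if not with_eeg or "alpha_hit_pre" not in subjects.columns:
        return stats, regs

    # spectral: hit/miss alpha (pre block, both groups pooled)
    ok = subjects[["alpha_hit_pre", "alpha_miss_pre"]].dropna()
    if len(ok) >= 2:
        _safe(
            "hit_miss_alpha_wsr",
            wilcoxon_sr,
            ok["alpha_hit_pre"], ok["alpha_miss_pre"],
            label_a="hit", label_b="miss",
        )
    # ERP hit/miss contrasts (pre block)
    for feat in ("peak100", "slope"):
        ok = subjects[[f"erp_{feat}_hit", f"erp_{feat}_miss"]].dropna()
        if len(ok) >= 2:
            _safe(
                f"hit_miss_{feat}_wsr",
                wilcoxon_sr,
                ok[f"erp_{feat}_hit"], ok[f"erp_{feat}_miss"],
                label_a="hit", label_b="miss",
            )
    # alpha power pre vs post within groups; between groups per block
    for gname, grp in (("sham", sham_grp), ("alpha", alpha_grp)):
        if len(grp) >= 2:
            _safe(
                f"alpha_pre_post_wsr_{gname}",
                wilcoxon_sr,
                grp["alpha_pre"], grp["alpha_post"],
                label_a="pre", label_b="post",
            )
            if len(grp) >= 3:
                try:
                    regs[f"alpha_baseline_regression_{gname}"] = linregress_baseline(
                        grp["alpha_pre"], grp["alpha_delta"]
                    )
                except ConfigError:
                    pass
    if len(alpha_grp) and len(sham_grp):
        for b in ("pre", "post"):
            _safe(
                f"alpha_group_mwu_{b}",
                mann_whitney_u,
                sham_grp[f"alpha_{b}"], alpha_grp[f"alpha_{b}"],
                label_a="sham", label_b="alpha",
            )
        # the emergent early-component contrast
        _safe(
            "erp68_84_post_group_mwu",
            mann_whitney_u,
            sham_grp["erp_mean68_84_post"], alpha_grp["erp_mean68_84_post"],
            label_a="sham", label_b="alpha",
        )
    if len(alpha_grp) >= 2:
        _safe(
            "erp68_84_pre_post_alpha_wsr",
            wilcoxon_sr,
            alpha_grp["erp_mean68_84_pre"], alpha_grp["erp_mean68_84_post"],
            label_a="pre", label_b="post",
        )
    if len(sham_grp) >= 2:
        _safe(
            "erp68_84_pre_post_sham_wsr",
            wilcoxon_sr,
            sham_grp["erp_mean68_84_pre"], sham_grp["erp_mean68_84_post"],
            label_a="pre", label_b="post",
        )
    return stats, regs


def render_report(result: CohortResult) -> str:
    """Markdown report of the cohort analysis (group summaries + stats)."""
    lines = ["# Cohort analysis report", ""]
    lines.append(f"Subjects: {len(result.subjects)} "
                 f"({(result.subjects['group'] == 'alpha').sum()} alpha, "
                 f"{(result.subjects['group'] == 'sham').sum()} sham)")
    lines.append("")
    lines.append("## Per-subject summaries")
    lines.append("")
    lines.append(result.subjects.round(4).to_markdown())
    lines.append("")
    lines.append("## Statistics")
    lines.append("")
    lines.append("| contrast | test | statistic | Z | p (two-sided) | n | method |")
    lines.append("|---|---|---|---|---|---|---|")
    for key, res in result.stats.items():
        lines.append(
            f"| {key} | {res.test} | {res.statistic:.4g} | {res.z_value:.3f} | "
            f"{res.p_two_sided:.4g} | {res.n} | {res.method} |"
        )
        if res.posthoc:
            for pk, pr in res.posthoc.items():
                flag = (
                    " *"
                    if np.isfinite(pr.p_two_sided) and pr.p_two_sided < res.posthoc_alpha
                    else ""
                )
                lines.append(
                    f"| &nbsp;&nbsp;post hoc {pk}{flag} | {pr.test} | "
                    f"{pr.statistic:.4g} | {pr.z_value:.3f} | {pr.p_two_sided:.4g} | "
                    f"{pr.n} | {pr.method} |"
                )
    if result.regressions:
        lines.append("")
        lines.append("## Baseline-dependence regressions")
        lines.append("")
        lines.append("| group | slope | intercept | R^2 | F | p | zero crossing |")
        lines.append("|---|---|---|---|---|---|---|")
        for key, reg in result.regressions.items():
            lines.append(
                f"| {key} | {reg.slope:.3f} | {reg.intercept:.3f} | "
                f"{reg.r_squared:.3f} | {reg.f_statistic:.2f} | {reg.p_value:.4g} | "
                f"{reg.zero_crossing:.3f} |"
            )
        caveats = {reg.caveat for reg in result.regressions.values() if reg.caveat}
        for c in caveats:
            lines.append("")
            lines.append(f"*Note: {c}*")
    lines.append("")
    return "\n".join(lines)
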