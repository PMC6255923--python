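"""Synthetic tactile-detection sessions with simultaneous single-channel EEG.

This module generates complete experimental sessions of a threshold-level
tactile detection task run under intermittent transcranial alternating
current stimulation (tACS): the trial schedule (three blocks, mixed
threshold / supra-threshold / null stimuli), a simulated logistic observer
whose detection probability is tracked by an adaptive intensity staircase,
the tACS on/off schedule, and one stimulus-locked EEG epoch per trial from
a hypothetical C3 electrode.

The generator builds in the statistical structure the analysis pipeline is
designed to detect:

* per-trial pre-stimulus alpha (~10 Hz) amplitude is a latent variable that
  *suppresses* detection (negative coefficient on the log-odds scale), so
  miss trials carry more alpha power than hit trials;
* the evoked-response kernel has an early (~70 ms) and a late (~100 ms)
  component; the late amplitude depends on perception (hit vs miss), and
  the early component is multiplied by a gain factor after alpha tACS,
  emulating a stimulation-induced change in synaptic gain at the
  phenomenological level.

tACS itself is represented as schedule metadata only: no electrical
artifact is injected into the epochs, mirroring analyses that discard
during-stimulation EEG. An optional artifact flag exists for robustness
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import EpochSet

__all__ = [
    "TaskConfig",
    "ObserverModel",
    "StaircaseState",
    "TacsProtocol",
    "ErpComponent",
    "EEGGenParams",
    "TrialRecord",
    "make_schedule",
    "respond",
    "staircase_update",
    "synth_epoch",
    "run_session",
    "trials_to_frame",
]

Block = Literal["pre", "during", "post"]
StimType = Literal["threshold", "supra", "null"]
Outcome = Literal["hit", "miss"]

BLOCKS: tuple[Block, ...] = ("pre", "during", "post")
STIM_TYPES: tuple[StimType, ...] = ("threshold", "supra", "null")


@dataclass(frozen=True)
class TaskConfig:
    """Trial-schedule parameters of the detection task.

    Defaults reproduce the three-block 700-trial design: 200 trials before,
    300 during and 200 after electrical stimulation, with a 70/10/20 %
    threshold/supra-threshold/null stimulus mix, a 2 s red cue, a 1 s
    response window, 0.5-1.5 s stimulus-onset jitter and a 4.5 um
    staircase step.
    """

    n_pre: int = 200
    n_during: int = 300
    n_post: int = 200
    p_threshold: float = 0.70
    p_supra: float = 0.10
    p_null: float = 0.20
    cue_s: float = 2.0
    resp_s: float = 1.0
    jitter_range_s: tuple[float, float] = (0.5, 1.5)
    step_um: float = 4.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_pre, self.n_during, self.n_post) <= 0:
            raise ConfigError("all block trial counts must be > 0")
        probs = (self.p_threshold, self.p_supra, self.p_null)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"stimulus-mix probabilities must be >= 0 and sum to 1, got {probs}"
            )
        lo, hi = self.jitter_range_s
        if not lo < hi:
            raise ConfigError("jitter range must satisfy min < max")
        if self.step_um <= 0:
            raise ConfigError("staircase step must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_pre + self.n_during + self.n_post

    def block_sizes(self) -> dict[Block, int]:
        return {"pre": self.n_pre, "during": self.n_during, "post": self.n_post}


@dataclass(frozen=True)
class ObserverModel:
    """Phenomenological logistic observer for the detection task.

    Detection probability on threshold trials is a lapse-adjusted logistic
    function of stimulus intensity around the observer's 50 %-detection
    point ``mu_um``, with slope set by ``spread_um``:

        P(hit) = (1 - lapse) * sigmoid((I - mu)/spread + alpha_weight * z)

    where ``z`` is the standardized latent pre-stimulus alpha amplitude of
    the trial. A negative ``alpha_weight`` makes high-alpha trials less
    likely to be perceived. Supra-threshold stimuli are always detected up
    to lapses; null stimuli are "detected" at the false-alarm rate. ``mu``
    follows a Gaussian random walk (sd ``drift_sd_um`` per trial) to mimic
    slow sensitivity changes of the fingertip.

    The default ``alpha_weight`` and the alpha-amplitude distribution in
    :class:`EEGGenParams` are jointly calibrated (``scripts/calibrate.py``)
    so that a 12-session cohort reproduces the hit/miss normalized alpha
    power means of ~0.95 / ~1.06 the pipeline is meant to resolve.
    """

    mu_um: float = 250.0
    spread_um: float = 25.0
    lapse: float = 0.02
    fa: float = 0.05
    drift_sd_um: float = 1.0
    alpha_weight: float = -0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 1.0 and 0.0 <= self.fa <= 1.0):
            raise ConfigError("lapse and false-alarm rates must lie in [0, 1]")
        if self.spread_um <= 0:
            raise ConfigError("psychometric spread must be > 0")
        if self.drift_sd_um < 0:
            raise ConfigError("drift sd must be >= 0")


@dataclass(frozen=True)
class StaircaseState:
    """State of the 2-consecutive-correct-down / 3-consecutive-incorrect-up
    intensity staircase: current threshold-trial intensity plus the two
    streak counters. At most one streak counter may be nonzero."""

    intensity_um: float
    correct_streak: int = 0
    incorrect_streak: int = 0

    def __post_init__(self) -> None:
        if self.correct_streak < 0 or self.incorrect_streak < 0:
            raise ConfigError("streak counters must be >= 0")
        if self.correct_streak and self.incorrect_streak:
            raise ConfigError("at most one streak counter may be nonzero")
        if self.intensity_um < 0:
            raise ConfigError("intensity must be >= 0")


@dataclass(frozen=True)
class TacsProtocol:
    """Stimulation protocol metadata.

    ``alpha`` mode: sinusoidal stimulation at the participant's individual
    alpha frequency at 1 mA, 6 s on / 6 s off (on during every other trial
    of the middle block). ``sham`` mode: a single 1 Hz cycle ramped to 1 mA
    at the start of every other trial, then off — replicating the skin
    sensation at stimulation onset without sustained current.
    """

    mode: Literal["alpha", "sham"] = "alpha"
    freq_hz: float = 10.0
    amp_ma: float = 1.0
    on_s: float = 6.0
    off_s: float = 6.0

    def __post_init__(self) -> None:
        if self.mode not in ("alpha", "sham"):
            raise ConfigError(f"unknown tACS mode {self.mode!r}")
        if self.mode == "alpha" and not (7.0 <= self.freq_hz <= 14.0):
            raise ConfigError("alpha tACS frequency must lie within 7-14 Hz")
        if self.amp_ma <= 0:
            raise ConfigError("tACS amplitude must be > 0")


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian-windowed deflection of the evoked-response kernel.

    ``role`` marks the two components with condition-dependent amplitude:
    ``"m70"`` (early component, multiplied by the post-alpha-tACS gain) and
    ``"m100"`` (late component, amplitude replaced per hit/miss outcome).
    """

    latency_ms: float
    width_ms: float
    amp_uv: float
    role: Literal["m70", "m100", "other"] = "other"

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigError("ERP component width must be > 0")


@dataclass(frozen=True)
class EEGGenParams:
    """Parameters of the single-channel (C3) epoch generator.

    Each epoch spans -1000..+1000 ms around stimulus onset and is the sum
    of 1/f^beta background noise, a pre-stimulus alpha sinusoid whose
    per-trial amplitude is the latent variable coupled to detection
    (tapered to zero after stimulus onset, mimicking post-stimulus
    desynchronization), and the Gaussian-component ERP kernel on stimulated
    trials. Amplitudes are in microvolts.
    """

    fs_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 1000.0)
    alpha_freq_hz: float = 10.0
    alpha_amp_mean: float = 14.0
    alpha_amp_sd: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 5.0
    erp_components: tuple[ErpComponent, ...] = (
        ErpComponent(74.0, 7.0, 0.35, role="m70"),
        ErpComponent(99.0, 11.0, -1.0, role="m100"),
    )
    g70_post_alpha: float = 5.0
    amp100_hit: float = -1.38
    amp100_miss: float = 0.70
    alpha_taper_ms: float = 100.0
    inject_tacs_artifact: bool = False
    artifact_amp_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 2 * 50.0:
            raise ConfigError("sampling rate must exceed twice the 50 Hz band edge")
        if self.g70_post_alpha < 0:
            raise ConfigError("post-alpha gain must be >= 0")
        if self.alpha_amp_mean < 0 or self.alpha_amp_sd < 0:
            raise ConfigError("alpha amplitude distribution must be non-negative")
        w0, w1 = self.epoch_window_ms
        if not w0 < 0 < w1:
            raise ConfigError("epoch window must bracket stimulus onset at 0 ms")

    def time_axis_ms(self) -> np.ndarray:
        """Stimulus-locked sample times in ms (t = 0 is a sample)."""
        w0, w1 = self.epoch_window_ms
        i0 = int(round(w0 * self.fs_hz / 1000.0))
        i1 = int(round(w1 * self.fs_hz / 1000.0))
        return np.arange(i0, i1 + 1) * (1000.0 / self.fs_hz)


@dataclass
class TrialRecord:
    """One trial of the detection task."""

    index: int
    block: Block
    stim_type: StimType
    intensity_um: float = np.nan
    onset_jitter_s: float = np.nan
    tacs_on: bool = False
    group: Literal["sham", "alpha"] = "sham"
    outcome: Outcome | None = None
    alpha_amp: float = np.nan


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records as the canonical trial table."""
    return pd.DataFrame(
        {
            "index": [t.index for t in trials],
            "block": pd.Categorical([t.block for t in trials], categories=BLOCKS),
            "stim_type": pd.Categorical(
                [t.stim_type for t in trials], categories=STIM_TYPES
            ),
            "intensity_um": [t.intensity_um for t in trials],
            "onset_jitter_s": [t.onset_jitter_s for t in trials],
            "tacs_on": [t.tacs_on for t in trials],
            "group": [t.group for t in trials],
            "outcome": [t.outcome for t in trials],
            "alpha_amp": [t.alpha_amp for t in trials],
        }
    )


def _mix_counts(n: int, probs: tuple[float, float, float]) -> list[int]:
    """Exact stimulus-type allocation for a block: largest-remainder rounding
    of n * p so the realized mix matches the configured one exactly."""
    raw = [n * p for p in probs]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def make_schedule(
    config: TaskConfig,
    protocol: TacsProtocol,
    rng: np.random.Generator | int | None = None,
) -> list[TrialRecord]:
    """Build the trial schedule (outcomes and intensities unset).

    Stimulus types are allocated exactly per the configured mix within each
    block and shuffled; stimulation (``tacs_on``) is flagged on every other
    trial of the middle block, starting with its first trial, for both the
    alpha and sham protocols. Onset jitter is sampled uniformly.
    """
    rng = np.random.default_rng(rng)
    probs = (config.p_threshold, config.p_supra, config.p_null)
    trials: list[TrialRecord] = []
    idx = 0
    for block in BLOCKS:
        n = config.block_sizes()[block]
        types: list[StimType] = []
        for stim, c in zip(STIM_TYPES, _mix_counts(n, probs)):
            types.extend([stim] * c)
        types = [types[i] for i in rng.permutation(n)]
        for pos, stim in enumerate(types):
            trials.append(
                TrialRecord(
                    index=idx,
                    block=block,
                    stim_type=stim,
                    onset_jitter_s=rng.uniform(*config.jitter_range_s),
                    tacs_on=(block == "during" and pos % 2 == 0),
                    group=protocol.mode,
                )
            )
            idx += 1
    return trials


def _sigmoid(x: float) -> float:
    # guard against overflow for extreme log-odds
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def detection_probability(
    observer: ObserverModel,
    stim_type: StimType,
    intensity_um: float,
    alpha_z: float = 0.0,
    mu_um: float | None = None,
) -> float:
    """P(hit) for a trial under the logistic observer.

    ``alpha_z`` is the standardized latent alpha amplitude; ``mu_um``
    overrides the observer's 50 % point (used while mu drifts in a session).
    """
    if stim_type == "supra":
        return 1.0 - observer.lapse
    if stim_type == "null":
        return observer.fa
    mu = observer.mu_um if mu_um is None else mu_um
    x = (intensity_um - mu) / observer.spread_um + observer.alpha_weight * alpha_z
    return (1.0 - observer.lapse) * _sigmoid(x)


def respond(
    observer: ObserverModel,
    trial: TrialRecord,
    rng: np.random.Generator,
    alpha_z: float = 0.0,
    mu_um: float | None = None,
) -> Outcome:
    """Draw the observer's hit/miss response for one trial."""
    p = detection_probability(observer, trial.stim_type, trial.intensity_um, alpha_z, mu_um)
    return "hit" if rng.random() < p else "miss"


def staircase_update(
    state: StaircaseState, outcome: Outcome, step_um: float
) -> StaircaseState:
    """Advance the adaptive intensity staircase by one threshold trial.

    Two consecutive hits lower the intensity by ``step_um``; three
    consecutive misses raise it by the same amount. Any step, and any break
    in a streak, resets both counters. Intensity is floored at zero.
    """
    if outcome == "hit":
        streak = state.correct_streak + 1
        if streak >= 2:
            return StaircaseState(max(state.intensity_um - step_um, 0.0), 0, 0)
        return StaircaseState(state.intensity_um, streak, 0)
    streak = state.incorrect_streak + 1
    if streak >= 3:
        return StaircaseState(state.intensity_um + step_um, 0, 0)
    return StaircaseState(state.intensity_um, 0, streak)


from functools import lru_cache

from scipy import signal as _sps

_NOISE_BAND_HZ = (1.0, 50.0)


@lru_cache(maxsize=8)
def _noise_shaping(n: int, fs_hz: float, exponent: float) -> np.ndarray:
    """Amplitude shaping of the background-noise spectrum: 1/f^(beta/2)
    rolled off outside the 1-50 Hz acquisition band (4th-order Butterworth
    magnitudes). Continuous recordings are band-passed before epoching, so
    epoched background noise carries no out-of-band power."""
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    lo, hi = _NOISE_BAND_HZ
    w = 2.0 * np.pi * f / fs_hz
    hp = _sps.butter(4, lo, btype="highpass", fs=fs_hz, output="sos")
    lp = _sps.butter(4, hi, btype="lowpass", fs=fs_hz, output="sos")
    for sos in (hp, lp):
        _, h = _sps.sosfreqz(sos, worN=w)
        shaping = shaping * np.abs(h)
    shaping.setflags(write=False)
    return shaping


def _one_over_f_noise(
    n: int, fs_hz: float, exponent: float, scale_uv: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian 1/f^beta noise, standardized to sd = scale_uv."""
    white = rng.standard_normal(n)
    if scale_uv == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    x = np.fft.irfft(spec * _noise_shaping(n, fs_hz, exponent), n=n)
    sd = x.std()
    return x * (scale_uv / sd) if sd > 0 else x


def erp_kernel(
    t_ms: np.ndarray,
    eeg: EEGGenParams,
    outcome: Outcome | None,
    post_alpha: bool,
) -> np.ndarray:
    """Evoked-response kernel: sum of Gaussian components with
    condition-dependent amplitudes (see :class:`ErpComponent`)."""
    kernel = np.zeros_like(t_ms)
    for comp in eeg.erp_components:
        amp = comp.amp_uv
        if comp.role == "m100":
            amp = eeg.amp100_hit if outcome == "hit" else eeg.amp100_miss
        elif comp.role == "m70" and post_alpha:
            amp = amp * eeg.g70_post_alpha
        kernel += amp * np.exp(-((t_ms - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2))
    return kernel


def synth_epoch(
    trial: TrialRecord,
    eeg: EEGGenParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one stimulus-locked epoch (1-D voltage array, uV).

    Epoch = 1/f^beta noise + pre-stimulus alpha sinusoid at the trial's
    latent amplitude (raised-cosine tapered to zero after onset) + ERP
    kernel on stimulated (non-null) trials. The ~100 ms component takes
    its hit or miss amplitude from the trial outcome (miss if unset); the
    ~70 ms component is gain-scaled iff the trial belongs to the post
    block of an alpha-tACS session.
    """
    t_ms = eeg.time_axis_ms()
    n = t_ms.size
    x = _one_over_f_noise(n, eeg.fs_hz, eeg.noise_exponent, eeg.noise_scale, rng)

    amp = trial.alpha_amp if np.isfinite(trial.alpha_amp) else 0.0
    if amp != 0.0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = np.ones(n)
        post = t_ms > 0
        env[post] = 0.5 * (1.0 + np.cos(np.pi * np.minimum(t_ms[post] / eeg.alpha_taper_ms, 1.0)))
        # cosine ramp-in at the epoch's left edge: an abruptly starting
        # sinusoid would add a broadband onset transient that continuous
        # (pre-epoch) oscillatory activity does not have
        ramp_ms = eeg.alpha_taper_ms
        lead = t_ms - t_ms[0] < ramp_ms
        env[lead] *= 0.5 * (1.0 - np.cos(np.pi * (t_ms[lead] - t_ms[0]) / ramp_ms))
        x = x + amp * np.cos(2.0 * np.pi * eeg.alpha_freq_hz * t_ms / 1000.0 + phase) * env

    if trial.stim_type != "null":
        post_alpha = trial.group == "alpha" and trial.block == "post"
        x = x + erp_kernel(t_ms, eeg, trial.outcome, post_alpha)

    if eeg.inject_tacs_artifact and trial.tacs_on and trial.group == "alpha":
        x = x + eeg.artifact_amp_uv * np.sin(2.0 * np.pi * eeg.alpha_freq_hz * t_ms / 1000.0)
    return x


def run_session(
    config: TaskConfig,
    observer: ObserverModel,
    protocol: TacsProtocol,
    eeg: EEGGenParams,
    rng: np.random.Generator | int | None = None,
    with_epochs: bool = True,
) -> tuple[pd.DataFrame, EpochSet | None]:
    """Simulate one complete session: schedule, responses, staircase, epochs.

    The staircase acts on threshold trials only; supra-threshold trials are
    delivered at twice the current staircase intensity and null trials at
    zero. The observer's 50 % point follows its random walk across trials.
    All randomness flows from the single ``rng`` stream, so an identical
    seed yields a bit-identical session. ``with_epochs=False`` skips EEG
    synthesis (behavior-only simulations).

    Returns the trial table and, unless disabled, the matching
    :class:`~somatacs.preprocess.EpochSet` (one row per trial, in order).
    """
    rng = np.random.default_rng(rng)
    trials = make_schedule(config, protocol, rng)
    stair = StaircaseState(intensity_um=observer.mu_um)
    mu = observer.mu_um
    epochs = [] if with_epochs else None
    t_ms = eeg.time_axis_ms()

    for trial in trials:
        # latent pre-stimulus alpha amplitude, recorded for oracle tests
        raw_amp = rng.normal(eeg.alpha_amp_mean, eeg.alpha_amp_sd)
        trial.alpha_amp = max(raw_amp, 0.0)
        alpha_z = (
            (raw_amp - eeg.alpha_amp_mean) / eeg.alpha_amp_sd
            if eeg.alpha_amp_sd > 0
            else 0.0
        )
        if trial.stim_type == "threshold":
            trial.intensity_um = stair.intensity_um
        elif trial.stim_type == "supra":
            trial.intensity_um = 2.0 * stair.intensity_um
        else:
            trial.intensity_um = 0.0
        trial.outcome = respond(observer, trial, rng, alpha_z=alpha_z, mu_um=mu)
        if trial.stim_type == "threshold":
            stair = staircase_update(stair, trial.outcome, config.step_um)
        if observer.drift_sd_um > 0:
            mu += rng.normal(0.0, observer.drift_sd_um)
        if epochs is not None:
            epochs.append(synth_epoch(trial, eeg, rng))

    table = trials_to_frame(trials)
    epoch_set = None
    if epochs is not None:
        epoch_set = EpochSet(
            data=np.asarray(epochs), fs_hz=eeg.fs_hz, t_ms=t_ms, labels=table
        )
    return table, epoch_set
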