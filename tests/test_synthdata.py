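"""Unit and property tests of the session generator: trial schedule,
observer model, adaptive staircase, and epoch synthesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somatacs.errors import ConfigError
from somatacs.synthdata import (
    EEGGenParams,
    ErpComponent,
    ObserverModel,
    StaircaseState,
    TacsProtocol,
    TaskConfig,
    TrialRecord,
    detection_probability,
    make_schedule,
    respond,
    run_session,
    staircase_update,
    synth_epoch,
    trials_to_frame,
)


class TestSchedule:
    def test_default_design_emits_exact_trial_counts(self):
        """700 trials split 200/300/200 with an exact 70/10/20 stimulus mix."""
        trials = make_schedule(TaskConfig(), TacsProtocol(), rng=0)
        df = trials_to_frame(trials)
        assert len(df) == 700
        counts = df["block"].value_counts()
        assert counts["pre"] == 200 and counts["during"] == 300 and counts["post"] == 200
        mix = df["stim_type"].value_counts()
        assert mix["threshold"] == 490 and mix["supra"] == 70 and mix["null"] == 140

    def test_stimulation_on_every_other_middle_block_trial(self):
        trials = make_schedule(TaskConfig(), TacsProtocol(), rng=1)
        df = trials_to_frame(trials)
        during = df[df["block"] == "during"].reset_index(drop=True)
        assert during["tacs_on"].sum() == 150
        assert (during["tacs_on"].to_numpy() == (during.index % 2 == 0)).all()
        assert not df.loc[df["block"] != "during", "tacs_on"].any()

    def test_degenerate_mix_yields_threshold_only(self):
        cfg = TaskConfig(p_threshold=1.0, p_supra=0.0, p_null=0.0)
        trials = make_schedule(cfg, TacsProtocol(), rng=2)
        assert all(t.stim_type == "threshold" for t in trials)

    def test_jitter_within_range(self):
        trials = make_schedule(TaskConfig(), TacsProtocol(), rng=3)
        jit = np.array([t.onset_jitter_s for t in trials])
        assert (jit >= 0.5).all() and (jit <= 1.5).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_threshold=0.5, p_supra=0.1, p_null=0.1),  # does not sum to 1
            dict(n_pre=0),
            dict(jitter_range_s=(1.5, 0.5)),
            dict(step_um=0.0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            TaskConfig(**kwargs)


class TestObserver:
    def test_supra_without_lapse_always_hits(self, rng):
        obs = ObserverModel(lapse=0.0)
        trial = TrialRecord(0, "pre", "supra", intensity_um=500.0)
        assert all(respond(obs, trial, rng) == "hit" for _ in range(200))

    def test_null_without_false_alarms_always_misses(self, rng):
        obs = ObserverModel(fa=0.0)
        trial = TrialRecord(0, "pre", "null", intensity_um=0.0)
        assert all(respond(obs, trial, rng) == "miss" for _ in range(200))

    def test_threshold_at_midpoint_hits_half_the_time(self, rng):
        """At intensity = mu with no lapse and no alpha coupling the hit
        frequency converges to 1/2 (Monte Carlo, 10^4 draws, 4-sigma CI)."""
        obs = ObserverModel(lapse=0.0, alpha_weight=0.0)
        trial = TrialRecord(0, "pre", "threshold", intensity_um=obs.mu_um)
        n = 10_000
        hits = sum(respond(obs, trial, rng) == "hit" for _ in range(n))
        assert abs(hits / n - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_alpha_suppresses_detection_probability(self):
        obs = ObserverModel()
        p_lo = detection_probability(obs, "threshold", obs.mu_um, alpha_z=-2.0)
        p_hi = detection_probability(obs, "threshold", obs.mu_um, alpha_z=+2.0)
        assert p_lo > p_hi


class TestStaircase:
    def test_two_consecutive_hits_step_down_and_reset(self):
        s = StaircaseState(100.0)
        s = staircase_update(s, "hit", 4.5)
        assert (s.intensity_um, s.correct_streak) == (100.0, 1)
        s = staircase_update(s, "hit", 4.5)
        assert s.intensity_um == pytest.approx(95.5)
        assert s.correct_streak == 0 and s.incorrect_streak == 0

    def test_broken_streak_leaves_intensity_unchanged(self):
        s = StaircaseState(100.0)
        for outcome in ("hit", "miss", "hit"):
            s = staircase_update(s, outcome, 4.5)
        assert s.intensity_um == 100.0

    def test_three_consecutive_misses_step_up_and_reset(self):
        s = StaircaseState(100.0)
        for _ in range(3):
            s = staircase_update(s, "miss", 4.5)
        assert s.intensity_um == pytest.approx(104.5)
        assert s.correct_streak == 0 and s.incorrect_streak == 0

    def test_intensity_floored_at_zero(self):
        s = StaircaseState(2.0)
        s = staircase_update(s, "hit", 4.5)
        s = staircase_update(s, "hit", 4.5)
        assert s.intensity_um == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), max_size=60))
    def test_streak_invariants_hold_for_any_outcome_sequence(self, outcomes):
        """At most one streak counter is nonzero, counters stay within the
        rule's bounds, and intensity moves only in whole steps."""
        s = StaircaseState(100.0)
        for hit in outcomes:
            s = staircase_update(s, "hit" if hit else "miss", 4.5)
            assert not (s.correct_streak and s.incorrect_streak)
            assert s.correct_streak <= 1 and s.incorrect_streak <= 2
            assert s.intensity_um >= 0
            assert (100.0 - s.intensity_um) / 4.5 == pytest.approx(
                round((100.0 - s.intensity_um) / 4.5)
            )


def staircase_equilibrium_oracle(
    observer: ObserverModel, step_um: float, k_max: int = 80
) -> float:
    """Expected detection rate of the 2-down/3-up staircase on a static
    logistic observer, from the exact stationary distribution of the
    (intensity level, streak state) Markov chain.

    Streak states: 0 = no streak, 1 = one hit, 2 = one miss, 3 = two
    misses. Intensity levels are mu + k*step for k in [-k_max, k_max]
    (reflecting boundaries; mass there is negligible for the default
    observer)."""
    n_k = 2 * k_max + 1
    n_states = 4 * n_k
    p_hit = np.array(
        [
            detection_probability(
                observer, "threshold", observer.mu_um + (k - k_max) * step_um
            )
            for k in range(n_k)
        ]
    )
    T = np.zeros((n_states, n_states))

    def idx(k, s):
        return 4 * k + s

    for k in range(n_k):
        p, q = p_hit[k], 1.0 - p_hit[k]
        k_dn, k_up = max(k - 1, 0), min(k + 1, n_k - 1)
        # s=0: fresh
        T[idx(k, 0), idx(k, 1)] += p
        T[idx(k, 0), idx(k, 2)] += q
        # s=1: one hit -> second hit steps down
        T[idx(k, 1), idx(k_dn, 0)] += p
        T[idx(k, 1), idx(k, 2)] += q
        # s=2: one miss
        T[idx(k, 2), idx(k, 1)] += p
        T[idx(k, 2), idx(k, 3)] += q
        # s=3: two misses -> third steps up
        T[idx(k, 3), idx(k, 1)] += p
        T[idx(k, 3), idx(k_up, 0)] += q
    # stationary distribution by power iteration
    pi = np.full(n_states, 1.0 / n_states)
    for _ in range(20_000):
        nxt = pi @ T
        if np.abs(nxt - pi).sum() < 1e-13:
            pi = nxt
            break
        pi = nxt
    pi /= pi.sum()
    per_level = pi.reshape(n_k, 4).sum(axis=1)
    return float(per_level @ p_hit)


class TestSession:
    def test_identical_seed_gives_bit_identical_sessions(self, small_task, observer, eeg_params):
        a = run_session(small_task, observer, TacsProtocol(), eeg_params, rng=11)
        b = run_session(small_task, observer, TacsProtocol(), eeg_params, rng=11)
        assert a[0].equals(b[0])
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_static_observer_detection_rate_in_plausible_envelope(self, eeg_params):
        """With no drift and no alpha coupling the staircase keeps the
        session detection rate within the 20-70 % range such tasks report."""
        obs = ObserverModel(drift_sd_um=0.0, alpha_weight=0.0)
        trials, _ = run_session(
            TaskConfig(), obs, TacsProtocol(), eeg_params, rng=5, with_epochs=False
        )
        thr = trials[trials["stim_type"] == "threshold"]
        rate = 100.0 * (thr["outcome"] == "hit").mean()
        assert 20.0 <= rate <= 70.0

    def test_staircase_equilibrium_matches_markov_chain_oracle(self, eeg_params):
        """Long-run detection rate of the simulated staircase agrees with
        the exact stationary analysis of the streak Markov chain."""
        obs = ObserverModel(lapse=0.0, drift_sd_um=0.0, alpha_weight=0.0)
        expected = staircase_equilibrium_oracle(obs, step_um=4.5)
        cfg = TaskConfig(
            n_pre=20_000, n_during=20_000, n_post=20_000,
            p_threshold=1.0, p_supra=0.0, p_null=0.0,
        )
        trials, _ = run_session(
            cfg, obs, TacsProtocol(), eeg_params, rng=17, with_epochs=False
        )
        rate = (trials["outcome"] == "hit").mean()
        assert rate == pytest.approx(expected, abs=0.02)

    def test_staircase_stays_bounded_near_observer_threshold(self, eeg_params):
        obs = ObserverModel(drift_sd_um=0.0, alpha_weight=0.0)
        cfg = TaskConfig(
            n_pre=4000, n_during=4000, n_post=2000,
            p_threshold=1.0, p_supra=0.0, p_null=0.0,
        )
        trials, _ = run_session(cfg, obs, TacsProtocol(), eeg_params, rng=23, with_epochs=False)
        dev = (trials["intensity_um"] - obs.mu_um).abs().max()
        assert dev < 30 * cfg.step_um

    def test_alpha_amplitude_negatively_correlates_with_detection(self, eeg_params):
        """Point-biserial correlation between the latent alpha amplitude
        and the hit/miss outcome is negative under the default coupling."""
        trials, _ = run_session(
            TaskConfig(), ObserverModel(drift_sd_um=0.0), TacsProtocol(),
            eeg_params, rng=29, with_epochs=False,
        )
        thr = trials[trials["stim_type"] == "threshold"]
        hit = (thr["outcome"] == "hit").to_numpy(dtype=float)
        r = np.corrcoef(thr["alpha_amp"], hit)[0, 1]
        assert r < -0.05

    def test_supra_and_null_trials_do_not_move_the_staircase(self, eeg_params):
        """Threshold-trial intensity is unaffected by interleaved supra and
        null trials: with a deaf observer (all misses) the track rises by
        one step per three threshold misses, regardless of the mix."""
        obs = ObserverModel(lapse=1.0, fa=0.0, drift_sd_um=0.0, alpha_weight=0.0)
        mixed = TaskConfig(n_pre=60, n_during=2, n_post=1, p_threshold=0.5, p_supra=0.3, p_null=0.2)
        pure = TaskConfig(n_pre=30, n_during=2, n_post=1, p_threshold=1.0, p_supra=0.0, p_null=0.0)
        tm, _ = run_session(mixed, obs, TacsProtocol(), eeg_params, rng=31, with_epochs=False)
        tp, _ = run_session(pure, obs, TacsProtocol(), eeg_params, rng=31, with_epochs=False)
        thr_m = tm[(tm["block"] == "pre") & (tm["stim_type"] == "threshold")]
        thr_p = tp[tp["block"] == "pre"]
        n = min(len(thr_m), len(thr_p))
        np.testing.assert_allclose(
            thr_m["intensity_um"].to_numpy()[:n], thr_p["intensity_um"].to_numpy()[:n]
        )


class TestEpochSynthesis:
    def test_silent_null_trial_yields_zero_epoch(self, rng):
        eeg = EEGGenParams(noise_scale=0.0)
        trial = TrialRecord(0, "pre", "null", alpha_amp=0.0)
        np.testing.assert_array_equal(synth_epoch(trial, eeg, rng), 0.0)

    def test_single_component_minimum_lands_at_its_latency(self, rng):
        eeg = EEGGenParams(
            noise_scale=0.0,
            erp_components=(ErpComponent(100.0, 10.0, -1.0),),
        )
        trial = TrialRecord(0, "pre", "threshold", outcome="hit", alpha_amp=0.0)
        x = synth_epoch(trial, eeg, rng)
        t = eeg.time_axis_ms()
        assert t[np.argmin(x)] == pytest.approx(100.0)
        assert x.min() == pytest.approx(-1.0)

    def test_miss_trials_carry_more_prestim_alpha_power_than_hits(self, eeg_params):
        """Across many trials, mean latent alpha amplitude (hence prestim
        alpha power) is higher on miss than hit trials."""
        cfg = TaskConfig(n_pre=2000, n_during=2, n_post=1, p_threshold=1.0, p_supra=0.0, p_null=0.0)
        trials, _ = run_session(
            cfg, ObserverModel(drift_sd_um=0.0), TacsProtocol(), eeg_params,
            rng=37, with_epochs=False,
        )
        pre = trials[trials["block"] == "pre"]
        assert (
            pre.loc[pre["outcome"] == "miss", "alpha_amp"].mean()
            > pre.loc[pre["outcome"] == "hit", "alpha_amp"].mean()
        )

    def test_post_alpha_gain_scales_early_component_only(self, rng):
        eeg = EEGGenParams(noise_scale=0.0, g70_post_alpha=2.0)
        t = eeg.time_axis_ms()
        pre_trial = TrialRecord(0, "pre", "threshold", group="alpha", outcome="miss", alpha_amp=0.0)
        post_trial = TrialRecord(1, "post", "threshold", group="alpha", outcome="miss", alpha_amp=0.0)
        x_pre = synth_epoch(pre_trial, eeg, np.random.default_rng(0))
        x_post = synth_epoch(post_trial, eeg, np.random.default_rng(0))
        early = (t >= 68) & (t <= 84)
        late = (t >= 96) & (t <= 104)
        assert np.abs(x_post[early]).max() > np.abs(x_pre[early]).max()
        np.testing.assert_allclose(x_post[late], x_pre[late], atol=0.2)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ConfigError):
            TacsProtocol(mode="alpha", freq_hz=20.0)
        with pytest.raises(ConfigError):
            ObserverModel(lapse=1.5)
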