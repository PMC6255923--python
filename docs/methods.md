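# Methods

This note documents the models, parameter choices and numerical decisions
behind `somatacs`: what the synthetic-data generator does and does not
emulate, how the analysis stages are defined, and where the design was
genuinely open.

## 1. Task and observer model

A session has three blocks — 200 trials pre-stimulation, 300 during, 200
post — with stimulus types allocated *exactly* per the 70/10/20%
threshold/supra/null mix within each block (largest-remainder rounding,
then shuffled). Exact allocation, rather than i.i.d. draws, makes the
design counts reproducible and keeps the threshold-trial count at 490 in
every session. Stimulation is flagged on every other trial of the middle
block (150 of 300), for both the alpha and the sham protocol; the two
differ only in the protocol metadata (individual alpha frequency at 1 mA,
6 s on/off, versus a single 1 Hz ramp cycle). Where a session description
leaves the train count ambiguous (total stimulation time versus
trains × duration), the trial-level rule — stimulation on every other
middle-block trial — is taken as authoritative.

The observer detects a threshold stimulus of intensity `I` (μm of
piezoelectric deflection) with probability

    P(hit) = (1 − lapse) · sigmoid((I − mu)/spread + alpha_weight · z)

with `z` the standardized latent alpha amplitude of the trial.
Supra-threshold stimuli are detected with probability `1 − lapse`; null
stimuli at the false-alarm rate. Defaults: `mu = 250 μm` (typical reported
intensities are ~240–270 μm), `spread = 25 μm` (one 4.5 μm staircase step
then moves detection probability by ~4–5 percentage points), `lapse =
0.02`, `fa = 0.05`, and a per-trial Gaussian random walk of `mu` with
`drift_sd = 1 μm` emulating slow sensitivity changes of the fingertip.
Response-window timeouts are not modeled (their handling in real sessions
is unreported); every trial produces a hit or miss.

### Staircase

Intensity decreases by one step after two consecutive hits and increases
by one step after three consecutive misses; both counters reset after any
step, and a hit resets the miss streak (and vice versa). The staircase
acts on threshold trials only — supra and null trials have fixed detection
probabilities, so letting them feed the streaks would bias the track.
Threshold pre-titration is not implemented; the initial intensity is the
observer's current 50% point, which is the state a titration procedure is
designed to reach.

The asymmetric rule has a stationary detection probability below 50%: the
exact streak-state Markov chain (tested against simulation in the suite)
gives ~0.40 for the default logistic observer. Sessions therefore start
near 50% and settle toward ~40%, which both keeps per-session detection
rates inside the 20–70% envelope reported for this procedure and produces
the characteristic decline of performance across blocks.

## 2. Synthetic EEG

Each trial yields one single-channel (C3) epoch spanning −1000…+1000 ms,
generated at 500 Hz and brought to the 250 Hz analysis contract by the
preprocessing stage. An epoch is the sum of:

* **Background noise** — Gaussian `1/f^β` noise (β = 1), standardized to
  `noise_scale = 5 μV`, with its spectrum rolled off outside 1–50 Hz by
  4th-order Butterworth magnitudes. Band-limiting at generation reflects
  that continuous recordings are filtered *before* epoching; without it,
  the epoch-wise zero-phase filter would inject low-frequency startup
  transients that contaminate the pre-stimulus spectrum near 7–8 Hz.
* **Alpha oscillation** — a sinusoid at the session's alpha frequency
  (default 10 Hz) with per-trial amplitude drawn from N(14, 1) μV
  (truncated at 0), random phase, a raised-cosine taper to zero over the
  100 ms after stimulus onset (post-stimulus desynchronization), and a
  matching cosine ramp-in over the first 100 ms of the epoch. The ramp-in
  removes the broadband onset click that an abruptly windowed sinusoid
  would otherwise create — continuous oscillatory activity has no such
  onset inside an epoch.
* **Evoked-response kernel** (non-null trials) — Gaussian components at
  74 ms (width 7 ms, amplitude 0.35 μV) and 99 ms (width 11 ms). The late
  component's amplitude depends on perception: −1.38 μV on hits, +0.70 μV
  on misses (matching reported group means). The early component is
  multiplied by `g70_post_alpha = 5` in post-block epochs of alpha-tACS
  sessions — a purely phenomenological gain standing in for a
  stimulation-induced change in synaptic gain. With these values the
  post-alpha enhancement of the 68–84 ms window mean is ≈ 1 μV, a
  contrast a 6-vs-6 group comparison detects reliably; the generator
  reproduces the direction and detectability of the effect, not the
  absolute signed window means of any particular dataset.

No tACS artifact is injected (during-stimulation EEG is discarded by the
analyses this package mirrors); an `inject_tacs_artifact` flag exists for
robustness experiments, default off.

### Calibration

`alpha_amp_mean/sd`, `noise_scale` and `alpha_weight = −0.8` were
calibrated jointly (`scripts/calibrate.py`) so that an end-to-end analyzed
cohort reproduces the design point of the normalized alpha contrast:
hit-trial group mean ≈ 0.95 and miss-trial group mean ≈ 1.06 FOM. This is
a calibration target, not an independent prediction: the round-trip test
verifies that generation and analysis are mutually consistent, not that
real cortex behaves this way.

## 3. Preprocessing

The analysis contract is 250 Hz, 1–50 Hz, single channel. Filtering uses
cascaded 4th-order Butterworth high- (1 Hz) and low-pass (50 Hz) sections
applied forward–backward; zero-phase filtering is chosen so evoked-response
latencies are not biased (filter order and phase are typically unreported;
a causal filter on real data would shift latencies by a few ms).
Resampling is polyphase with anti-aliasing. Trial selection is label-based
and order-preserving; all EEG statistics run on threshold trials only, and
an empty selection raises rather than returning a silent empty set.

## 4. Spectral analysis

The Morlet wavelet uses m = 7 cycles, σₜ = m/2πf₀, amplitude normalization
A = 1/(σₜ√2π), and is truncated at ±5σₜ (amplitude < 4·10⁻⁶ of peak).
Power is the squared magnitude of the same-length convolution. The
frequency grid is 1–50 Hz in 1 Hz steps (the spacing is a package choice;
only the range is standard). Samples closer to an epoch edge than the
truncated half-support are flagged as cone-of-influence; they are
*included* in pre-stimulus averages by default (matching the apparent use
of the full window in practice) and can be excluded via
`exclude_edges=True`. Below ~6 Hz the wavelet support exceeds a 2 s epoch;
computing there requires the explicit `allow_short=True` (all samples
edge-flagged).

FOM normalization divides each time–frequency value by the per-frequency
median over all pre-stimulus (−1000…0 ms) samples concatenated across the
trials of the normalization group, making that median exactly 1. The
normalization group is the session's threshold trials of the block under
analysis (the median is session- and block-specific, since the alpha peak
is also re-identified per block); pooling across blocks is available via
the function arguments. Whether hit and miss trials should be pooled for
the median is not fully settled in the field's descriptions; this package
pools all threshold trials of the group.

The individual peak frequency is the argmax, within 7–14 Hz, of the trial-
and time-averaged **raw** pre-stimulus spectrum (ties to the lowest
frequency). Raw rather than FOM power is used because FOM pins every
per-frequency median to 1, leaving no spectral peak to find in flat-ish
normalized spectra; on data with a genuine alpha rhythm the raw spectrum
shows the peak directly. Band power then averages FOM values over
peak ± 2 Hz × (−1000…0 ms), with the band clipped to the grid (warning)
when the peak sits near an edge. Secondary bands for null contrasts:
theta 4–7, beta 15–29, gamma 30–50 Hz, each peak ± 2 Hz.

The tACS stimulation frequency is estimated from ≥ 10 s of resting
baseline with a Welch periodogram (2 s Hann segments, 50% overlap),
maximum in 7–14 Hz.

## 5. Evoked responses

Baseline correction subtracts each trial's mean over −150…0 ms; averaging
runs over 0…1000 ms with per-sample SEM. Features: late extremum =
*minimum* in 92–108 ms, early extremum = *maximum* in 60–88 ms (where two
window variants circulate, 60–88 ms is used because it is the one paired
with the statistics), inter-peak slope = ΔV/Δt in μV/ms (published units
of "ms/μV" are treated as a transposition; the printed means are
numerically consistent with μV/ms), and the 68–84 ms window mean. All
features use the raw sensor sign convention; `ERPWaveform.flipped()`
reproduces display-inverted plots. Latencies are reported on the 4 ms
sample grid without sub-sample interpolation; extrema ties break to the
earliest sample. Reported peak values are signed; when "larger" is meant
as "larger in magnitude" the caller should compare `abs(value)` — the
package does not decide that interpretation.

## 6. Statistics

All tests are two-sided. The Wilcoxon signed-rank test discards zero
differences (Wilcoxon's original treatment) and enumerates all 2ⁿ sign
assignments of the midranked |differences| for effective n ≤ 12 — so
cohorts of 6–12 use exact p-values — with a tie-corrected normal
approximation above that. The Mann–Whitney U test enumerates all
C(n₁+n₂, n₁) labelings for combined n ≤ 12 (valid under ties, since the
permutation distribution conditions on the observed values). The reported
Z is the normal-approximation z-score of the smaller rank sum / smaller U
(the convention of standard statistics packages, hence negative under any
effect). Friedman tests (k = 3 blocks) take the tie-corrected χ² and run
the three pairwise signed-rank post hocs at the Bonferroni level
0.05/3 ≈ 0.017; identical-across-conditions input yields χ² = 0 rather
than an indeterminate value. The baseline-dependence regression (OLS of
the pre-to-post power change on baseline power) reports slope, intercept,
R², the F-test of the slope and the baseline at which predicted change
crosses zero; because the baseline enters both axes, regression to the
mean alone produces a negative slope, and every regression result carries
that caveat rather than any methodological correction.

## 7. Cohorts and problem sizes

`CohortSpec` assigns consecutive seeds (`seed, seed+1, …`) to alpha-group
subjects first, then sham; everything downstream is a pure function of
those seeds. The per-subject analysis re-identifies the alpha peak and
re-normalizes per block, extracts evoked features for the pre/post blocks
and the pre-block hit/miss split, and summarizes behavior; the cohort
battery then mirrors the standard contrasts (hit/miss alpha WSR; per-group
Friedman over blocks; between-group MWU of baseline-normalized
performance; pre/post alpha WSR and the baseline regression; the 68–84 ms
contrasts).

The statistical-calibration tests run hundreds of cohorts and therefore
use reduced sessions — 200-trial pre (and, for the evoked contrast, post)
blocks with a minimal middle block, and a 5–16 Hz analysis grid (the
alpha-band computation is per-frequency, so restricting the grid changes
nothing in the band statistics). Sizes were chosen so the suite exercises
calibration at meaningful replication counts: 200 null cohorts for the
type-I-error check of the hit/miss alpha test (the alpha/detection
coupling switched off), 50 cohorts for the detection rate of the
post-stimulation early-component contrast (group MWU at p < 0.05; the
paired pre/post signed-rank variant is less powerful at n = 6 since its
smallest attainable two-sided p is 1/32).

## 8. What the generator does not emulate

Single channel only (no spatial structure, re-referencing or ICA); no
artifacts (eye blinks, line noise, electrode drift) and hence no cleaning
pipeline; a pure-sinusoid alpha rather than bursty narrowband activity, so
FOM peak identification on normalized spectra behaves differently than on
real data (hence the raw-spectrum peak rule); no between-subject
variability in alpha frequency, ERP morphology or psychometric parameters
beyond the seeds; stationarity within blocks (no fatigue or attention
drift beyond the observer's random walk); tACS reduced to schedule
metadata and one gain parameter — no electric-field, entrainment or
plasticity dynamics. Passing tests therefore validate the analysis chain
and its calibration on data with known ground truth; they do not certify
effect sizes or variability of real recordings.

## 9. Known limitations

* Exact enumeration is O(2ⁿ) / O(C(n₁+n₂, n₁)) and switches to asymptotics
  above combined n = 12; mid-sized samples (13–25) get the normal
  approximation where an exact or Monte-Carlo p would be preferable.
* The cone-of-influence policy (include, flag, optionally exclude) changes
  alpha-band pre-stimulus averages by a few percent; analyses sensitive at
  that level should set `exclude_edges=True` consistently.
* `resample_filter` assumes the target rate divides the input rate
  rationally; exotic rates resolve through large polyphase factors.
* The HDF5 epoch fixture stores the trial table as embedded CSV, which is
  convenient but not self-describing; FIF export carries no event
  metadata beyond the side-car table.
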