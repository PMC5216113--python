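# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Signal model and segmentation

The input is a single-channel chest-belt signal sampled at 100 Hz into
a 12-bit ADC (counts in [0, 4095]). Breathing power lies almost
entirely below 2.5 Hz, so the stream is first low-pass filtered with a
zero-phase 4th-order Butterworth at 5 Hz (applied forward–backward, so
the magnitude response is squared and the phase is exactly zero). The
cutoff and order are package choices: 5 Hz leaves a factor-of-two guard
band above the breathing band while still removing quantization noise
and most wide-band sensor noise.

Peak/valley detection is a windowed retracement (hysteresis) rule. The
stream is cut into 10-s windows with 30% overlap; inside each window
the threshold is `c · (max − min)` with coefficient `c = 0.3` by
default (0.2 and 0.4 are the documented alternatives). A peak is
confirmed at the running argmax once the signal has fallen at least one
threshold below the running maximum, a valley symmetrically. Window
overlap means most extrema are confirmed twice; duplicates closer than
0.25 s are merged and strict valley/peak alternation is enforced,
keeping the more extreme of two same-kind neighbors. Two boundary
rules: an event at the very first sample of the stream is discarded
(the running extremum starts there, so it is an artifact of the
recursion, not a confirmed extremum), and confirmed extremum timestamps
are re-localized on the *unfiltered* signal within ±0.08 s — zero-phase
filtering shifts the minimum of an asymmetric valley corner by a few
samples, and the raw signal still holds the exact corner. Confirmation
decisions, thresholds and depth measurements all stay on the filtered
stream.

Cycles are valley→peak→valley triples; the rising edge is the
inhalation, the falling edge the exhalation. Cycles shorter than 1 s
are discarded. Each cycle is linearly interpolated onto 128 uniform
time points and min-max scaled to [0, 100]; at the mean cycle length of
3.77 s the interpolation grid corresponds to an effective sampling rate
of 128/3.77 ≈ 34 Hz. Interpolation is linear because the cycles are
smooth at this scale and higher-order schemes would only add ringing
near apnea plateaus.

## Features

Eleven features per cycle:

* `fft_mag_0 … fft_mag_4` — magnitudes of the unnormalized DFT
  coefficients k = 0…4 of the 128-point normalized cycle. Magnitudes
  (not real/imaginary pairs) keep the count at five and make the
  features phase-invariant.
* `ntc` — the number of ±10 crossings of the first derivative of the
  normalized cycle, with the derivative taken as the per-sample forward
  difference (units: normalized amplitude per interpolation step).
  With sampled data an *exact* derivative value of ±10 is a
  measure-zero event, so the implementation counts level crossings: a
  sign change of (derivative − 10) or (derivative + 10) between
  consecutive samples, with a run of exact hits counted once. The ±10
  levels sit above the slope of any smooth breathing edge but below the
  transients of apnea blips, so swallow-bearing cycles cross them and
  clean cycles do not — the crossing count is also invariant to
  constant offsets by construction.
* durations and depths — inhale, exhale and total duration (s) and
  inhale/exhale depth (ADC counts, peak minus boundary valley) measured
  before normalization, since apnea elongation is precisely the
  information normalization removes.

A diagnostic information-gain report is available: merit = H(C) −
H(C|A) in bits, with H(C) the class entropy and H(C|A) the conditional
entropy after discretizing a feature into 10 equal-frequency bins
(plug-in estimates; the empirical merit is always in [0, H(C)]). The
binning choice trades resolution against per-bin counts at the few
hundred cycles a session provides.

## Posterior-probability SVM

Features are standardized with training-set statistics. The classifier
is an RBF-kernel SVM (the kernel family is a package choice; a linear
kernel is available) with inverse-frequency class weights, because meal
recordings contain several times more normal than swallow cycles.
Hyperparameters can be selected by stratified cross-validated grid
search on the training folds only; the defaults (C = 10, gamma =
"scale") are used when no grid is given. The decision value is
evaluated from the stored support expansion `D(x) = Σ_k y_k a_k
K(x_k, x) + b`; the feature-space norm of the weight vector is kept as
the scale constant turning `D(x)` into a geometric margin distance
(diagnostic only).

The posterior map is `P(y=1|x) = 1/(1 + exp(A·D(x) + B))` with `A < 0`.
(A, B) are fitted by minimizing the negative log likelihood with damped
Newton iterations (the problem is convex; convergence is declared when
a full undamped step moves the parameters by less than 1e-8, and
failure to converge raises with diagnostics). Two deliberate choices:

* The sigmoid is fitted to *out-of-fold* decision values from an
  internal 3-fold split of the training set. In-sample decision values
  cluster at ±1 for support vectors and would produce an over-confident
  sigmoid.
* No target-smoothing correction is applied — the plain likelihood is
  minimized. For perfectly separable calibration data the plain-NLL
  minimizer diverges (the slope grows without bound); the fit then
  stops once the NLL falls below 1e-6 and keeps the current, already
  numerically perfect, parameters.

Classification applies a threshold `Pth` (default 0.5): a cycle is a
swallow iff its posterior is ≥ `Pth`, the boundary counting as a
swallow.

## HMM refinement

The cycle sequence is modeled as a two-state hidden Markov chain
(state 0 normal, state 1 swallow) with first-order transitions. The
observable is the SVM posterior discretized into N = 10 equal windows;
window m covers ((m−1)/N, m/N], with 0 assigned to window 1 (so 0.71
falls in window 8). λ = (A, B, π) is estimated by counting from
ground-truth labeled training sequences: transitions pooled within (not
across) sequences, emissions per state and window, π from sequence
starts. All counts receive additive smoothing α = 0.5 before row
normalization — per-subject matrices from real data contain exact
zeros, which would otherwise make some observations impossible at
decode time; any remaining zeros are floored at 1e-12 before logs. A
state never observed with a successor gets a uniform transition row
with a warning. Emissions are estimated from the *out-of-fold*
posteriors produced during sigmoid calibration, for the same reason the
sigmoid is: in-sample posteriors are nearly 0/1 and would make B
unrealistically sharp.

Decoding is the Viterbi maximum a posteriori state path in log space
(exactly testable against exhaustive path enumeration); a
forward–backward per-cycle MAP decoder is available behind
`decoder="posterior"`. The locality structure — swallow→swallow
probability around 0.04 versus normal→normal around 0.76 — is what the
refinement exploits: an isolated detection must overcome a log-prior
penalty of about `log(a_nn²/(a_ns·a_sn)) ≈ 0.9`, and a detection
adjacent to a real swallow about `log(a_nn/a_ss) ≈ 2.9`, so
mid-confidence false positives (especially swallow-adjacent ones) are
removed while strongly observed swallows survive. The same mechanism
occasionally suppresses weakly observed true swallows, which is why
refinement trades a little recall for precision.

In the leave-one-subject-out harness all three matrices are estimated
from training subjects only. Estimating them from the test subject's
own ground truth would leak label information; a per-subject mode can
be emulated by fitting `SwallowHMM` on a single subject's sequences
directly.

## Synthetic-data generator

The generator emulates the statistical structure of meal recordings;
its defaults are the study conditions the pipeline is tested under.

* Cycle skeleton: lengths are truncated-normal with mean 3.77 s and CV
  0.12 (truncated to [0.4, 2]× the mean); the inhale occupies a
  uniform 35–50% of the cycle; depths are truncated-normal with mean
  600 and CV 0.10 on a baseline of 1800 counts; valley levels wander by
  a truncated-normal ±12 counts. Cycle boundaries are snapped to the
  sample grid, and the session starts with a partial exhale and ends
  with a partial inhale so that the first and last true valleys are
  interior, confirmable corners.
* Waveform: the inhale is a quarter-sine ramp (steep at the valley,
  flat at the peak), the exhale a quarter-cosine decay (flat at the
  peak, steep at the valley). Valleys are therefore sharp corners and
  peaks rounded — the asymmetry a retracement detector faces on real
  belt data; a pure sinusoid would make segmentation unrealistically
  easy.
* Swallows: a hidden Markov chain over cycles with the default
  transition matrix [[0.76, 0.24], [0.96, 0.04]] (stationary swallow
  fraction 0.2) decides which cycles carry a swallow; the initial state
  is drawn from the stationary distribution. A swallow inserts an apnea
  plateau — hold at the current amplitude for a truncated-normal
  duration from (0.25, 1.2) s — at exhale onset or mid-inhale (fair
  coin by default), with a superimposed damped oscillation ("blip") of
  110 counts at 4 Hz decaying with τ = 0.4 s. The blip is what makes
  the NTC feature informative: 110 counts is chosen so that, after the
  5-Hz filter and 128-point resampling, the normalized derivative
  actually crosses ±10, while the filtered blip swing stays below the
  0.3-coefficient retracement threshold so swallow cycles do not split.
  The ground-truth swallow timestamp is the apnea midpoint, emulating a
  push-button press.
* Feeding/chewing irregularities: normal cycles occasionally carry a
  short hold (0.08–0.4 s) with a full-amplitude blip — the saliva
  swallows and breath-holds that dominate false positives in real meal
  recordings. The rate is 0.06 for cycles deep in normal breathing and
  0.5 for cycles adjacent to a swallow, reflecting that neighboring
  cycles are modulated by the swallow itself. Without this confusion
  source the synthetic task is trivially separable and the two-tier
  comparison degenerates.
* Sensor model: additive Gaussian noise (σ = 8 counts by default),
  then rounding and clipping to [0, 2¹² − 1]. One RNG stream per
  session, seeded explicitly; identical config + seed reproduce the
  byte-identical stream.

Not simulated: drinking (removed before processing in the protocol the
package follows), talking/walking/sleep artifacts, and cardiac
components. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and the claimed qualitative behaviors
(threshold trade-off, posterior bimodality, locality-driven precision
gain), not field performance on any particular human cohort.

The fixture suite (`write_fixture_suite`) emits five scenarios:
no-swallow, exhale-only, inhale-only, mixed, and a high-noise variant
(σ = 55, depth CV 0.28) tuned so that both threshold-coefficient
failure modes are active — 0.2 splits cycles on blips, 0.4 merges
shallow cycles into neighbors — making the 0.2 < 0.3 > 0.4 recovery
ordering observable.

## Problem sizes

The shipped checks use: 240-s sessions (≈ 63 cycles) across 20 seeds
for segmentation recovery; ≥ 5000 cycles for transition recovery;
n = 5000 scores for sigmoid recovery (at this n the binomial
information bound puts the intercept's standard error near 0.03, so
recovery is checked at a design — slope −0.6, scores ~N(0, 2) — chosen
to maximize Fisher information); 200 random models with sequences up
to length 10 for the Viterbi/enumeration identity; and 20 cohorts of 6
subjects × 420 s for the leave-one-subject-out comparison, pooling
TP/FP/P counts across cohorts before forming the precision comparison.

## Known limitations

* The retracement detector assumes one dominant extremum pair per
  breath; severe motion artifacts would need dedicated rejection.
* Additive smoothing with unequal state counts gives the rarer state a
  higher emission floor in bins unseen for both states; with a
  well-calibrated sigmoid such observations are rare, but a posterior
  landing in a dead bin is decided mostly by the smoothing ratio.
* The Platt-style sigmoid assumes a monotone score-to-probability map;
  if decision values were anti-correlated with labels the fit refuses
  (positive fitted slope) rather than silently producing inverted
  posteriors.
* Per-event (as opposed to per-cycle) scoring, ROC analysis, and
  liquid-intake discrimination are out of scope.
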