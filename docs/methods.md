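# Methods

This package implements an EEG analysis of emotional picture viewing —
alpha-band event-related desynchronization (ERD) from a complex-Morlet
time–frequency decomposition, mean-amplitude scoring of six ERP components,
and a between-subjects ANOVA battery — together with a synthetic-EEG
generator that emulates the study design so that every stage can be
validated quantitatively end to end.

## Study design emulated by the generator

Twenty subjects each complete two blocks (sadness, disgust) of 90 trials.
A trial is 4 s of fixation followed by 4 s of picture presentation; the
inter-trial interval is therefore a fixed 8 s (uniform jitter is available
via `StudyDesign.iti_jitter_s` but off by default, as nothing in the design
requires it).  Each block mixes three conditions, 30 trials each, in
randomized order: negative (`Sad` or `Dis`), positive (`SadPos`/`DisPos`)
and neutral (`SadNeu`/`DisNeu`).  Recordings contain 32 scalp channels of
the 10–20 system plus vertical and horizontal EOG at 1024 Hz.  A per-trial
behavioral-correctness flag is simulated at 99.5 % accuracy; ERP averaging
uses correct trials only, ERD uses all trials (the selection is a flag on
both paths).

## Signal model

The generated voltage is a sum of four parts, amplitudes in microvolt:

1. **Background activity**: independent per-channel noise with power
   spectral density ∝ 1/f^β (β = 1 by default, `noise_scale` = 7 µV RMS),
   flattened below a 1 Hz knee so slow drift stays bounded, as a hardware
   high-pass would enforce.
2. **Alpha oscillator**: a single 10 Hz source (center of the 8–13 Hz
   band) with amplitude `alpha_base_amp` = 25 µV at the posterior maximum
   of a focal topography `w(ch) = 0.2 + 0.8·exp(−d²/2σ²)` (d = distance to
   the occipital pole, σ = 0.55), and a Wiener phase walk
   (1.5 rad·s^−1/2) so the rhythm is induced rather than phase-locked.
3. **ERP components**: Gaussian-windowed half-sine bumps injected inside
   each component's scoring window, with a scalp pattern equal to 1 on the
   target electrode group and Gaussian falloff elsewhere; per-subject
   multiplicative gains (lognormal, σ = 0.15, mean 1) are *traits* — drawn
   from a subject-level random stream so they are identical in a subject's
   two blocks — and trial-to-trial gains jitter lognormally (σ = 0.2,
   mean 1).
4. **Ocular artifacts**: blinks (hann² templates, 0.35 s, 200 µV on the
   vertical EOG, Poisson 15/min) mixed into scalp channels with gain
   0.4·exp(−d²/2·0.6²) from the frontal pole, plus horizontal saccade
   steps on the horizontal EOG with small lateral-frontal mixing.

### The ERD envelope and its analytic expectation

Per trial with suppression depth `s` (condition-dependent), the alpha
amplitude envelope is 1 before onset, ramps down (raised cosine) to a
trough at exactly 1 s, crosses a plateau on [1, 2] s whose *squared* value
is linear in time with mean exactly `(1−s)²` (tilt +0.15, rising, so the
trough at 1 s is unique), then recovers exponentially to `1 − 0.2·s` by 4 s
and relaxes to 1 during the next fixation — well before the next trial's
reference interval.  Because the test interval of the ERD index is [1, 2] s
and the reference interval [−0.75, −0.25] s sits at envelope 1, the
time-averaged power ratio is exactly `(1−s)²` and

    E[Di] = (1 − s)² − 1.

Default depths: 0.55 (negative), 0.50 (positive), 0.30 (neutral), the
qualitative ordering the analysis is expected to recover; between-subject
depth offsets are N(0, 0.08), again subject-level traits.  The suppression
depth is applied in full over posterior channels and at 0.75/0.6 of its
value over central/frontal channels, making measured ERD
posterior-dominant.

## Preprocessing

4th-order Butterworth band-pass 0.1–60 Hz and a Q = 30 IIR notch at 50 Hz,
both forward–backward (zero phase); common-average reference over the 32
scalp channels (EOG excluded and carried through); ocular cleanup either by
least-squares regression on the two demeaned EOG leads (default — it has an
analytic ground truth) or by FastICA with deterministic seeding, zeroing
sources whose |r| with an EOG lead exceeds 0.7 and falling back to
regression with a logged warning if the decomposition does not converge.
The stage order filter → notch → re-reference → ocular is enforced by the
pipeline driver; a scrambled order is rejected.  Bad-channel interpolation
and amplitude-based epoch rejection are intentionally out of scope.

## Time–frequency analysis and ERD

The continuous wavelet transform uses a complex Morlet kernel with 7
cycles per frequency (σ_t = 7/2πf), evaluated on a 1–40 Hz grid at 0.5 Hz
steps (an alpha-only 8–13 Hz grid is provided for ERD-focused runs).
Kernels are normalized so a sinusoid of amplitude A yields ridge power A².
Power is computed per trial and then averaged across trials — averaging
power, not coefficients, preserves induced activity.  Epochs for ERD are
cut at [−2, +4] s around picture onset; reflection padding of one wavelet
support handles the edges and a cone-of-influence mask is stored (the ERD
intervals lie well inside it).

The ERD index per channel is `Di = (P_test − P_ref)/P_ref` with `P` the
mean band power per sample over the interval — normalizing by interval
length is what makes the 1 s test and 0.5 s reference intervals
commensurable; raw interval sums would shift Di by the interval-length
ratio.  `erd_strength = −Di` is reported alongside so "larger ERD" is a
larger positive number.  A second path computes `P` from band-filtered
voltage (mean of squared voltages), and the tests check both paths against
an independent band-filter + Hilbert-envelope oracle.  Topographic maps
interpolate per-channel values onto the unit disc (cubic inside the
electrode hull, nearest-neighbor fill, masked beyond the head circle);
ROI summaries are unweighted means over member channels.

## ERP scoring

Epochs span [−0.2, +4] s with the mean over the 200 ms before onset
subtracted per trial and channel.  Component scores are the signed mean
amplitude over the component window — no peak picking — averaged over the
electrode group: N1 (100–200 ms) and EPN (270–470 ms) over PO3, PO4, O1,
Oz, O2; P2 (130–190 ms), N2 (200–250 ms), P3 (250–380 ms) and LPP
(700–4000 ms) over Fp1, Fp2, AF3, AF4.  Window endpoints round to the
nearest sample (< 1 ms error at 1024 Hz) and are inclusive.  Grand
averages weight subjects, not trials, equally.  "Larger N1/EPN/N2" in
contrast tables means a larger magnitude of the negative deflection;
contrasts operate on signed values with the expected sign declared per
comparison.  An emotional-minus-neutral difference wave is available as a
convenience output but scoring is on raw mean activity.

## Statistics

Subjects' condition means are treated as independent observations
(between-cells analysis; with 20 subjects × 6 cells the valence effect is
tested on (2, 114) degrees of freedom).  The two-way ANOVA uses Type-II
sums of squares via residual sums of nested least-squares fits, so
unbalanced tables are handled; for balanced tables this equals the
sequential decomposition.  Effect size is partial η² = F·df1/(F·df1+df2).
Post hoc families are Bonferroni-corrected (`p_adj = min(1, m·p)`, m = the
number of level pairs in the family); the a-priori pairs (sadness vs
disgust, each emotional condition vs its block's neutral) are reported
unadjusted in a separately labeled "planned" family.  Cohen's d uses the
pooled SD without small-sample correction.  A repeated-measures variant is
deliberately not the default, to match the between-cells structure above.

## Numerical and design choices

* The montage follows the 32-lead cap of the 10–20 system; electrode
  coordinates are standard 2-D projections onto the unit disc.
* HDF5 is the recording container (arrays + a JSON header); a documented
  CSV + events-TSV + JSON fallback exists for interoperability.  Parse
  errors name the offending field.
* Generator determinism: a recording is a pure function of (design,
  effects, subject, block, seed), via `numpy.random.SeedSequence` spawn
  keys; subject traits come from a subject-scoped stream.
* Epochs whose span would cross a recording edge are dropped with a
  logged warning; zero qualifying trials is an error naming the condition.
* Zero reference-interval power raises rather than returning ±inf.
* A study run is a pure function of its YAML-serializable `RunConfig`;
  derived per-subject results are cached on disk keyed by a hash of the
  config and ids, so partial reruns are cheap.

### Effect-size calibration

Default effect sizes were fixed by a single pilot simulation so that every
injected contrast direction is recoverable at the study's sample size with
high probability (the weakest margins — P2 disgust-vs-sadness and the
pooled EPN emotional-vs-neutral contrast — were widened once in that pass);
they have not been adjusted since and are treated as fixed study
conditions.

### Problem sizes used in validation

Wavelet-heavy validation runs analyze at 256 Hz and ERP recovery at
512 Hz; the seeded direction-pattern runs use 128 Hz and 10 subjects with
the ERP branch of the pipeline (ocular regression as the only cleaning
stage — the generator injects no line noise or drift, and blinks are what
threatens prefrontal scores).  Alpha at 10 Hz and all component windows
(≥ 50 ms) are fully resolved at these rates; trial counts and the ERD
intervals are never scaled.  `scripts/acceptance.py` states the `n` it
used next to every quantity it reports.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on:
1/f background, an induced posterior alpha rhythm with a controlled
suppression time course, phase-locked condition-dependent ERP deflections,
realistic blink mixing, and between-subject variability.  It deliberately
omits volume-conduction physics (no dipole forward model), heteroscedastic
or non-stationary noise, latency jitter of components, eye-movement-locked
potentials beyond the linear EOG mixing, and any behavioral reaction-time
structure.  Passing tests therefore demonstrate that the implementation
measures what it claims to measure under the stated signal model — not
that the scientific conclusions would replicate on real recordings.

## Known limitations

* The ERD spatial profile comes from an imposed depth gradient plus an
  alpha topography, not from source geometry.
* FastICA on rank-reduced scalp data can mix blink and saccade sources
  when they overlap temporally; the regression path is the default for
  exactly that reason.
* The between-cells ANOVA ignores the within-subject correlation of
  condition means; its type-I calibration holds under the simulated
  exchangeable null, which is the analysis model, not necessarily the
  physiological truth.
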