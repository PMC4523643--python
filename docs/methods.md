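# Methods

`quadfatigue` analyses electrically evoked isometric knee-extension
recordings and quantifies how reliably the derived fatigue measures can
be reproduced across testing days. This note documents the models,
parameter choices, and numerical conventions behind the package, and
what the synthetic-data tests do and do not demonstrate.

## The measurement it models

A subject's quadriceps is stimulated transcutaneously while the lower
leg is strapped to a strain gauge, so knee-extension torque (Nm) is
recorded at 1 kHz without any voluntary effort. The standard protocol
is

1. ten single-twitch stimuli (300 µs biphasic pulses), one every 2 s;
2. forty tetanic contractions: 35 Hz pulse trains of 3 s separated by
   1 s pauses (15 contractions per minute, 160 s in total);
3. ten further twitches immediately after the tetanic phase.

The twitch spacing and the quiet lead-in/tail around the stimulus
schedule are not fixed by the measurement itself; the package defaults
(2 s spacing, 1 s lead-in and tail) are conventional values that leave
each twitch fully relaxed and give the analysis a pre-stimulus baseline
segment. All timing is configurable through `StimulationProtocol`.

## Tetanic analysis

Per contraction, torque is the mean of the **last second** of the 3 s
on-phase (the plateau, after fusion is complete); at 1 kHz that is the
final 1000 samples, and `round(fs)` samples at other rates. Windows are
half-open `[onset, offset)` with sample *i* covering `[i/fs, (i+1)/fs)`.

The tetanic phase is subdivided into interval 1 (contractions 1–15),
interval 2 (16–30), interval 3 (1–30) and interval 4 (1–40). Within an
interval:

* **Fatigue Index (FI)** = mean torque of the final three contractions
  of the interval / mean of its first three (interval 2 therefore uses
  contractions 28–30 over 16–18). Scale-invariant; 1 means no decline.
* **Slope of regression (SOR)** = OLS slope of torque against elapsed
  time at contraction onset (Nm/s). Because published tables of this
  quantity are arithmetically consistent only with a per-contraction
  regressor, a `contraction_index` mode (Nm per contraction) is also
  provided; with the default 4 s cycle the two differ by exactly a
  factor of 4. The seconds mode is the default.

Segmentation normally uses the known stimulus schedule
(`segment_by_protocol`); a threshold segmenter (`segment_by_threshold`,
baseline = median of the first 0.5 s, threshold = 5% of the
baseline-subtracted maximum, crossings merged when separated by <20 ms,
runs ≥1 s classified tetanic) serves as a fallback when timing metadata
is absent and as an independent cross-check in tests. With the default
amplitude hierarchy, post-tetanic twitches sit near 4% of the tetanic
maximum, so the cross-check runs the threshold segmenter at 2%.

## Twitch analysis

Twitch segments are low-pass filtered at 15 Hz with a 4th-order
Butterworth applied forward–backward (zero phase, so timing features do
not shift). Filtering is applied to the twitch analysis only: tetanic
plateau means average 1000 samples and are numerically insensitive to a
15 Hz low-pass, so the raw trace is used there.

Per twitch, a local baseline (mean of the 50 ms preceding the onset —
robust to slow drift) is subtracted; **peak torque** is the window
maximum above that baseline and the **rise slope** is
`0.4·peak/(t70 − t30)`, where t30/t70 are the first times the ascending
limb crosses 30% and 70% of the peak, linearly interpolated between
samples. A twitch is flagged invalid (excluded from series averages,
never an exception) when its peak does not exceed 3× the SD of the
baseline segment or the crossings cannot be located. Series summaries
are arithmetic means over valid twitches, reported separately for the
initial and the final ten-twitch series.

## Reliability battery

For each outcome variable measured on two sessions (left/right sides
averaged per subject-session first, the convention when no side
difference exists; configurable):

* **Paired t-test** (two-sided, df = n−1) for systematic bias.
  Identical sessions give t = 0, p = 1; a constant nonzero shift has
  zero difference variance and is flagged degenerate rather than
  returning an arbitrary statistic.
* **ICC(3,1)** — two-way mixed-effects model, consistency definition,
  single measures: with n subjects and k = 2 sessions,
  `ICC = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error)`,
  MS_error being the residual after removing the session main effect.
  The 95% CI is the Shrout–Fleiss F-based interval with df (n−1) and
  (n−1)(k−1). Qualitative classes follow Shrout's bands (fair
  0.41–0.60, moderate 0.61–0.80, substantial ≥0.81, below-fair under
  0.41); the bands leave (0.60, 0.61) and (0.80, 0.81) uncovered, so
  they are applied to values rounded to two decimals, which closes the
  gaps.
* **SEM** = SD(differences)/√2 by default — it requires no ICC estimate
  and matches how published reliability tables of this kind are
  reproducible within rounding; the classical
  `SD_pooled·√(1 − ICC)` is available as `method="icc"`. The reported
  95% band follows the as-published convention `SEM·(1 ∓ 1.96)`, whose
  lower bound is negative for any positive SEM; it is reproduced for
  fidelity and labelled as such in the output
  (`sem_ci_convention`).
* **MDC95** = 1.96·√2·SEM ≈ 2.772·SEM, an exact identity asserted
  across every report row.
* **Bland–Altman**: bias = mean difference, limits of agreement =
  bias ± 1.96·SD(differences); heteroscedasticity is operationalised as
  the Pearson correlation between |difference| and pair mean with its
  two-sided p-value.

No multiple-testing correction is applied (none is conventional for a
descriptive reliability table), and normality screening is left to the
user as a diagnostic; nothing in the pipeline gates on it.

## Synthetic-recording generator

Twitches are modelled by the standard muscle impulse response
`A·(t/Tc)·exp(1 − t/Tc)` (peak `A` at the time-to-peak `Tc`); tetanic
force is the linear summation of these kernels at 35 Hz, which at
`Tc ≥ 0.07 s` produces a fused plateau (within-plateau ripple under 10%
of the mean). Each contraction's waveform is rescaled so that the mean
of its last on-phase second equals the programmed plateau exactly,
making noiseless pipeline recovery an exact (1e−9 Nm) test rather than
an approximate one.

Per-contraction plateau amplitudes follow a two-exponential fatigue
law, normalised so contraction 1 equals the programmed baseline:
`m(n) = f·exp(−(n−1)/τ_fast) + (1−f)·exp(−(n−1)/τ_slow)` with defaults
f = 0.45, τ_fast = 6, τ_slow = 50 contractions. These defaults were
calibrated once so that the **measured** cohort-mean interval-4 FI —
after the default drift and noise are superimposed — is ≈0.30, the
canonical extent of evoked quadriceps decline over 40 contractions, and
so the early interval FI (~0.55) exceeds the cumulative ones
(convexity). Post-tetanic twitch depression is a single multiplicative
factor (default 0.47) on twitch amplitude.

Measurement imperfections: additive white Gaussian noise (default SD
0.1 Nm), a linear baseline ramp (default 0.005 Nm/s) and an optional
random-walk drift — the kind of baseline wander a strap-mounted strain
gauge shows. Note that because plateau torque is deliberately computed
without baseline subtraction (as in practice), the drift slightly
inflates late-contraction torques and hence measured FI relative to the
programmed values; the calibration above accounts for this.

Cohorts follow the additive variance-component model
`y(subject, session) = µ + b_subject + s_session + ε` with everything
Gaussian — exactly the two-way layout ICC(3,1) is defined for. Defaults
(µ = 27 Nm, between-subject SD 14 Nm, between-session SD 2.5 Nm) give
peak-torque heterogeneity and ICC ≈ 0.97, typical of evoked-torque
test-retest data; fatigue parameters, twitch time-to-peak and motor
thresholds get their own between-subject spread with session jitter at
0.6 of the between-subject SD, which places FI-variable ICCs in the
0.6–0.9 range reliability studies of this measure report. Truncated
(redraw) normals keep amplitudes physical, at the cost of a slight
departure from exact normality in extreme tails. A `calibrated_retest`
mode reproduces day-2 intensity recalibration by matching the session-2
baseline to session 1's first-contraction torque within a small error
(default SD 0.5 Nm) rather than re-drawing a session effect.

One integer seed governs a cohort; per-subject streams are spawned
deterministically from it (`numpy` `SeedSequence`), so regeneration is
bit-identical and subjects are independent.

### What the generator does not emulate

No electrophysiology (membrane excitation, M-waves, recruitment), no
EMG, no potentiation dynamics beyond the single depression factor, no
torque-dependent noise, no electrode-placement artefacts. Passing tests
therefore demonstrate that the *analysis* recovers known signal
structure under realistic noise/drift — not that the generator spans
every failure mode of real recordings (e.g. movement artefacts or
unfused tetani at low stimulation frequency).

## Problem sizes used in the validation suite

Deterministic worked examples run on printed report inputs; oracle
equivalence of the ICC uses 1000 random cohorts of 3–8 subjects against
a brute-force two-way ANOVA written with explicit loops; parameter
recovery uses 200 replicate cohorts at n = 500 (mean estimate within
±0.01 of the true ICC 0.9) and at the study-scale n = 12 (±0.05);
end-to-end simulation uses 12-subject two-session cohorts of full 202 s
traces. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances while keeping the whole suite fast.

## Known limitations

* The SEM formula used by any given published table is rarely stated;
  `sd_diff/√2` and `SD·√(1−ICC)` differ when bias or low ICC is present.
  Both are offered; reports state which was used.
* FI and SOR are computed from raw (unsubtracted) plateau means, so
  heavy baseline drift biases them; the twitch path is drift-protected
  by local baselines, the tetanic path intentionally mirrors field
  practice.
* The threshold segmenter assumes contractions dominate the trace
  maximum; traces whose twitches fall below the threshold fraction of
  the tetanic maximum need the fraction lowered or schedule-based
  segmentation.
* ICC estimates at n = 12 carry wide confidence intervals (a property
  of the design, not the implementation); the package reports them
  rather than hiding them.
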