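# Methods

## The measurement problem

Continuous media hide experimental structure: a viewer's heart rate mixes
stimulus-driven modulation with intrinsic fluctuation and noise, and no
event markers exist to average over. Inter-subject correlation (ISC)
sidesteps this by correlating the *same* signal across people who receive
the same stimulus: whatever synchronises must be stimulus-locked. When
the two groups receive the same story through different senses, synchrony
*between* groups can only come from shared narrative processing, because
the presentations share no low-level features.

## Signal model of the synthetic audience

Each subject i in modality group g is generated at 1 Hz as

    x_i(t) = b_i + λ_s·s(t) + λ_m·m_g(t) + ε_i(t)

- `s(t)` — the narrative signal, common to all subjects;
- `m_g(t)` — one signal per modality group, capturing low-level
  stimulus-driven modulation specific to that presentation;
- `ε_i(t)` — AR(1) individual noise, coefficient φ ∈ [0, 1) (default 0.5),
  innovation SD σ (default 1);
- `b_i` — a per-subject baseline (bpm), N(70, 5²), present because Pearson
  windows must be translation-invariant and the tests verify they are.

`s` and each `m_g` are Gaussian noise low-pass filtered with a 4th-order
Butterworth at 0.1 Hz, then Gram–Schmidt orthogonalised and standardised.
The cutoff makes the stimulus components vary on the 5–10 s scale on
which attention is believed to modulate heart-rate synchrony, and gives
the permutation null realistic autocorrelation to contend with; it is a
modelling choice, not an empirical estimate of any recording's spectrum.
Artifacts are single-sample +40 bpm spikes at a configurable per-second
rate, isolated and interior by construction so neighbour-mean repair is
always defined.

Defaults mirror the emulated study design: two groups of 30, 3300 s
(~55 min) recordings. A "paper-like" operating point uses λ_s = 0.38
(with λ_m = 0.6, φ = 0.5, σ = 1), calibrated once so that the mean
between-group ISC is ≈ 0.05, the magnitude regime the method is meant to
resolve.

What the generator does **not** emulate: respiratory sinus arrhythmia,
circadian or vigilance drift, ECG waveform morphology, non-stationary
artifact bursts, or any coupling between movement and heart rate. Passing
tests therefore show the *analysis chain* is correct and calibrated under
a plausible signal model — not that any particular real recording meets
that model.

## Preprocessing

Heart rate: the instantaneous rate 60/RR is a step function over each
inter-peak interval; each 1 s bin [t, t+1) receives its time-average, and
bins outside the peak train carry the nearest defined rate. Bins are
half-open, 0-based from stimulus onset, so windows never overlap probe
boundaries ambiguously.

Artifact flagging replaces by-hand marking with a reproducible rule: a
sample is implausible outside 40–180 bpm or when it moves more than
20 bpm from its predecessor (both thresholds exposed in configuration).
Repair bridges each flagged run with the mean of the nearest clean
neighbours — the natural closure of the single-sample neighbour-mean rule
to runs, and order-independent, hence idempotent. Boundary runs copy the
single nearest clean value.

Movement collapses triaxial acceleration as the rectified sum
|x|+|y|+|z| per sample (then 1 s bin means). A signed sum and the
Euclidean norm are selectable, since "sum of the axes" is ambiguous;
the rectified sum is the default because a signed sum lets opposing
axes cancel real motion.

## Synchrony

Pearson r is computed in a 15-sample window slid one second at a time
over each pair's common span (T seconds → T − 14 windows). Windows in
which either series is constant have no defined correlation and are
excluded from all summaries rather than zero-filled, which would bias
medians toward zero. A pair's windows collapse to their arithmetic mean;
a participant's ISC is the median of their row of pair values (medians
resist the skew of correlation distributions); the time course is the
per-window median over pairs. The mean-of-windows pair summary is a
documented choice — the row and time-course medians are fixed, but the
pair-level collapse is configurable (median, Fisher-z mean) for
sensitivity analysis.

The sliding correlations are evaluated by rolling cumulative sums after
removing each series' global mean; the de-meaning step keeps the
cumulant algebra well-conditioned for signals riding large offsets
(≈70 bpm baselines), and the implementation agrees with a naive
per-window `corrcoef` loop to 1e-12.

## Inference

**Parametric.** A one-tailed one-sample t-test asks whether the
per-participant ISC distribution lies above zero; Cohen's d = mean/SD
with a 95 % CI from inverting the noncentral-t CDF in its noncentrality
parameter (deterministic, matching the reporting convention of
sensitivity analyses). Power arithmetic solves the noncentral-t power
equation for whichever of {d, n, power} is missing, by bisection.

The participant ISCs entering this test are not independent — every pair
is shared by two participants, and all of one participant's pairs share
that participant's series. Simulation at the package's own scales shows
the consequence plainly: with 60 fully independent AR(1) subjects the
one-tailed test at α = .05 rejects in ~9.5 % of null cohorts at 3300 s
(~20 % at 600 s), and if the two group-specific signals are present their
windowed cross-covariance acts as a cohort-level shared random component
that inflates rejection to ~30 %. The parametric test is reported for
interpretability; calibrated decisions come from the permutation test.

**Permutation.** For each participant the series is circularly rotated
by an offset drawn uniformly from [15, T − 15] (a one-window guard band
at each end so the rotated series never trivially realigns) and the
participant ISC is recomputed against unshifted partners; 10,000
iterations by default (tests use 199–999). Rotation preserves the
autocovariance up to the wraparound seam, so the null shares the data's
autoregressive structure. p = (1 + #{null ≥ observed}) / (1 + n_iter),
never exactly zero. The observed statistic is computed through the
identical code path as offset 0. Decisions across participants use
Benjamini–Hochberg step-up FDR at q = 0.05. The permutation rotates the
target's series jointly against all partners; rotating the partners'
frame instead is the same comparison in a shifted frame and agrees at
decision level.

Null ISCs are evaluated in float32 (~1e-7 relative error) because they
are consumed only through rank comparisons; observed-vs-null decisions at
that precision are indistinguishable from float64, and the null sweep is
the pipeline's dominant cost.

## Low-level salience

Visual conspicuity follows the classic center-surround architecture:
Gaussian pyramids (center levels 2–4, surround offsets 3–4, rectified
differences summed at the level-2 scale) over luminance (intensity),
red–green and blue–yellow opponency (colour: RG = R−G,
BY = B−(R+G)/2), four oriented Gaussian-derivative responses
(orientation), frame-to-frame luminance change (flicker) and
Reichardt-style shifted products of consecutive luminance pyramids
(motion — zero for a static scene by construction, unlike a plain
shifted difference). Each map is normalised by peak promotion: rescaled
to [0, 1] and multiplied by (M − m̄)², M the global and m̄ the mean local
maximum, which favours maps with one dominant peak. This is a
channel-level simplification of the full multi-scale feature bank of the
reference architecture: only the five per-channel RMS traces feed
downstream modeling, so channel fidelity is what matters, and no
numerical agreement with any specific salience implementation is claimed.
The first frame's temporal channels are defined as zero. Audio salience
is per-second RMS of the waveform (stereo averaged to mono), exactly
scale-covariant.

Per-second summaries: RMS over pixels per frame, mean over the frames of
each second; one row per whole stimulus second.

## Narrative vs low-level modeling

Condition-level heart rate is the per-second mean of per-participant
z-scored series — averaging standardized subjects lifts the
stimulus-locked component above individual noise, and the tests verify
the average correlates with the generating signal better than any
individual does. Three nested OLS models predict one condition's series:
seconds (trend); + the other condition's heart rate (the narrative
proxy — the only component the conditions share); + the six salience
features, at lag 0 by default (a lag flag exists for exploring
physiological delay). R² is monotone along the chain by construction;
BIC = n·ln(RSS/n) + k·ln(n) with k counting intercept, slopes and the
error variance, so the trend model has k = 3. The variance uniquely
added by each block (ΔR²) is the headline comparison. Volume-from-vision
regression (RMS volume on the five conspicuity channels) quantifies
audiovisual co-occurrence — the confound the nested comparison controls.

## Immersion ratings

Raters answer a probe every 30 s on a 1–7 scale. Cleaning: responses
slower than 5 s become missing; raters with more than 20 % missing after
that are dropped. Reliability is the mean pairwise Pearson correlation
over shared probes (a pooled each-vs-rest variant is available, since
"correlation over time" admits both readings). The ISC link averages the
time course over each probe's trailing window [p − 30, p) — the rating
reflects the just-experienced content; centered bins are available.
Peaks are maximal runs above mean + 3 SD of the whole time course,
invariant to affine rescaling.

One generative subtlety the package makes explicit: windowed ISC rises
where the shared signal is locally *variable*, not where its level is
high — within a window, the pair correlation grows with the shared
signal's within-window variance. A rating cohort that tracks the
narrative signal's level is therefore uncorrelated with the ISC time
course even at high shared loading (0/10 replicates recovered a positive
link in simulation). The generator's ground-truth immersion trace is
accordingly the narrative signal's 15 s rolling SD
(`synth.narrative_activity`), its moment-to-moment eventfulness; with
that coupling the ISC–rating correlation is recovered in ≥ 9/10
replicates. Ratings are discretised to the integer scale with exact
per-rater missing and slow-response counts (positions random), so
exclusion arithmetic is deterministic given the rates.

## Numerical and scale choices

- Window variances are declared zero below a 1e-10 relative tolerance;
  such windows are excluded, not repaired.
- The d CI and power solvers guard scipy's noncentral-t CDF against
  underflow-to-NaN at extreme noncentrality.
- Test-suite simulations run at reduced scale (cohorts of 600–3300 s,
  199–1000 shuffle iterations, 10–50 replicates) — sizes chosen so the
  whole suite exercises every stochastic claim at meaningful resolution;
  the defaults users get are the full-scale constants (10,000 iterations,
  q = 0.05, 15 s window).
- All generators are deterministic given their seed; the pipeline writes
  every constant it used to a JSON manifest, and seeded reruns are
  byte-identical.

## Known limitations

- The salience model is a five-channel approximation; absolute feature
  magnitudes are not comparable across implementations.
- The parametric group test's miscalibration under ISC dependence is
  characterised, not corrected; use the permutation decisions when size
  matters.
- Rating analyses assume a common probe grid across raters.
- No lagged or directional (leader–follower) synchrony, and no
  frequency-domain coherence — the windowed Pearson family only.
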