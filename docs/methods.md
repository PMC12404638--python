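# Methods

This note records the models, the defaults and why they are what they
are, the choices made where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## Generative model of a session

A session is a stimulus schedule (a large once-presented set used for
fitting, and a small repeat set used for reliability and held-out
scoring), a layered feature hierarchy, and Poisson spike counts.

**Schedule.** `make_schedule(n_single, n_repeat_stimuli, n_repeats,
duration_mean, duration_jitter, seed)` draws durations uniformly in
`mean ± jitter` and presents all (stimulus, repeat) pairs in one seeded
random permutation. Bins per stimulus are `ceil(duration / bin_width)`
(the last partial bin is kept). The default layouts mirror a typical
primate-audio experiment: 489 + 10×11 sentences of ~1.6 s and
292 + 11×15 vocalizations of ~1.0 s, at 50-ms bins (20-ms for the
time-scale analysis).

**Feature hierarchy.** Layer 1 is the base feature matrix (smooth
band-limited noise standing in for a cochleagram, or a real cochleagram
/ user-supplied activations). Each deeper layer applies a stored
temporal convolution kernel, a tanh, and integer-stride downsampling,
so sampling rates are non-increasing with depth. Two kernel regimes:

- *structured* ("trained-like"): temporal smoothers, differencers, and
  spectral contrasts with gain large enough to engage the tanh — an
  organized, information-preserving nonlinearity;
- *random* ("untrained"): small i.i.d. weights (`0.5/sqrt(k·d)`), which
  keep the tanh near its linear range.

`perturb_hierarchy` rebuilds features after either re-initializing
kernels (small random) or permuting the entries of each existing kernel.
Permuting large structured weights destroys their organization while
keeping their magnitudes, pushing activations into tanh saturation; this
is why a permuted trained-like stack loses more linear information about
the base signal than a re-initialized one (tested).

**Units.** Each simulated multi-unit reads one target layer through a
ground-truth causal 250-ms linear filter (3 active feature dimensions,
Gaussian-smoothed random lag profiles with width `trf_smooth` lags —
set 0 for drive up to the bin Nyquist). Rate = `baseline + gain ·
relu(drive)`; rectification keeps rates non-negative without clipping.
Counts are Poisson per bin and per presentation; repeats share the rate,
so reliability is controlled by the gain/baseline ratio. Poisson was
chosen (no noise model is canonical here) because it yields a
closed-form expected trial-pair correlation, `var(rate)/(var(rate) +
mean(rate))` per bin, used as a test oracle. Defaults — gains 20–60
spikes/s on unit-norm filters, baselines 2–10 spikes/s — were picked
once to put typical ceilings near 0.3–0.6, the regime where noise
correction matters; no per-unit firing statistics exist to calibrate
against, and the defaults live in `RunConfig`, not in the estimators.

**Regions.** Primary units draw their target layer from the shallow
half of the stack, non-primary from the deep half, with 25% crossover —
a soft hierarchy that gives the regional analysis a recoverable but not
degenerate effect.

## Reliability and noise correction

For each unit, R resamples each draw one distinct trial pair per repeat
stimulus and concatenate the members into aligned long sequences (one
seeded random stimulus order per resample, shared by both sequences);
the Pearson correlations form the *true* distribution, and correlating
against the half-length circular shift of the second sequence forms the
*null*. Constant sequences yield undefined correlations; these
resamples are excluded and counted, never set to 0. R defaults to
100,000 in `CorrelationDistribution`-producing calls at full scale, but
the pipeline and tests default to a few thousand — the ceiling (a mean)
stabilizes long before that.

Classification: *tuned* = one-sided rank-sum (true > null) p < 0.05;
*well-tuned* additionally requires mean(true) − mean(null) ≥
δ·std(null), boundary inclusive, δ = 0.5 by default (1.0 as a
robustness setting). The gap uses means; the accepted-unit count is
non-increasing in δ (tested).

A caution the package makes explicit: the rank-sum over R resamples
treats them as independent, but they reuse the same trials. Conditioned
on a unit's data, the true-vs-null mean gap is a fixed offset of order
1/√(total bins), while the test resolves differences of order 1/√R —
so the nominal level is not controlled and the test becomes more
anticonservative as R grows (empirically ~0.35–0.4 of pure-noise units
are flagged at p < 0.05 with R = 4000). This is precisely why the
stricter δ-gap criterion exists; downstream analyses should rely on
*well-tuned*, not *tuned*. The reliability table reports R next to
every p-value.

Noise correction divides a model–neuron correlation by the square root
of the ceiling (two independent noise sources in a trial pair, one in a
model–response pair). Ceilings at or below a floor (default 1e-3) mark
the unit uncorrectable; it is excluded and logged rather than clipped.

## TRF estimation

- Lag window: causal, 250 ms, `n_lags = round(window·rate)` with
  round-half-up (5 lags at 20 Hz, 13 at 50 Hz). Causality is a modeling
  choice (physiological plausibility); the window never crosses stimulus
  onsets — each stimulus is lagged separately with zero padding, then
  concatenated.
- Penalty grid: 21 log-spaced points over 1e-5…1e15. Folds are
  contiguous temporal blocks (3 by default), identical across penalties,
  to limit autocorrelation leakage; the ridge path per fold is computed
  from one eigendecomposition of the training Gram matrix, so the whole
  grid costs barely more than one solve.
- Design columns are z-scored on the training folds; the intercept is
  fit by centering and never penalized. Final weights are refit on all
  training data at the selected penalty and reported on the original
  feature scale.
- Degenerate (all-zero) designs return a flagged zero-weight model
  predicting the mean count.

## Frontends

The STRF baseline uses an ERB cochleagram: 211 center frequencies
equally spaced in ERB-rate (Glasberg–Moore) between 50 and 8000 Hz,
4th-order gammatone magnitude gains applied to Hann-windowed short-time
spectra, root-summed power per filter, log-compressed with a floor of
1e-5 of the global peak (omitting the log demonstrably cripples
spectrogram frontends). Frames hop at the target frame rate (20 Hz
default) with window = hop/(1 − overlap), overlap 87.5%.

Resampling is band-limited rational-factor (`resample_poly`, linear-pad
edges), output length `round(n·target/source)`. The low-pass used by
the time-scale sweep is a zero-phase (forward–backward) 4th-order
Butterworth; a cutoff at Nyquist is the identity by convention, above
Nyquist is an error.

## Evaluation and analyses

Held-out scoring concatenates predictions and responses for the repeat
set in a fixed stimulus order, one response sequence per repeat index;
the per-repeat Pearson correlations are averaged and noise-corrected.
Model comparisons are two-sided Wilcoxon signed-rank tests with the
median-difference direction reported (the display threshold, 0.01, and
the selection threshold, 0.05, are both configurable); BH runs within
each model's 2L-test family. Model-to-STRF correlation ratios cancel
the common ceiling, so they equal the raw-correlation ratios (asserted
numerically).

Best layer is the argmax of corrected correlation with ties to the
shallowest layer; depth fraction is 1-based ℓ̂/L. The hierarchy test is
a one-sided rank-sum (non-primary deeper). The time-scale sweep refits
the TRF at every cutoff (filtering predictions instead would let the
fit exploit pre-filter structure); the "indistinguishable set" contains
every cutoff whose paired signed-rank test against the best cutoff has
p ≥ 0.01, plus the best cutoff itself, and bit-identical score columns
are treated as indistinguishable without a test.

## Verification studies and problem sizes

`spikereadout.studies` fixes the conditions used by the test suite and
`scripts/acceptance.py`. Sizes were chosen once for stable Monte-Carlo
estimates on a single core: 100 random instances for the ridge oracle;
~15k-bin sequences for ceiling consistency (tolerance 0.02 against the
Gaussian closed form; corrected score of the exact Poisson rate within
0.05 of 1); 300 gain-0 units at R = 4000 for null calibration; a
200-unit four-layer session for generating-layer recovery; ten 16-unit
single-generating-layer sessions for the median-peak check; a 400-unit
session (≈200 per region) for the hierarchy test plus 100 label
shuffles; 10 units per condition for the time-scale sweep, with sharp
readouts on near-white features (broadband condition) versus 2-Hz
band-limited base features.

## Known limitations

- The generator's hierarchy is a stack of generic saturating
  convolutions; it emulates declining sampling rates and increasing
  nonlinearity, not any real speech network's representations or
  receptive-field sizes. Passing recovery tests show the *estimators*
  work, not that real cortical data would behave this way.
- Trial-to-trial variability is purely Poisson and stimulus-locked;
  real recordings have slow gain drift, attention effects, and
  correlated noise across channels, all of which bias ceilings in ways
  the synthetic tests cannot expose.
- The tuned-test calibration issue described above is inherent to the
  resampling design, not fixable by a larger R.
- CV folds may split within a stimulus; with strong autocorrelation and
  very few stimuli this can bias penalty selection slightly downward.
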