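# Methods

This note documents the models, numerical conventions and design choices
behind `timbreaffect`, and what the synthetic data can and cannot show.

## Stimulus synthesis

Tones are additive: partial *k* of fundamental *f₀* has amplitude
*k*^−σ, where σ (`slope_param`) controls spectral rolloff; partials at or
above Nyquist are dropped. The fundamental of pitch class D# in octave
*n* is 440·2^(−6/12)·2^(n−4) Hz (equal temperament, A4 = 440 Hz; D# six
semitones below A), so D#4 ≈ 311.13 Hz. Each clip is 500 ms at 44.1 kHz,
peak-normalised, faded with a raised-cosine ramp over the final 50 ms
(last sample exactly zero), and written as 16-bit PCM WAV via
`scipy.io.wavfile`; internal processing is floating point.

The envelope is a linear attack of `attack_time` seconds followed by
exponential decay at rate `decay_param` s⁻¹; the percussion archetype
multiplies the decay rate by 12 so its tail is impulsive. Vibrato is
sinusoidal FM (depth in cents, integrated to phase so partials stay
harmonic), flutter is sinusoidal AM, and a white-noise floor is mixed at
`noise_level` relative RMS. Random phases and noise derive from the
per-stimulus seed, so output is byte-deterministic.

The default roster defines 12 instrument series across the four families
(brass with weak/normal/strong attacks and flutter, woodwinds with
flutter, strings with vibrato and pizzicato, percussion with
felt/wood/metal mallets) over family-appropriate octave subranges of
octaves 1–7, totalling **137 stimuli**. Per-stimulus jitter (±15–25% on
slope, attack, decay, noise) prevents degenerate duplicate descriptor
columns. The archetypes are deliberately *not* models of real
instruments; they exist to span wide ranges of every descriptor.

## Simulated ratings

Ratings follow a planted-effect model. Per scale, a latent mean in [0, 1]
is an intercept plus a weighted sum of range-normalised stimulus features
(synthesis parameters or derived descriptors), optionally logistically
squashed, then clamped. A rating by participant *j* for stimulus *i* is
`clamp(round(1 + 8·(latent_i + b_j + ε_ij)), 1, 9)` with participant
intercepts `b_j ~ N(0, participant_sd)` and per-rating noise
`ε ~ N(0, noise_sd)`. An optional stimulus-level random effect
(`stimulus_sd`) adds noise to the latent mean itself — shared by all
participants, it is the variance component that no descriptor model can
explain, and it is what bounds achievable Q² away from 1. Defaults (40
participants, noise_sd 0.08, participant_sd 0.08) give Cronbach's α in
the mid-0.9s, matching the reliability typically seen in such studies.

The default planted mapping makes energy arousal rise with register and
brightness, tension rise with register, modulation and noisiness, and
valence peak in mid registers with sharp attacks — the qualitative
structure such studies report. It is a simulation device, not a
perceptual model: passing tests show the *pipeline* recovers planted
structure, not that these mappings hold for human listeners.

## Descriptor extraction

Three computation stages:

1. **Input representations.** The temporal energy envelope is the
   amplitude of the analytic signal (Hilbert transform), low-pass
   filtered with a 3rd-order Butterworth at 5 Hz; filtering is zero-phase
   (`sosfiltfilt`) so the envelope is not delayed, and negative
   excursions are clipped to zero. The spectrogram is a Hamming-window
   STFT of 23.2 ms with 5.8 ms hop — 1024/256 samples at 44.1 kHz — with
   no padding (83 frames for a 500-ms clip). Bin centres are carried in
   Hz and on the ERB-rate axis `21.4·log10(4.37·f/1000 + 1)`
   (Glasberg–Moore). The ERB axis is a relabelling of STFT bin centres,
   not a filterbank resampling. The DC bin is excluded throughout.
2. **Descriptors.** The attack segment comes from the weakest-effort
   method: first-crossing times at 10%…90% of the envelope maximum (step
   10%), "efforts" being the intervals between successive crossings; the
   attack is bounded by the crossings whose efforts stay below 3× the
   mean effort, with a logged fallback to the direct 10%/90% crossings in
   degenerate cases, and a one-sample floor on the duration. Log attack
   time is log₁₀ of the duration; attack slope is the mean local envelope
   slope over the attack; temporal centroid is the envelope's first
   moment over the whole clip. Frame-level spectral descriptors treat the
   magnitude spectrum as a mass distribution on the ERB axis: the first
   four standardised moments (single-active-bin frames report skewness
   and kurtosis as 0), least-squares slope of magnitude on frequency,
   spectral decrease `Σ_{k≥2}(a_k − a_1)/(k − 1) / Σ_{k≥2}a_k` over bins,
   95% rolloff on cumulative *squared* magnitude (the only place energy
   rather than magnitude is used), flatness (geometric/arithmetic mean;
   zero if any bin is zero), crest (max/mean), and spectral variation
   (one minus the normalised correlation of successive frames).
3. **Summaries.** Frames whose peak magnitude is below −60 dB relative to
   the loudest frame are excluded (otherwise the faded tail dominates the
   statistics); each series is summarised by its median and IQR with
   linear-interpolated percentiles. The spectral-centroid median is
   log₁₀-transformed, as is attack time — both quantities are modelled on
   log scales. Total: 10 × 2 + 3 = 23 descriptors.

## Reduction

Pearson correlations across stimuli feed an average-linkage hierarchy on
the distance 1 − |r| (absolute value so anticorrelated near-duplicates
also cluster). Data-driven pruning repeatedly takes the strongest pair
with |r| > 0.905 and drops the member lower in a keep-priority list
(unlisted names rank last; ties keep the alphabetically first), which is
deterministic and idempotent. The canonical reduction for this descriptor
family removes spectral slope (median and IQR), spread median, rolloff
median and kurtosis (median and IQR) — slope/spread/rolloff medians track
the centroid median, slope IQR the centroid IQR, kurtosis the skewness
measures. The pipeline's default (`removals="reference"`) commits to that
six-descriptor removal so the retained set of 17 is stable across
stimulus rosters; `removals="data"` applies the threshold rule, whose
outcome is a property of the particular stimuli. KMO is computed from the
anti-image partial correlations of the retained set via the inverse
correlation matrix. Range normalization stores per-column min/max so
held-out folds can be transformed with training statistics (values
outside [0, 1] are allowed and logged); the pipeline normalises once
globally by default.

## PLSR

PLS1 by NIPALS on z-scored predictors (the Kaiser-style eigenvalue-1
threshold is only meaningful on standardised variables, even though the
network uses range normalization): each component's weight vector is the
normalised covariance of the deflated predictors with the response
residual. Components are retained while the training score variance
(ddof = 1) is ≥ 1, minimum one. R², RMSE (population mean square) and the
per-component incremental R² (which sums exactly to the total) come from
the full fit; Q² = 1 − PRESS/TSS with PRESS pooled over five seeded
random folds and TSS about the whole-sample mean (per-training-fold mean
behind a flag). The reported loading table scales each unit-norm weight
column by `y-loading · sd(score)`, i.e. the predictor's contribution to
the fitted response through that component; this makes magnitudes
comparable across components, so ranking descriptors by their maximum
absolute loading is dominated by predictive components. Loadings are a
convention-dependent quantity — across implementations only their signs
and ranks are comparable, and that is all the rank tables use.

## Neural network

A 17-3-1 perceptron with logistic sigmoids at hidden and output layers,
targets on [0, 1] via (rating − 1)/8 (held-out RMSE is then on the unit
scale), weights and biases initialised uniformly in ±0.05. Training is
full-batch: per-pattern gradient deltas of ½(t − o)² are summed over the
108 training stimuli and applied once per epoch, making the update
invariant to presentation order; the reported MSE trace is the mean of
(t − o)², and the convergence contract is MSE < 0.008 within the epoch
budget (700 epochs default; 1000 for the slower-converging tension
dimension). Learning rate defaults to 0.2 with no momentum; training
aborts if MSE exceeds 10× its initial value. Cross-validation partitions
the 137 stimuli into five folds of 27 plus 2 leftover stimuli appended to
every 29-item test set; each fold's network gets a deterministic init
seed spawned from the master seed. Feature contributions follow Milne's
connection-weight method: input *i* contributes
`Σ_j (W1[i,j]/Σ_{i'}|W1[i',j]|)·w2[j]` (per-hidden-unit absolute-sum
normalization; a global normalization is available behind a flag),
expressed as signed percentages whose magnitudes sum to 100 per model and
averaged across the five fold models (optionally renormalised after
averaging).

## Evaluation

Cronbach's α treats the participants as items and the stimuli as
observations — the orientation that measures inter-rater consistency of
one scale; the transpose (stimuli as items) is available but untested
against the invariants. Percent improvement of the network over the
regression is `round(100·(nn − plsr)/plsr)` with halves rounded away from
zero — the convention that reproduces the published comparison integers
exactly. Rank tables take the top six descriptors by absolute loading
(PLSR, max across components) or absolute averaged contribution (NN),
with ties broken by canonical descriptor order.

## Problem sizes and numerical notes

The synthetic study uses 137 stimuli × 40 participants; descriptor
extraction processes 83 frames × 512 bins per clip; cross-validation
uses five folds everywhere. The recovery benchmark plants equal effects
(+0.35) on spectral flatness median, spectral crest median and attack
slope — three retained descriptors chosen for mutual near-orthogonality
on the default stimulus set so the planted mapping is identifiable — with
a stimulus-level noise SD of 0.05 on the unit response scale. Percentile
convention is linear interpolation between order statistics (matching
`numpy.percentile`'s default). Degenerate inputs are errors, not NaNs:
silent clips, constant columns, zero response variance and zero-duration
attacks all raise typed exceptions.

## Limitations

Synthetic tones span wide descriptor ranges but are not psychoacoustic
models of instrument identity, and no loudness equalisation is applied.
The rating generator's linear-Gaussian structure is favourable to both
models; real rating data are ordinal, heteroscedastic and participant-
dependent in ways the generator only caricatures. Results on synthetic
data therefore validate the computations — descriptor arithmetic, model
fitting, cross-validation bookkeeping, contribution analysis — rather
than any perceptual claim. Harmonic-partial tracking, loudness models,
mixed-effects analyses of the raw ratings and multi-response PLS are out
of scope.
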