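# Methods

This note documents the models, the parameter choices that matter, what
the synthetic generator does and does not emulate, and the numerical
conventions used throughout `eegclean`.

## Data model and conventions

Epoched multichannel EEG is held as one `(n_epochs, n_channels,
n_samples)` float array at a shared sampling rate, with per-epoch
condition labels, optional artifact annotations, and subject ids.
Amplitudes are microvolts everywhere (EDF physical units are converted on
read); time indexing is 0-based with half-open `[start, end)` intervals,
which makes the correction stage's splicing unambiguous. The default
working rate is 200 Hz with 1 s epochs: long enough for δ-band features,
short enough that thousands of trials stay desk-scale. Filtering is
zero-phase 4th-order Butterworth; resampling is polyphase with output
length `round(n·g/f)`.

## The 58-feature bank

One 58-dimensional vector per epoch: univariate features are computed per
channel and averaged across channels; connectivity features are averaged
over channel pairs (ordered pairs for Granger). Family totals are
complexity 25, continuity 27, connectivity 6.

Parameter choices, with defaults and reasons:

- **Amplitude histograms** (Shannon/Tsallis/subband entropies): 64
  equal-width bins spanning `[min, max]`. Fixed for reproducibility; the
  entropy of a constant signal is defined as 0.
- **Tsallis orders**: q ∈ {1.1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 7, 10}; q = 1
  is computed as the Shannon limit in nats. Ten orders make the
  complexity family total come out at 25.
- **Subband information quantity**: Daubechies-4 wavelet decomposition at
  the level that puts the approximation band near 0–3 Hz (level 5 at
  200 Hz), entropies of the reconstructed δ/θ/α/β/γ subbands; γ pools all
  detail bands above β, falling back to the highest available band at low
  rates.
- **Cepstrum**: real cepstrum `irfft(log|rfft(x)| + ε)`; coefficients
  c[1], c[2] (c[0] only carries amplitude scale).
- **Nonlinear features**: largest Lyapunov exponent by Rosenstein's
  method (embedding dimension 5, delay at the first autocorrelation zero
  crossing, Theiler window from the spectral mean period; nats/sample);
  Higuchi fractal dimension with k_max = 10; Kennel false-nearest-
  neighbour fraction at dimension 3 with ratio tolerance 15. Series too
  short to embed return the documented sentinel 0.
- **AR coefficients**: order-2 Yule–Walker (MLE autocovariances) on the
  mean-removed signal.
- **Spectral features**: Welch PSD (1 s Hann segments, 50 % overlap),
  trapezoid band powers over δ 0–3, θ 4–7, α 8–15, β 16–31, γ 32–fs/2 Hz;
  median frequency splits cumulative power in half; diffuse slowing is
  the indicator of the PSD peak below 8 Hz. δ-band **coherence** is
  averaged over 0–4 Hz as that statistic is conventionally defined; this
  deliberate 0–3 vs 0–4 asymmetry is kept as printed in the clinical
  feature list the bank follows. Coherence averages half-second Hann
  segments (≥ 3 per 1 s epoch) — with full-epoch segments
  magnitude-squared coherence would be identically 1.
- **Burst/suppression**: envelope = 100 ms moving RMS; burst = envelope
  above mean + 1 SD for ≥ 100 ms; suppression = envelope below 10 μV for
  ≥ 500 ms; run boundaries are corrected for the centred window's
  half-width smear. Regularity uses the sorted-squared-amplitude form
  `REG = sqrt(3 Σ i²u(i) / (N² Σ u(i)))` ∈ (0, 1], defined as 1 for the
  all-zero signal.
- **Spikes**: excursions of `|x − μ|` beyond 3σ lasting ≤ 70 ms; *sharp*
  spikes last < 20 ms (the printed clinical rule makes spikes "≤ 70 ms"
  and sharp spikes "< 70 ms", which cannot distinguish them; 20 ms is the
  conventional sharp-transient cut and is configurable).
- **Connectivity**: histogram mutual information on a 16×16 grid (bits);
  PLI = |mean sign of the analytic-signal phase difference|; Granger =
  mean bivariate F-statistic over ordered pairs with AIC lag selection up
  to order 10 (the "all pairs" aggregation is the mean; degenerate
  collinear pairs return 0); cross-correlation magnitude/lag from the
  normalised full cross-correlation, lag reported in ms.

Degenerate inputs (constant channels) always produce finite documented
sentinels — entropy 0, mobility 0, fractal dimension 1 — never NaN,
because the detectors require finite matrices.

## Outlier detection

All scorers are oriented so that **higher = more anomalous**, and flags
are the top ⌈contamination·n⌉ scores (ties broken toward lower epoch
index), so the only tuning input is the artifact-frequency estimate. The
default contamination, 0.172, matches the generator's default prevalence.

- **HBOS**: per-feature equal-width histograms (equal-frequency when
  `dynamic_bins`); score = Σ_f log 1/(density + ε). Values outside the
  training range within `tol` bin-widths of an edge are assigned the edge
  bin; farther out they receive the minimum density. Defaults 10 bins /
  tol 0.5; the ensemble's second HBOS uses 50 bins / tol 0.1 (a "rigid"
  policy).
- **LOF / OCSVM / PCA** are scikit-learn behind the module surface (LOF
  value; negated one-class-SVM decision function, RBF kernel, ν = 0.2;
  squared reconstruction error from the top principal components).
- **ABOD**: negated variance of the distance-weighted angle statistic
  `⟨a−p, b−p⟩ / (|a−p|²|b−p|²)` over pairs of the k = 10 nearest
  neighbours (self-matches excluded).
- **Autoencoder**: bottleneck MLP (32–8–32) trained to reconstruct the
  standardized matrix, seeded; score = per-row squared reconstruction
  error. **VAE**: a compact dense variational autoencoder (one hidden
  layer per side, latent 5) trained with the reconstruction + KL
  objective in numpy; the score uses the deterministic mean encoding.
- **LSCP**: base detectors are fitted on the full matrix, scores
  z-normalised, and their per-row mean forms a pseudo ground truth; for
  each row the base detector best Pearson-correlated with the pseudo
  target over the row's k_local = 30 nearest neighbours supplies the
  emitted score. Default base set: HBOS(50, 0.1), HBOS(10, 0.5), OCSVM.
- **Fitting modes**: `aggregated` fits once on all epochs; `per_subject`
  fits and thresholds within each subject independently, which matters
  whenever artifact severity or signature differs between recording
  setups. `random_search` samples hyper-parameter configurations and
  ranks them by F-score against annotations, logging every trial.

## Gap-interpolation correction

A flagged epoch is repaired by replacing one G-sample segment. Defaults
G = 40 samples (200 ms at 200 Hz) and context half-width h = 32, giving
the 104-sample self-supervised training window (32 left context + 40 gap
+ 32 right context) cut at random positions from clean epochs.

**Localisation.** The paper-level procedure flags whole trials; where to
place the gap at inference is this package's addition:
`locate_artifact_segment` slides a G-sample window and picks the one
maximising the summed absolute deviation from the per-channel median,
clamped so both h-contexts fit.

**Architecture.** One network per gap offset; all G networks consume the
same channels × 2h context array (time as the width dimension). Each is
a 1-D convolutional encoder over time (channel rows as input channels;
16→32→32 filters, kernels 5/5/3, stride 2) followed by a dense head
(hidden 32 by default) that emits one frame — a vector of channel values.
Because the output of an offset model is a single frame rather than a
time series, a mirrored convolutional decoder has no matching output
geometry; the dense head plays the decoder's role. Each model predicts
the *residual around the linear bridge* between the gap's edge samples —
a skip connection that guarantees edge continuity and means an untrained
(zero-residual) model already coincides with linear interpolation.
Training is full manual-backprop numpy with Adam (lr 2·10⁻³, decoupled
weight decay 0.05, batch 64), squared-error loss, deterministic given the
seed; models are independent and can be trained in parallel. A non-finite
loss raises immediately, naming the offset. Temporal coupling between
offset models (e.g. recurrent state) is deliberately absent.

Correction replaces exactly the located G samples of flagged epochs —
everything else is bit-identical, and unflagged epochs pass through
untouched — so the operation's footprint is auditable.

## Evaluation

F-score is F1 with "artifact" as the positive class; Cohen's κ uses
marginal chance agreement; both are defined 0 in their degenerate cases
and are recomputable from the emitted confusion counts. The reference
detector knows only the artifact count k: it flags k of n epochs
uniformly at random, and since F = TP/k with hypergeometric TP, its
expected F-score is k/n (0.172 at the default prevalence) — this is what
`scripts/acceptance.py` re-simulates.

The downstream probe trains a linear SVM (standardised inputs, C = 0.01)
under stratified 5-fold cross-validation with identical fold assignments
across data variants, so accuracy differences isolate the variant. Two
input representations are available: down-sampled flattened epochs, and
per-channel log band powers. The benchmark experiments use the band-power
representation because the generator encodes condition as an α-power
modulation with random oscillator phases — information that is invisible
to a linear classifier reading raw amplitude samples. For the
artifact-trial comparison the probe additionally trains each fold's
classifier only on trials the detector kept (`train_mask`) and scores
only artifact-bearing test trials (`eval_mask`): a rejection pipeline
never trains a condition model on trials it has flagged, and the question
correction answers is whether flagged trials become usable by models
built from clean data.

## The synthetic generator

Clean epochs are sums of five band oscillators (δ…γ, one random
frequency, per-channel random phase and log-normal amplitude) over a
1/f^α noise floor (α = 1, 10 μV RMS); class c scales the α-band amplitude
by 1 + 0.2·c across six classes. Artifacts are additive, time-localised,
and annotated with exact interval/channel masks: blink (biphasic < 4 Hz
pulse, 300–500 ms, frontal-dominant), muscle (20–80 Hz burst, 200–600 ms,
several channels), pop (step with exponential decay on exactly one
channel), drift (sub-hertz ramp), mixed 0.4/0.3/0.2/0.1 at prevalence
0.172 and peak amplitude `magnitude` × the epoch's pooled SD (default 8).
One global seed drives counter-based substreams keyed by epoch index, so
generation is order-independent and fully reproducible. Default shape
follows the study conditions (32 channels at 200 Hz, six classes,
thousands of short trials); the test benchmark uses 1,000 epochs at 8
channels — the package's chosen problem size for the seeded experiments.

**What the generator does not emulate** — and hence what passing tests do
not show about recorded EEG: volume conduction and realistic topography,
evoked (phase-locked) responses, non-stationary background, heterogeneous
or subtle artifact morphologies, annotator noise. Two visible
consequences: (i) injected artifacts are *extreme global* feature-space
outliers, so detector rankings compress at the top — in particular the
angle-based scorer, whose 1/d⁴ distance weighting saturates on gross
outliers, performs on par with the global methods here even though it is
by far the weakest on real recordings; (ii) with random oscillator
phases, mid-gap samples ~100 ms from the context carry little linearly
extractable information, so the interpolators' realistic target is the
conditional mean — clearly better than linear interpolation mid-gap, but
a conservative (power-shrunk) reconstruction.

## Known limitations

- Correction replaces a single fixed-length segment per flagged epoch;
  artifacts longer than G = 40 samples are only partially removed.
- The conditional-mean reconstruction under-represents band power inside
  the gap; power-preserving (stochastic) decoding is future work.
- Detection assumes artifacts are rare (prevalence well below 0.5) and
  that a usable contamination estimate exists.
- The per-offset ensemble retrains G networks per data set; weights are
  serialisable, but there is no transfer across channel counts or rates.
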