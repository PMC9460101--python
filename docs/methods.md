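# Methods

## The model

`sincvoice` classifies voice disorders from raw sustained-vowel waveforms.
The first layer of the classifier is a bank of parametrized band-pass
filters: each channel's impulse response is the difference of two scaled
sinc low-pass kernels,

    g[n] = 2 f2 sinc(2 pi f2 n) − 2 f1 sinc(2 pi f1 n),

with `sinc(x) = sin(x)/x`, `sinc(0) = 1`, cutoffs `f1 < f2` in normalized
frequency, and `n` over symmetric integer offsets. Only the two cutoffs
per channel are learned, so an 80-channel front end has 160 scalars where
a free-form 80×251 convolution has 20,080 (plus biases). Every kernel is
even-symmetric by construction, and each channel's frequency response is a
single contiguous band — which is what makes the learned front end
directly interpretable: the band table *is* the explanation.

The reference stack (`default_sincnet_spec`) is: sinc front end (80
channels × 251 taps) → max-pool 3 → batch norm → layer norm → leaky-ReLU →
two (60, 5) conv blocks with the same pool/norm/activation pattern and
dropout 0.5 → three 2048-node fully connected blocks with dropout 0.3 →
softmax. Two baselines share everything except the front end: `CNN(1D)`
replaces the sinc bank with a fully learnable 80×251 convolution, and
`CNN(2D)` consumes a log-magnitude STFT image (25 ms window, 10 ms hop)
through three (3,3)-kernel, (3,3)-stride conv blocks with channels
(80, 60, 60), conv dropout 0, 0.5, 0.4 and FC dropout 0.3, 0.2, 0.2.

### Cutoff constraint

During optimization the cutoffs are reparameterized so every real-valued
parameter pair maps to a valid band:

    f1 = min(min_low + |raw_low|, nyquist − min_band)
    f2 = min(f1 + min_band + |raw_band|, nyquist)

`min_low = min_band = 50 Hz` by default: bands stay wider than typical F0
resolution and can never collapse to zero width. This mapping is total —
no gradient clipping or projection step is needed. Its one quirk is the
|x| kink at zero, where the subgradient sign is taken as +1.

### Gradients

The network stack is a compact reverse-mode layer library on NumPy
(`sincvoice.nnet`) with hand-derived backward passes. The sinc layer's
gradient is analytic: since `d/df [2 f sinc(2 pi f n)] = 2 cos(2 pi f n)`
for every integer offset including 0, the loss gradient with respect to a
cutoff is the kernel-level gradient dotted with a windowed cosine probe.
A finite-difference check on a 4-filter miniature agrees to ~1e−7
relative. Front-end convolutions (both sinc and free-form) run via FFT;
mid-stack convolutions via im2col matrix multiplication; the 2-D blocks
exploit kernel == stride, which makes tiles non-overlapping and the
backward pass a reshape.

## Windowing and the resolution limit

Truncating the ideal band-pass response ripples badly, so kernels carry a
Hamming taper by default (`window="none"` is kept for oracle tests against
the analytic response). The taper sets a frequency resolution of roughly
a 4·sr/L Hz main lobe (≈255 Hz at L=251, 16 kHz). A band much narrower
than two main lobes cannot concentrate 85% of its response energy in-band
no matter the implementation; mel-spaced low channels (50–70 Hz wide) sit
in that regime and measure ≈0.5, while resolvable bands measure 0.93–0.99.
Energy-concentration checks therefore use linear-spaced or upper-mel
channels whose bands are wide relative to the main lobe.

## Initialization

Band edges tile [50 Hz, Nyquist − 50 Hz] on the mel scale (denser below
1 kHz, matching where voice detail concentrates); `linear` spacing is
available. Initialization is deterministic given the configuration. Bands
whose mel width falls below the 50 Hz floor are widened to the floor by
the constraint mapping.

## Synthetic vowels

The proprietary clinical recordings this kind of system is trained on
cannot be redistributed, so the package ships a source-filter generator
whose class presets emulate the qualitative disorder signatures described
clinically for sustained /a/:

| class  | jitter % | shimmer % | HF noise (dB rel. voiced) | AM depth |
|--------|---------:|----------:|--------------------------:|---------:|
| Normal |      0.3 |       1.5 |                       −50 |      0   |
| FD     |      3.0 |       8.0 |                       −40 |      0   |
| Neo    |      1.5 |       4.0 |                       −10 |      0   |
| Pho    |      1.5 |       4.0 |                       −22 |      0   |
| VP     |      1.0 |       3.0 |                       −40 |      0.8 |

Mechanism: a Rosenberg-style glottal flow pulse train (per-cycle period
jittered by `jitter_pct`, per-cycle amplitude by `shimmer_pct`) is
differentiated (lip-radiation effect — removes the DC of the nonnegative
pulse train and flattens its tilt so the first formant dominates the
spectrum, as in real /a/) and fed through a cascade of second-order
resonators at (800, 80), (1200, 90), (2800, 120) Hz. High-passed
(>2.5 kHz) or band-passed Gaussian noise is added at `hf_noise_db` below
the voiced RMS; vocal-palsy nonstationarity is a slow sinusoidal
amplitude modulation (`am_depth` 0.8 at 4 Hz, random phase). Output is
peak-normalized to 0.9, so generation is clip-free by construction, and
byte-identical for a given seed.

Default synthesis rate is 16 kHz (44.1 kHz is configurable); default
duration 3 s, shortened to 1 s in the training experiments below.

What the generator does *not* emulate: speaker variability, recording
channel effects, perceptual realism of pathology, vowels other than /a/,
or the overlap structure of real disorder classes. Passing tests
demonstrate that the architecture, training loop and metrics behave
correctly on a learnable task with planted class signatures — not that
the system reaches clinical accuracy on real voices.

## Training

Utterances are split 8:2 (stratified) into train+validation and test;
the 80% pool supports stratified 5-fold cross-validation (per-class
shuffle, round-robin). Models consume 200 ms chunks peak-normalized to
unit amplitude; the utterance's label is broadcast to its chunks, and an
utterance's prediction is the argmax of the mean of its chunk posteriors
(lowest class index on ties). Training: Adam, lr 1e−3, batch 32, ≤30
epochs (20 in the desk-scale experiments), early stopping with patience 5
on validation loss, best-validation checkpoint restored. Chunks are cut
at 100 ms shift: at 16 kHz this is already ~9 chunks per training second,
and denser shifts multiply epoch cost for little extra diversity at desk
scale. All randomness derives from explicit seeds; single-threaded runs
are bit-reproducible.

### Desk-scale profile

Experiments that actually train models use `compact_sincnet_spec` /
`compact_cnn1d_spec`: the same topology at reduced width (32 front-end
channels × 101 taps, two (16, 5) conv blocks, two 64-node FC blocks,
pool 4). The full-width reference specs are constructed and
parameter-audited in the test suite but not trained there; problem sizes
(40 utterances/class for the 4-class task and the convergence comparison,
16/class for the band-recovery runs, 1 s utterances) were chosen so a
complete run finishes in minutes on one CPU core. On the default 4-class
task the compact SincNet reaches 100% utterance test accuracy within 20
epochs. The convergence advantage of the sinc front end over the
free-form one is a property of the default task size: on a much smaller
corpus (16/class) both models converge erratically and the ordering of
their early validation losses is close to chance.

## Metrics

Accuracy = 100 × trace/total of the utterance-level confusion matrix
(rows = true class); per-class sensitivity = 100 × diagonal/row-sum; UAR
= unweighted mean of per-class sensitivities (#classes = 4 or 3 or 2
depending on the task); specificity = 100 × TN/(TN+FP) for binary
detection. A class with an empty test row has undefined sensitivity and
is excluded from UAR with a warning rather than scored 0, which keeps UAR
well-defined on tiny folds. Cross-validated results aggregate as
mean ± sd across folds. t-SNE scatter plots of utterance embeddings (the
mean of chunk activations feeding the softmax) use scikit-learn's
implementation with perplexity clamped to n/4 for small sets.

## PSD interpretability

`psd_profile` passes a waveform through the front end, estimates a
256-point PSD per channel and averages across channels. The estimator is
Welch with 256-point segments, 50% overlap and a Hamming taper, keeping
all 256 two-sided bins so the per-channel matrix is exactly
(n_filters × 256); peak and band-energy reporting use the one-sided half
(62.5 Hz bins at 16 kHz). Welch-with-overlap was chosen over a bare
periodogram for variance reduction on 1–3 s signals; `detrend` is off so
an all-zero input yields an exactly zero profile. Profile comparisons
between two front ends report each profile's *relative* first-formant
energy share rather than the raw ratio, because absolute front-end gain
is arbitrary (unit-passband sinc kernels vs small-scale learned kernels
differ by ~30× in raw energy regardless of spectral shape).

## Numerical choices and degenerate inputs

- `sinc(0) = 1` handled exactly (no epsilon); kernels are evaluated
  analytically, never by FFT design.
- An all-zero chunk skips the peak-normalization divide and passes
  through as zeros; an untrained model maps it to a near-uniform
  posterior.
- Normalization layers use eps = 1e−5; batch norm keeps running
  statistics (momentum 0.1) for single-sample inference.
- Ties in argmax resolve to the lowest class index everywhere.
- The band table CSV round-trips cutoffs at 6-decimal precision; bands
  narrower than the 50 Hz floor cannot be represented and are widened by
  the constraint on re-import.

## Known limitations

- The NumPy training loop is single-core and desk-scale; it is not meant
  for corpora beyond a few hundred utterances.
- The 2-D baseline requires kernel == stride in its conv blocks (as
  configured); arbitrary-stride 2-D convolution is not implemented.
- Mel-spaced low-frequency channels are narrower than the kernel's
  frequency resolution; their effective selectivity is set by the window
  main lobe, not the nominal band edges.
- Synthetic-task accuracy says nothing quantitative about clinical
  performance (see the generator's non-goals above).
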