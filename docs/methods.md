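# Methods

`oblfp` decodes the presence of an odor from single trials of multichannel
olfactory-bulb local field potentials (LFPs). This note documents the model
and procedure choices, the synthetic data the package is validated on, and
the limits of what those validations show.

## Problem setting

A trial is a 32-channel extracellular recording sampled at 30 kHz for 2 s,
labeled by the odorant delivered (one of six monomolecular odorants at some
concentration in % v/v) or by the mineral-oil control. The task is binary:
odor presence vs absence, decided from a single trial. Class order is fixed
everywhere: index 0 = absence, index 1 = presence.

## Preprocessing

1. **Bandpass** — fifth-order Butterworth, 0.5–100 Hz, applied
   forward–backward (zero phase). Offline trial analysis conventionally
   avoids phase distortion, so all attenuation reasoning uses the *squared*
   Butterworth magnitude response. The 0.5 Hz corner rings slowly relative
   to a 2-s trial; we therefore extend the reflect padding to
   0.2 / low_cut seconds (0.4 s), capped at the trial length, which keeps
   passband gain within 0.1% at 50 Hz. Residual sub-hertz edge ripple is
   unavoidable at this trial length and is irrelevant above ~5 Hz.
2. **Downsampling** — plain 30:1 sample selection (60000 → 2000 samples,
   30 kHz → 1 kHz). No extra anti-alias stage: the 100 Hz cut-off is far
   below the 500 Hz post-decimation Nyquist.
3. **Welch PSD** — per channel, 256-point Hann window, 50% overlap,
   one-sided density (power per Hz), `detrend=False` so white-noise power
   is conserved (sum(psd)·Δf ≈ variance). A 2000-sample trial gives
   floor((2000−256)/128)+1 = 14 segments and 129 bins (0–500 Hz at
   3.90625 Hz resolution). The classifier input is therefore a 32×129
   matrix.
4. **Robust scaling** — per (channel, bin) feature over trials:
   (x − median)/IQR with linearly interpolated quartiles; a zero IQR is
   replaced by 1 so constant features map to 0. Statistics are fit on each
   fold's training trials only. The implementation is a direct
   median/percentile computation (so the scaler parameters are plain
   arrays); tests cross-check it against scikit-learn's `RobustScaler`.

## Architectures

Both networks read the scaled PSD matrix as a 1-D signal with 32 input
channels and 129 positions — the convolutional axis is the frequency-bin
axis. This is the single most consequential reading of the design: the
spectra, not the raw time series, carry the discriminative signal, and the
networks learn structure *across frequency*. (A raw-series variant would
slot into the architecture registry; it is not implemented.)

Where a layer hyperparameter was open (stem kernel sizes and widths, bias
conventions, placement of batch normalization), we fixed it by requiring
the trainable-parameter totals to reproduce the published model sizes,
which act as a checksum on the architecture: 155.1 K (attention model),
306.3 K (residual model), 461.4 K combined. The resolved configurations:

**AttentionCNN** (155,104 params): maxpool s2 → [Conv1D 32→48, k5 →
BatchNorm → ReLU → maxpool s4] → [Conv1D 48→128, k3 → BatchNorm → ReLU →
maxpool s4] → three parallel Conv1D branches (kernels 1/3/5, 64 filters
each, biased, no branch BatchNorm) → concat 192 → squeeze-and-excitation
(r = 16, unbiased bottleneck) → CBAM-style spatial attention (per-position
mean and max over channels, stacked, Conv1D kernel 7, sigmoid mask) →
global average pool → dropout 0.3 → FC 256 + ReLU → dropout 0.5 →
linear 2. The bin axis contracts 129 → 64 → 16 → 4 before global pooling.

**ResCNN** (306,274 params): maxpool s2 → Conv1D 32→32, k7, stride 2 (+BN,
ReLU) → maxpool s4 → three 64-channel squeeze-and-excitation residual
blocks (the first projects 32→64 through a 1×1 conv + BN shortcut) →
Conv1D 64→128, k3 (+BN, ReLU) → maxpool s2 → two 128-channel SE-residual
blocks → global average pool → dropout 0.4 → linear 2. Residual-path
convolutions carry no bias (BatchNorm follows); each block's SE gate uses
r = 16.

Squeeze-and-excitation: z_c = mean_t u_c(t); s = σ(W₂ δ(W₁ z));
ũ_c = s_c·u_c, with δ = ReLU, W₁ ∈ R^(C/r×C), W₂ ∈ R^(C×C/r).

Max pooling uses kernel = stride and drops ragged tails; convolutions use
'same'-style padding so lengths are governed by pooling alone. Weights
initialize fan-in-scaled uniform (U(±1/√fan_in)); batch-norm starts at
unit scale, zero shift. All randomness flows through one seeded generator.

The numerical core is a compact numpy layer library with hand-written
backpropagation (`oblfp.nn`), exactly covering the primitives above; its
gradients are finite-difference-verified and its squeeze-and-excitation
agrees with an independent scalar oracle to 1e-6.

## Training and fusion

Five-fold stratified cross-validation: ~20% test per fold; 10% of the
remaining training portion (at least one trial per class) becomes the
validation set. Stratification keeps balanced data balanced per fold — the
partition is otherwise unconstrained. Optimizer: AdamW, initial learning
rate 5e-4, decoupled weight decay 1e-4, batch size 32 (unstated in the
protocol; 32 chosen and recorded in run manifests). Schedules: cosine warm
restarts (T₀ = 10 epochs, T_mult = 2, zero floor) for standalone model
evaluation; one-cycle (cosine ramp from lr0/25 to lr0 over the first 30%
of the horizon, anneal to lr0/1e4) for the two ensemble members. Early
stopping monitors validation loss with min_delta = 0.001 and patience 15
(from a stated 15–20 range); the best-validation-loss checkpoint is
restored for testing.

Fusion is parameter-free late fusion: p_ens = (p_att + p_res)/2, odor
declared iff p_ens(presence) > 0.5. The strict inequality sends exact
ties to odor-absence.

Class balancing before the main binary run randomly under-samples the
majority (odor-presence) class, without replacement, to the control count
(2013/336 → 336/336 = 672 trials). The balancing seed is an explicit
argument; no hidden default.

## Evaluation

Accuracy, precision, recall (= sensitivity; one quantity, two names),
specificity, and F1 come straight from the confusion counts with presence
positive; a zero denominator makes the metric *undefined* (reported as
None with a logged reason), never 0. AUC is the Mann–Whitney rank
statistic with half-credit ties. Per-fold values aggregate as mean ±
sample SD.

Calibration: confidence = max(p_ens) ∈ [0.5, 1]; 10 equal bins on
[0.5, 1] split by correctness, plus group mean confidences and a binned
reliability table (both emitted because either convention is defensible).

Concentration analysis: per level, a balanced binary run vs controls; the
five fold accuracies are tested against 0.5 with a two-sided one-sample
t-test (df = 4; sidedness was open — two-sided is the conservative
choice). Status labels: p ≥ 0.05 at chance; p < 0.05 marginal;
p < 0.001 and accuracy > 70% reliable; p < 0.001 and accuracy > 85%
robust. The detection threshold is the lowest concentration that is at
least "reliable". Exactly constant fold accuracies at 0.5 short-circuit
to t = 0, p = 1 (the t-test degenerates at zero variance).

Per-odor analysis mirrors the main balancing at odorant scale: each
odorant vs control, under-sampled to the smaller group, full 5-fold
ensemble run, one shared seed across odorants.

Embeddings: the two members' post-global-average-pool vectors concatenate
to 320 features per trial; t-SNE (perplexity 30 unless n is small, fixed
seed 42) produces 2-D and 3-D coordinates, and the silhouette score over
odorant labels is computed in the 2-D embedding. Identical features for
all trials make the silhouette undefined (flagged, not zeroed).

Latency benchmarking runs 50 discarded warm-up passes then 200 timed
passes per batch size, reporting mean ± SD latency, throughput, and the
real-time factor (trial duration / latency). Wall-clock numbers are
hardware-dependent and never asserted in tests.

## Synthetic data

The generator emulates exactly the statistics the decoder relies on:

* **Background**: per-channel white noise amplitude-shaped to 1/f^(β/2)
  in the frequency domain (β = 2 by default, a typical LFP slope in the
  1–100 Hz band), scaled to `noise_sd` = 100 µV; frequencies below 0.1 Hz
  are clamped to keep the 1/f divergence finite.
* **Respiration**: one 3 Hz sinusoid per trial (random phase), shared
  across channels with a smooth per-channel scale (0.7–1.0), mimicking
  volume conduction of the sniff rhythm; amplitude 50 µV.
* **Odor response**: additive band-limited noise power — a Gaussian
  amplitude envelope exp(−(f−center)²/(2·halfwidth²)) on the same
  background shaping, weighted per channel by a loading vector (default: a
  smooth 0.4–1.0 gradient across the probe) and across concentration by a
  Hill gain 1 + max_gain·cʰ/(cʰ + kʰ) (defaults k = 0.3% v/v, h = 2, so
  the half-saturation sits at the standard test concentration). The effect
  is purely spectral by construction — band power, not a phase-locked
  waveform — because the decoder consumes PSDs. Any saturating monotone
  dose curve would do; Hill was chosen for its two interpretable
  parameters.
* **Default odorant panel**: six odorants with distinct band centers
  (70, 60, 40, 30, 20, 12 Hz) and descending max_gain (8 → 1.2), giving a
  per-odor separability spread from excellent to weak.
* **Layouts**: the main layout (six odorants × ~336 trials at 0.3% plus
  336 controls = 2349 trials, 2013 odor-presence) and a concentration
  layout (0.03/0.1/0.3/1.0% × 200 plus 200 controls = 1000 trials). The
  stated total for the concentration set is inconsistent in the source
  material (2600 vs the enumerated 1000), so counts are configuration,
  defaulting to the enumerated groups.

Every trial draws from a counter-derived substream
(`SeedSequence(seed, spawn_key=(trial_index,))`), so any subset of a
layout — for example the survivors of class balancing — regenerates
bit-identically without materializing the rest. This also lets the
pipeline featurize trial-by-trial in constant memory; a full 672-trial
canonical set is never held as raw signal (it would be ~5 GB).

**What the generator does not model**: spikes, cross-frequency coupling,
trial-to-trial adaptation, inter-subject variability (subject ids are
assigned round-robin and carry no signal), electrode artifacts, or the
absolute power levels of real recordings. Passing the recovery tests
therefore shows the pipeline is correct and sensitive to band-limited
spectral power differences of the modeled size — it does not certify
real-data accuracy, and the published real-data numbers (86.2% accuracy
etc.) are out of scope without the original recordings.

## Validation problem sizes

The recovery suite runs three synthetic experiments chosen as the smallest
sizes that make their qualitative claims statistically meaningful: the
headline run uses the full 672-trial balanced layout at canonical
32 × 60000 resolution with strong effects (all max_gain ≥ 3.5) and must
reach accuracy ≥ 0.95 and AUC ≥ 0.98; the zero-effect control uses 200
half-second trials and must land inside the 95% binomial interval around
0.5; the dose ladder uses 60 trials per level (half-second trials) and
must be non-decreasing in concentration with the top level reliably
detected. The scaled runs shorten the horizon to 60 epochs but keep the
standard patience of 15 — the one-cycle warm-up occupies the first 30% of
the horizon at low learning rates, so a patience shorter than the warm-up
would stop training before the peak rate arrives.

## Known limitations

* Trial time alignment to odor onset/inhalation is not modeled; the
  container records trials as given and never re-windows.
* Trial duration is treated as data-driven (the feature stage only needs
  ≥ 256 samples at 1 kHz); the canonical 2-s assumption appears only in
  the generator defaults.
* The five baseline architectures of the comparison harness are registry
  stubs; only the two ensemble members are implemented.
* Ingestion of the original public dataset's layout is a declared,
  unimplemented adapter (`read_crcns`), since the data requires an
  external download.
* Training is CPU-oriented and single-threaded numpy; it is intended for
  desk-scale experiments, not large hyperparameter sweeps.
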