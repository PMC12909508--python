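# Methods

This note documents the models, defaults, and numerical choices behind
`epilobe`, and what the synthetic benchmark does and does not show.

## Synthetic EEG generator

Each synthetic subject is a channels × samples matrix (µV, 256 Hz by
default) over eight bipolar 10–20 channels chosen so that every lobe
has two channels (`FP1-F7, FP2-F8, T7-P7, T8-P8, P7-O1, P8-O2, O1-A1,
O2-A2`). The background per channel is the sum of

* pink (1/f-amplitude) noise, RMS `noise_level` = 5 µV,
* band-limited alpha (8–13 Hz) noise, RMS `background_alpha_power` = 2 µV,
* band-limited delta (0.5–4 Hz) noise, RMS `background_delta_power` = 2 µV,

all drawn independently per channel from one seeded generator; the seed
fully determines the output. Seizures are ~3 Hz spike-wave bursts — a
biphasic Gaussian-derivative spike followed by a slow half-wave,
repeated per 1/3-s cycle and Tukey-tapered — added *only* to the
channels of the event's lobe. The burst RMS is 20 µV times the
activity-tier factor 1.0 / 2.0 / 3.5 (Low / Medium / High). The tier
factors are a free design choice, spaced widely enough that tertile
binning of band-power features separates the tiers; no quantitative
tier definition exists to calibrate against. Spike-wave morphology
itself is a choice: any waveform separating the classes would do, and
the 3 Hz spike-wave is the clinical archetype.

`generate_dataset` places `events_per_subject` bursts (8–16 s, seeded
onsets) per subject, cycling the lobe assignment across subjects so
every lobe is represented in every partition (a balanced design —
otherwise small-sample benchmarks measure lobe-coverage luck rather
than the localizer). Subjects are split 70/10/20 by count with at
least one subject per partition (10 subjects → 7/1/2, 3 → 1/1/1);
partitions are disjoint by construction.

What the generator does **not** emulate: volume conduction and dipole
geometry, inter-channel correlation structure, EMG/ocular artifacts,
non-stationary background, or realistic seizure evolution. Passing the
end-to-end benchmark therefore shows the pipeline's machinery is wired
correctly and can exploit lobe-localized low-frequency structure; it
does not predict clinical performance.

## Dual-tree complex wavelet transform

Two parallel real, periodized, perfectly reconstructing DWTs give the
real and imaginary parts of each complex sub-band. Approximate
analyticity requires a half-sample delay between the trees; we obtain
it with linear-phase biorthogonal filters of odd length (integer group
delay, tree a: `bior4.4`) and even length (half-integer group delay,
tree b: `bior3.5`), the classical odd/even dual-tree construction. At
level 1 both trees share one filter and tree b sees the input delayed
by one sample. Because each tree is exactly invertible, the round trip
with untouched coefficients is exact (measured max relative L2 error
~1e-12 over 50 random length-1024 signals), and denoising gain varies
by < 1 dB under circular shifts of 1–8 samples — the shift-tolerance
that motivates the dual tree over a single DWT.

Denoising soft-thresholds the complex detail magnitudes per sub-band at
the universal threshold σ_k √(2 ln N_k) with σ_k estimated by the MAD
of |D_k| around its median (÷ 0.6745); the approximation band is never
thresholded. Depth defaults to four levels.

## Preprocessing defaults

Low-pass: 4th-order Butterworth at 30 Hz, applied forward-backward
(zero phase). Windows: 2 s, 50 % overlap, 0-based half-open sample
intervals, trailing partial window dropped (count = ⌊(N−w)/h⌋+1). A
segment is *seizure* when ≥ 50 % of its samples lie inside an annotated
interval, *non-seizure* when wholly outside every interval padded by
the exclusion margin, *excluded* otherwise. The margin defaults to
60 s in `label_segments`; the synthetic pipeline uses 20 s because its
recordings are 120 s long — with a 60 s margin almost no inter-ictal
segment would survive. Both are config keys. Channel-to-lobe mapping
uses the first electrode of a bipolar pair: FP/F → frontal,
T → temporal, P → parietal, O → occipital, C → excluded; unknown
prefixes are excluded with a log line, never an exception.

Independent-component artifact removal is out of scope; the low-pass
plus wavelet denoising stand in for it.

## Backbone and layer counting

The reference backbone starts from the canonical 50-layer bottleneck
residual network. Counting every primitive node — input, conv, BN,
activation, pool, addition, FC, softmax, output — its layer graph has
177 nodes. We remove the last five (final ReLU, global average pool,
FC, softmax, output) and append ten: two inception-residual blocks
(branch filters 64 and 128), a RegNet refinement block, four stacked
3×3 convolutions (64→128→256→512), global average pooling, FC, and
softmax. Appended composite blocks are custom layers counting as one
node each; the convention is frozen in `backbone.layer_graph`, making
177 − 5 + 10 = 182 auditable. (No published enumeration of the ten
layers exists; this one reproduces the stated arithmetic while keeping
each appended unit a meaningful module.)

The inception-residual block is X = ReLU(incep(y) + proj(y)), where
incep concatenates 1×1, 3×3, 5×5 convolutions and a same-padded 3×3 max
pool, and proj is a 1×1 convolution inserted because the concatenation
changes the channel count — a residual sum requires addable shapes.
The RegNet block computes Z2 = ReLU(BN(1×1 conv)), runs a ConvLSTM cell
on Z2 (state carried across refinement stages; BN + ReLU applied to the
hidden output, not the cell state), fuses concat[Z2, O] through a 3×3
convolution, expands back with a 1×1 convolution, and adds the result
to the stage input (the undefined fifth term of the residual sum is
taken equal to the fourth, i.e. the branch output). All of this runs on
the in-repo autodiff engine; training uses Adam at learning rate 1e-4
with batch 140 class defaults for the detection head (epochs 100) and
the same optimizer for brief backbone training.

Desk scale: widths ×1/8, one bottleneck per stage, 64×64 single-channel
spectrograms, 8 backbone epochs. These sizes are the package's own
benchmark conditions; the topology is unchanged by scaling.

## SVGL-HBO

Positions are continuous in [0,1]^d; mask = (position > 0.5). Fitness
χ is the 3-fold stratified cross-validated accuracy of a fixed probe
(logistic regression on standardized features, fixed split seed),
memoized per mask; an empty mask scores 0. Population 30, 100
iterations, bounds [0,1], θ = 2, step size ϖ = 0.05 decaying as
1/√iteration. Per agent per iteration a fair coin picks the phase (the
schedule is unspecified in the source formulation; 0.5 is the neutral
choice).

The accuracy fitness is non-differentiable, so the Langevin exploration
needs a gradient surrogate — the main interpretive decision. We use a
two-point simultaneous-perturbation estimate of the probe's
cross-entropy on the continuous relaxation (features scaled
elementwise by the position), with variance reduction: the same
perturbation is evaluated at the agent and at a snapshot of the best
position (refreshed every 10 iterations), and the snapshot's averaged
gradient is added back as the control variate. The surrogate's probe is
an L2-regularized logistic fitted by a few Newton steps on a fixed
stratified holdout — thousands of surrogate evaluations per search make
this the hot path. Exploitation moves candidate = prey ± x2 · ⊥ · Φ
with Φ = |prey − position| elementwise, ⊥ = θ · iter/total, sign +1
iff x2 ≤ 0.5, and keeps the move only if χ improves. The truncated
fitness expression is read as χ = accuracy exactly; an optional
feature-count penalty exists but is off by default.

On 8 features (3 informative) the search matches the exhaustive
255-mask optimum across seeds; the best-so-far trace is non-decreasing
and positions never leave the bounds.

## Fuzzy Seizure Activity Index

Inputs: relative alpha power, relative delta power (Welch PSD), and
spectral entropy normalized by log of the number of PSD bins. Each
variable has three generalized-bell memberships; level centers default
to tertile midpoints of the training distribution, width β = half the
inter-center distance (so neighbouring bells cross near 0.5), slope
γ = 2. The rule table has four rows — (L,L,L)→L, (M,M,M)→M, (L,H,H)→L,
(M,M,L)→H — taken as canonical where the prose rule list disagrees with
it; unmatched inputs fall back to the maximum-strength rule (with bell
memberships every strength is strictly positive, so the fallback is a
guard, not a code path in practice). Rule strength is the min over
antecedent degrees; consequent crisp values are 0.25/0.50/0.75; DF is
their strength-weighted average, hence always inside [0.25, 0.75]; the
stage is the nearest consequent. The index is a relative, signal-derived
tier with no clinical calibration.

## Wave-GRU localizer

Four stacked GRU layers (50 units at reference; 32 in the desk-scale
benchmark), dropout 0.2 between layers, softmax head over the four
lobes. The candidate state uses sin(·) instead of tanh; gates use
logistic sigmoids. The source mixing equation reuses the reset gate
with an undefined symbol; default mode uses standard update-gate mixing
h = (1−u)h + u·c (otherwise the computed update gate is dead code), and
the literal reset-gate mixing is available via `paper_literal_gate`.
Update-gate biases initialize at −2 so the unit starts biased toward
carrying memory — with neutral gates the product of step Jacobians
decays like 0.5^T and gradients over 100 steps vanish regardless of the
activation; with the memory-biased start the first-step input gradient
stays above 1e-8 over 100 steps for all tested seeds.

Input sequences: each 2-s segment is split into 8 sub-windows of
0.25 s; per sub-window the features are log band powers (delta, theta,
alpha, beta) averaged within each lobe's channels — 16 values — plus
the scalar fuzzy index, which enters as an input feature (whether it
gates or merely accompanies the localizer is ambiguous in the source;
input feature is the weaker, safer reading). Training: cross-entropy,
batch 128 (64 at desk scale), weight decay 1e-7, Adam or SGD (lr 0.01).
Hyperparameters (lr log-uniform 1e-4..1e-1, dropout 0.1..0.5,
optimizer) are tuned by the in-repo sequential searcher minimizing
validation MSE on one-hot targets — MSE is kept as the tuning objective
even though the final model trains with cross-entropy. Tuning uses the
subject-wise validation partition, which is stricter than holding out a
fraction of training segments.

## Metrics and evaluation

Specificity, accuracy, precision, recall, F1, and MCC are computed
directly from TP/TN/FP/FN. A zero factor in the MCC denominator yields
0 by convention. Lobe metrics are one-vs-rest per class with a macro
average (the binary formulas don't extend canonically; this convention
is ours). The end-to-end benchmark balances seizure/non-seizure
segments 1:1 by majority-class subsampling before training and
evaluation.

## Known limitations

* The synthetic benchmark's class separation is deliberately strong;
  the reported desk-scale accuracies say nothing about clinical EEG.
* The DT-CWT's odd/even filter pairing is only approximately analytic;
  Q-shift designs achieve better analyticity at levels ≥ 2.
* The autodiff engine is single-threaded float32 numpy; reference-scale
  (224×224, full widths) training is out of its intended envelope.
* EDF writing covers the synthetic recordings' needs (uniform rate,
  16-bit) and is not a general-purpose EDF+ writer.
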