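# Methods

`longlesion` implements a training pipeline for segmenting *new* multiple
sclerosis (MS) lesions between two longitudinal FLAIR MRI acquisitions, and
the lesion-wise evaluation that goes with it. This note records the models,
the synthetic data they are exercised on, the numerical choices, and the
limits of what the tests demonstrate.

## The detection model

Two architectures share the same building blocks (two 3×3×3 convolutions +
instance normalization + ReLU per level, 2× average pooling between
levels).

1. **Single time-point segmentation U-Net** — encoder and decoder linked by
   skip connections, 1 input channel, 2-class softmax output. Its role is
   to teach the encoder what an MS lesion looks like, using widely
   available cross-sectional data (Stage 1).
2. **Siamese new-lesion network** — one encoder with *shared weights*
   applied to both time-points (weight sharing is structural: there is a
   single parameter set), a per-level aggregation block, and a single
   decoder. The aggregation block concatenates the two time-points'
   feature maps along channels (doubling the channel count) and applies a
   1×1×1 convolution with ReLU back to the original channel count.
   Concatenation order is fixed (tp1, tp2); no output symmetry is imposed.

Training proceeds in three stages: Stage 1 trains encoder + decoder on
(FLAIR, lesion-mask) pairs; Stage 2 builds the siamese network around the
Stage-1 encoder — which is frozen from this point on — and pretrains
aggregation + decoder on synthetic longitudinal pairs; Stage 3 fine-tunes
the same trainable parts on real pairs. All stages minimize the soft Dice
loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e-5 on the lesion-class
probability, with Adam at learning rate 1e-4 and β₁ = 0.9 ("momentum 0.9"
is read as Adam's β₁; Adam has no classical momentum). Inference averages
the per-voxel class probabilities of an ensemble of networks trained on
different train/validation splits over sliding windows (stride = half
patch, uniform overlap averaging) and takes the arg-max class; an exact
0.5 tie resolves to background.

The networks run on a small reverse-mode autodiff engine written on numpy
(3D convolution, instance norm, ReLU, 2× average pooling, nearest-neighbour
2× upsampling, channel concatenation, softmax, Dice/MSE losses, Adam).
Nearest-neighbour upsampling was chosen over trilinear in the decoder for
its exact, cheap gradients; at the network widths used here the difference
is immaterial. Gradients are verified against central finite differences
in the test suite. Everything is deterministic given a seed.

## Synthetic longitudinal pairs

From one FLAIR volume and its lesion mask, `synthesize_pair` fabricates a
two-time-point sample with a known new-lesion mask in three steps:

1. shared geometric augmentation (axis flips, in-plane quarter-turns) and
   duplication; at the end, each copy receives an *independent* draw of the
   quality augmentation (below), so the pair differs the way two real
   acquisitions would;
2. per-lesion fates: each 26-connected component is kept in both
   time-points, inpainted out of one, or out of both, drawn i.i.d. with
   probabilities (keep_both 0.4, remove_tp1 0.3, remove_tp2 0.15,
   remove_both 0.15). A lesion removed from tp1 only is by construction a
   *new* lesion. A lesion removed from tp2 only is a *disappearing* lesion:
   generated but never labelled, since the detection target is new lesions.
3. 0–3 synthetic lesions placed at atlas-weighted locations restricted to
   WM ∪ GM (placement weights tp2-only 0.6 / both 0.3 / tp1-only 0.1, with
   identical intensity realizations when placed in both). Only tp2-only
   lesions join the new-lesion mask. A generated blob that would touch an
   existing lesion is dropped rather than merged, which keeps the
   bookkeeping exact: the new-lesion mask always equals (components with
   fate remove_tp1) ∪ (tp2-only generated supports).

The fate and placement probabilities are package defaults, exposed in
`SynthesisConfig`; remove_tp1 is weighted up because it is the only source
of component-derived new lesions.

Inpainting and generation are pluggable callables. Trained regression
U-Nets (1→1 inpainter; 2-channel generator: noise-filled image + lesion
mask → image) can be used, and the package ships classical fallbacks so
the pipeline runs with no trained weights: inpainting fills each
(1-voxel-dilated) lesion region with the inverse-square-distance-weighted
mean of a surrounding healthy shell plus shell-matched Gaussian noise;
generation blends a Gaussian-tapered hyperintense blob. `corrupt_for_inpainting`
and `prepare_generator_sample` build the training samples for the neural
versions (regions/lesions replaced by Gaussian draws with the image's
global mean and SD).

## Quality augmentation

Nine operators emulate MRI acquisition variability: Gaussian blur (SD
uniform in [0.5, 1.75] voxels), unsharp-mask edge enhancement, an axial
mean filter of length sz ∈ {2, 3, 4} (thick-slice emulation), anisotropic
downsample/upsample along one axis (factor in [1.5, 4], cubic B-spline
resampling), additive Gaussian noise (SD in [0.02, 0.1] of the normalized
intensity scale), a multiplicative polynomial bias field
`exp(Σ c_k φ_k(x))` over coordinates scaled to [−1, 1], and three k-space
artifacts: motion (k-space composed from FFTs of affinely transformed
copies — rotations in [−5, 5]°, translations in [−4, 4] mm — partitioned
into contiguous blocks along the phase-encoding axis), spikes (added
high-magnitude k-space points; defaults 5–20 % of the DC magnitude), and
ghosting (every 2nd–4th k-space plane along one axis attenuated by
20–80 %, sparing the DC plane so mean intensity is preserved).

Choices the operator definitions leave open, fixed here: blur SD is in
voxel units; convolution boundaries are reflective (no intensity drain at
the brain edge); when several operators fire the order is spatial-domain →
k-space → noise, mimicking the acquisition chain; each operator fires
independently with default probability 1/9 and at most 3 operators apply
per draw; spike/ghost ranges were set to be visible but sub-destructive
and are config-exposed. Every draw is logged with exact parameters;
replaying a log reproduces the output bitwise. Each operator has an
identity-limit setting (zero SD, zero amount, factor 1, zero coefficients,
zero transforms, zero attenuation) asserted by the tests.

## Phantom data

The phantom emulates only the statistical structure the pipeline assumes:
a nested-ellipsoid head (background / CSF / GM / WM), FLAIR-like
intensities (CSF ≈ 0.15, WM ≈ 0.5, GM ≈ 0.6, additive Gaussian noise
SD 0.03), lesions as super-Gaussian-tapered ellipsoids (`exp(−(r/R)⁴)`,
binarized at taper ≥ 0.3 so masks have soft partial-volume rims that
exercise the evaluator's partial-overlap branches), placed fully inside WM
with enforced component separation so connected-component counts are
exact, and a WM-weighted, center-emphasized lesion-probability atlas
normalized to integrate to 1. Default grid 96³ at 1 mm isotropic (tests
use 48³). It does **not** model anatomy, multi-contrast appearance,
scanner noise statistics, registration error, or lesion growth; passing
tests demonstrate the pipeline's mechanics and trainability, not clinical
performance.

## Evaluation

Voxel-wise: Dice = 2TP/((TP+FN)+(TP+FP)), PPV = TP/(TP+FP),
TPR = TP/(TP+FN). Zero denominators are reported as undefined flags
rather than zeros (Dice of two empty masks is 1); cohort means exclude
flagged cases and report the exclusion count.

Lesion-wise, after removing components smaller than 3 mm³ from both masks:
a ground-truth lesion is detected if ≥ 10 % of it is covered (lesion
sensitivity S_L); a predicted lesion is a true positive if ≥ 65 % of it
overlaps ground truth and ≤ 70 % of it lies outside (lesion PPV, P_L);
LesF1 = 2·S_L·P_L/(S_L+P_L). All thresholds are inclusive ("at least" /
"no more than"): a component of exactly 3 mm³ survives and an overlap
exactly at a threshold passes. Note that a lesion ≥ 65 % inside is
automatically ≤ 35 % outside, so the 70 % clause cannot reject on its own;
it is implemented literally anyway and both thresholds are configurable,
because reference analyzers differ in bookkeeping detail. Matching is
per-component by any-overlap; no one-to-one assignment is made, so one
prediction spanning two ground-truth lesions can detect both. The
aggregate score is (Dice + LesF1)/2. Cohort comparisons use the paired
two-sided Wilcoxon signed-rank test (zero differences dropped,
significance at p < 0.05; the all-zero case is reported as degenerate with
p = 1). Connectivity is 26-connected everywhere.

## Desk-scale problem sizes

The end-to-end workflow (`workflows.scaled_end_to_end`) uses 48³ phantoms,
a 2-level base-8 network, 12³ training patches, 12 single time-point
phantoms, 40 synthetic pairs, a 3-network stage-2 ensemble
(150 / 250 steps, batch 4), and 10 held-out easy pairs (1 baseline + 2 new
lesions, radius 2.5–4 mm, contrast 0.5, noise SD 0.02), predicted with 32³
windows at stride 16. For these short schedules the learning rate is
raised to 2e-3; the full-scale default remains 1e-4. These sizes are the
package's reference configuration for demonstrating that stage-2
synthetic pretraining alone yields a working detector; they are not tuned
per run.

## Known limitations

- The classical inpainting/generation fallbacks are simple local models;
  they are statistically matched to the phantom but would be visibly
  synthetic on real FLAIR.
- Motion simulation uses nominal masks: the lesion mask is not moved with
  the k-space transforms, as is conventional for this augmentation.
- Disappearing lesions are generated but not labelled or evaluated.
- No deformable registration error, lesion growth/shrinkage, or
  multi-modal input is modeled.
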