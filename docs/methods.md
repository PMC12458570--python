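# Methods

This note documents the models and procedures implemented in `lucid`, the
assumptions behind them, the numerical choices that were genuinely open, and
what the synthetic benchmark does and does not establish.

## Problem setting

A digital otoscope records a short video of the ear canal; a clinician (or a
downstream diagnostic model) needs one or a few still frames showing the
tympanic membrane (eardrum) clearly.  Frames are typically unusable for one
of three reasons: the eardrum is only partially in view or absent, it covers
too small a fraction of the image, or the frame is blurred / focused away
from the eardrum.  The package scores every frame on these three axes and
fuses the scores by weighted rank.

## Per-frame scores

**Eardrum view score.**  A 3-class classifier assigns probabilities that a
frame shows no, a partial, or the full eardrum.  Each class carries an
"eardrum area score" (0, 0.5, 1) and the view score is the expectation

    S_edv = P_full · 1 + P_partial · 0.5 + P_non · 0  ∈ [0, 1].

Probabilities are the softmax of the classifier logits.  (The alternative
reading — using raw logits — would not bound S_edv or make it an
expectation; softmax is the deliberate choice here.)  Class order is fixed
as (none, partial, full) in every array and serialized output.

**Eardrum coverage score.**  Pixel labels are too expensive to collect, so
the eardrum is segmented weakly, from image-level presence labels only.
Grad-CAM on a binary eardrum/background classifier localizes the evidence;
*adversarial climbing* then perturbs the input image for `T` iterations
along the gradient of

    L = y_fg − y_bg − λ_restrict · ‖M ⊙ (CAM(x_t) − CAM(x_0))‖₁,
    M = 1[CAM(x_{t−1}) > τ],

raising the foreground logit while the masked ℓ₁ term keeps already-strong
activations from saturating.  The per-iteration maps are summed over the
trajectory and normalized.  The binary refinement subtracts a weighted
background map,

    BC-AdvCAM(x) = AdvCAM_fg(x) − λ_bc · AdvCAM_bg(x),

clamped at zero — structures that activate the background head (canal wall,
wax-like texture) are suppressed from the eardrum map.  The map is
thresholded at a fraction τ of its maximum and the coverage score is
S_edc = eardrum pixels / all frame pixels (the *whole* frame, not the FOV
interior, so a zoomed-in eardrum scores higher than a distant one).

**Clarity score.**  Otoscope frames defeat FFT/wavelet blur detectors (dark
surround, low variance, low-frequency energy).  Instead:

1. *Field of view.*  Candidate circles from a Hough transform on Canny
   edges (quantile thresholds, hence invariant to global intensity scaling)
   are each scored by the lightness change ΔL = |mean interior lightness −
   mean lightness of a width-Δr exterior annulus|; the highest-ΔL circle is
   the FOV.  The winning candidate's *center* is then refined over its ±2 px
   neighborhood with the same ΔL objective.  The *radius* is deliberately
   kept from the Hough accumulator: the accumulator peak follows the
   edge-gradient maximum, which stays on the rim under blur, whereas the
   annulus-contrast objective drifts outward on soft rims (the annulus
   prefers to be fully dark).
2. *Blur score.*  Signed 3×3 Sobel responses (both orientations pooled)
   are collected strictly inside the FOV; sharp frames put mass in the tails
   of this signed edge-energy distribution, blurred frames concentrate it at
   zero.  A 2-component Gaussian mixture is fitted by EM and the wider
   component's standard deviation σ_max measures the tail.  The score is
   S_bl = σ_max / (C_p + ϵ) with C_p the RMS contrast (intensity standard
   deviation) inside the FOV and ϵ = 10⁻⁶.
3. *Focus score.*  The sharpness map S(x,y) = (∇²I_G)² (Laplacian of the
   σ_smooth-Gaussian-smoothed intensity) is maximized over the image;
   S_F = r_FOV − dist(focus point, FOV center), clamped below at zero so an
   out-of-FOV focus cannot go negative and outrank in-FOV blur.
4. The composite clarity score is S_blf = S_bl × S_F.

**Informative score.**  Each raw score is ranked across the video's frames
(rank 1 = best; ties take the average of tied positions) and fused:

    S_I = 0.4 · Rank(S_edv) + 0.2 · Rank(S_edc) + 0.4 · Rank(S_blf).

Smaller S_I = more informative.  Top-k selection sorts ascending S_I, ties
broken by larger S_edv, then smaller frame index — a deterministic total
order.  The weights are configurable and must sum to 1.

## The classifier

The view and CAM models are one architecture: a 3-block CNN (3×3 convs with
channels 16/32/32, ReLU, two 2×2 max-pools, global average pooling, linear
head) implemented in numpy with hand-written backpropagation.  The CAM
stages need the gradient of a class logit w.r.t. the last conv features and
the gradient of the climbing loss w.r.t. the *input image*; writing the
network explicitly makes both exact and keeps the whole pipeline
deterministic for a fixed seed.  Inputs are resized to 64×64 and kept in
[0, 1].  Training: Adam (lr 10⁻³), batch 32, cross-entropy, best checkpoint
by validation accuracy; because a small randomly initialized CNN occasionally
draws a poor optimisation run, training restarts up to three times with
derived seeds and keeps the best-on-validation model (skipping remaining
restarts once validation accuracy reaches 0.97) — still fully deterministic
for a given seed.  The binary CAM model trains 30 epochs, the 3-class view
model 25.  A deeper pretrained backbone with 224×224 inputs is
the natural production substitution; the score formulas, not the backbone,
are the contract, and the backbone is pluggable behind
`ConvNetClassifier`'s interface.

## Numerical and design choices

- **CAM normalization.**  Maps are min-max normalized to [0, 1] after
  upsampling, before thresholding and before the BC subtraction.  Without a
  common scale the foreground−background subtraction is meaningless.
- **Stop-gradients in the restriction term.**  Inside the climbing loss the
  Grad-CAM channel weights and the map-normalization constant are treated as
  constants; the gradient flows through the feature maps only.  Full
  second-order differentiation through the channel-weight gradients would
  require an autodiff engine for marginal benefit; the stop-gradient form is
  the standard practical approximation.
- **Climbing defaults.**  T = 30 iterations, λ_restrict = 7, τ = 0.5,
  λ_bc = 1.  The step size ε = 0.02 (on [0, 1] intensities) is calibrated to
  this package's small CNN: with 30 raw-gradient steps it raises the target
  logit on essentially every eardrum-present test image, where a smaller
  step leaves the restriction term dominant on a minority of images.  All
  five are config keys.
- **GMM initialization.**  Edge-energy samples are near-zero-mean *scale*
  mixtures.  k-means initialization splits them into left/right clusters and
  EM stalls there, badly underestimating σ_max.  Both components are instead
  initialized at the sample median with variances taken from the inner and
  outer halves of the absolute deviations; EM (≤200 iterations, tol 10⁻⁶)
  then separates the components by variance.  An all-identical sample is
  reported as σ_max = 0 with a degenerate-fit flag.
- **Grayscale** is BT.601 luma (0.299, 0.587, 0.114), the common video
  convention; frames are floats in [0, 1] from decode onward.
- **Coordinates** are 0-based (x, y) = (column, row), origin top-left,
  everywhere.
- **Focus tie-break:** a flat sharpness map returns (0, 0) (smallest row,
  then column) — deterministic, and such frames score S_F near r_FOV only if
  the FOV happens to sit at the origin, which the FOV-fit geometry excludes.
- **Failure handling.**  A frame with no detectable FOV circle shows no
  otoscope content; it is kept in the score table with all three raw scores
  set to 0 rather than dropped, so the rank denominators stay consistent
  across axes.  Because softmax gives every scorable frame S_edv > 0, a
  no-FOV frame can never win selection over a valid frame.
- **Video containers.**  Lossless multi-page TIFF stacks and directories of
  PNG stills are the supported containers (plus single stills).  Lossless
  round-trips make pixel-exact determinism testable; camera-codec decoding
  can be layered onto `read_frames` without touching any scoring code.

## Synthetic data: what it emulates and what it does not

The generator renders the otoscope imaging regime geometrically: a dark
surround, a bright band-limited-noise-textured circular FOV, an optional
lighter textured "eardrum" disk (fully inside the FOV, clipped by its rim,
or absent — the three view classes; partial placement puts 25–75% of the
disk outside), Gaussian blur of controllable σ, an optional blur-exempt
5-px-checker focus patch (radius 12 px) marking the sharpest point, and
sensor noise.  Ground truth (masks, FOV circle, visibility, blur, focus
location) is exact by construction.  Rendering is bit-deterministic per
spec + seed.

Benchmark sizes were chosen to exercise every stage at desk scale: 200
training / 40 test images for the binary CAM benchmark, 300 for the view
classifier, 64×64 classifier inputs, 240×240 detection frames, 20 ten-frame
videos (160×160) for end-to-end selection.

The binary benchmark's presence class mixes fully visible and rim-clipped
eardrums (the binary task merges the partial and full view classes).  This
matters beyond fidelity to the labeling scheme: if every present image shows
a large centered drum, some training runs reach high accuracy through
*negative* evidence — channels that detect canal-wall texture with negative
head weights — and the foreground CAM degenerates to a flat map.  Requiring
the model to flag small clipped drums blocks that shortcut and keeps the
class evidence, hence the activation map, on the drum pixels.

What passing these tests shows: the formulas are implemented exactly; the
detectors recover known geometry within stated pixel tolerances; the blur
score is strictly monotone in true blur; the BC refinement genuinely
improves IoU over plain Grad-CAM and climbing over neither; the fused rank
score recovers a frame designed to dominate all three axes.  What it does
*not* show: performance on clinical otoscopy — real frames have specular
highlights, wax, vignetting, motion blur and anatomy the generator does not
model, and the small CNN is far from a production backbone.  Two observed
consequences of the synthetic regime: Grad-CAM from this GAP-CNN tends to
*over*-cover the eardrum disk, so adversarial climbing concentrates rather
than expands the mask (while still improving IoU) — on deep networks and
complex objects, where CAMs under-cover, climbing works by expansion; and
because the synthetic drum is easy to localize, the three CAM variants
produce nearly identical maps on well-trained runs, so their mean-IoU
margins are far smaller (∼10⁻³–10⁻²) than on clinical imagery, where the
background structures that BC-AdvCAM suppresses actually occur.

## Known limitations

- Frames focused on a non-eardrum structure inside the FOV can still score
  well: the coverage model may follow the focused structure, and the clarity
  score rewards any central sharpness.
- The blur score's monotonicity is demonstrated on static texture; strong
  specular highlights would inflate both σ_max and the contrast C_p in ways
  the synthetic benchmark does not probe.
- Rank fusion amplifies tiny raw-score differences between near-tied frames
  into full rank gaps; with many near-identical good frames the top-1 choice
  among them is effectively arbitrary (top-k mitigates this).
- No temporal smoothing: each frame is scored independently.
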