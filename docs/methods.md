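# Methods

## Problem and model

Fetal head circumference (HC) is measured on the trans-thalamic
ultrasound plane, where the skull cross-section is well approximated by
an ellipse.  `fetalhc` treats the measurement as one-stage, anchor-free
*rotated-ellipse detection*: a convolutional encoder–decoder looks at
the image once and directly emits the five ellipse parameters
`(cx, cy, a, b, θ)` plus a confidence; HC then follows in closed form
from the semi-axes and the pixel size, with no segmentation, contour
extraction or ellipse-fitting stage anywhere in the pipeline.

An oriented ellipse is parameterized by its center in pixels (x right,
y down, 0-based pixel centers), *semi*-axes `a ≥ b ≥ 0` in pixels, and
an angle `θ ∈ [0°, 180°)` between the short axis and the vertical.  In
the image frame this equals the angle of the major axis from the
horizontal; a single conversion function owns that identity and all
trigonometric code works with the major-axis angle.

### Detection heads (stride 4)

The network downsamples to 1/32 and decodes back to 1/4 of the input
(bilinear ×2 upsampling → 3×3 refinement → skip concatenation → 1×1
fusion).  Four heads read the stride-4 feature map:

- **Center heatmap** — each ground-truth ellipse is splatted as an
  anisotropic Gaussian centered on its axis-aligned enclosing box
  `(bx, by, w, h)` with `σx = w/(6s)`, `σy = h/(6s)` in grid units, so
  the ±3σ extent matches the box.  The integer center cell is clamped
  to exactly 1.  Trained with the penalty-reduced ("variant") focal
  loss with `α = 2`, `β = 4`, normalized by the object count.
- **Center offset** — the sub-pixel remainder `(cx/s − ⌊cx/s⌋, …)`,
  supervised with smooth-L1 at the center cell; makes center recovery
  exact despite the stride.
- **Semi-axes** — regressed in input-image pixels (not stride units;
  this keeps the HC formula free of stride bookkeeping) through a
  softplus so they are strictly positive.
- **Angle** — soft-stagewise regression (SSR), below.

### Soft-stagewise angle regression

The angle is decoded from a three-stage soft classification with bin
counts `(S₁, S₂, S₃) = (18, 10, 10)` over `V = 180°`, giving nominal
bin widths 10°, 1° and 0.1°:

    θ = Σₖ Σᵢ pᵢ⁽ᵏ⁾ · (i + ηᵢ⁽ᵏ⁾) · V / Πⱼ≤ₖ sⱼ*,   sⱼ* = sⱼ(1 + Δⱼ)

`p⁽ᵏ⁾` are per-stage softmax probabilities and `η` per-bin shifts, both
read per pixel at the center cell; `Δ` is a per-image vector produced
from globally pooled bottleneck features.  `Δ` and `η` are squashed by
tanh so bins cannot invert order (Δ is additionally scaled by 0.999 so
`1 + Δ` stays strictly positive under float32 tanh saturation).
Supervision is only through smooth-L1 on the decoded angle — gradients
flow through the decode — and the residual is taken as the minimal
circular difference `min(|dθ|, 180 − |dθ|)`, removing the artificial
discontinuity at 0°/180° (a config switch restores the plain linear
difference).  With `use_ssr=False` the dynamic-range terms are frozen at
zero and the head degenerates to fixed-bin expectation regression, which
serves as the "direct angle regression" ablation arm.

### Gaussian KLD regression loss

Small angle or center errors can produce large rotated-overlap changes,
and rotated IOU itself is awkward to compute and to differentiate.  The
coupling loss therefore embeds each oriented ellipse as a 2-D Gaussian
with mean at the center and covariance `Σ = M²`,
`M = R(ψ)·diag(a, b)·R(ψ)ᵀ` (so `Σ` has eigenvalues `a², b²` along the
ellipse axes and `det M = a·b`), and penalizes the Kullback–Leibler
divergence of the predicted Gaussian from the target:

    D = ½(μp−μt)ᵀΣt⁻¹(μp−μt) + ½Tr(Σt⁻¹Σp) + ½ln(|Σt|/|Σp|) − 1
    L_kld = 1 − 1/(1 + ln(D + 1))          (natural log, L_kld ∈ [0, 1))

Because the divergence mixes center, axes and angle in one quadratic
form, optimizing one parameter re-weights the gradients of the others —
the mechanism that improves joint recovery of the ellipse pose.  The
2×2 algebra is written in closed form (scalar covariance entries), so
the loss is exactly differentiable through the package's autodiff.

### Total objective

    L = w_h·L_heat + w_o·L_offset + w_a·L_axes + w_θ·L_angle + w_k·L_kld

All terms are means over ground-truth objects; negatives contribute only
to the heatmap term (with the object count floored at 1).  The axes
term is included in the total by default (`include_axes_in_total`), and
`use_kld` / `use_ssr` switch the ablation variants.  Default weights
are `w_h = w_o = w_k = 1` and `w_a = w_θ = 0.05`: the axes and angle
residuals are in pixels and degrees (O(10)–O(40) early in training) and
at desk scale they otherwise drown the O(1) heatmap loss in the shared
trunk — in controlled runs the unweighted sum reached ~10% detection in
the same budget where heatmap-only training reached >90% correct peaks.
Down-weighting size terms is the usual convention for center-point
detectors; setting every weight to 1.0 restores the plain unweighted
sum.

### Inference

Detection cells are 3×3 local maxima of the heatmap above a score
threshold (default 0.3, a conventional choice for center-point
detectors, recorded in config — not a value taken from any reference);
`max_peaks` defaults to 1 because a standard plane contains one head.
The center is `(ix + ox)·s`, the axes are read at the cell and sorted so
`a ≥ b`, the angle is the SSR decode wrapped into [0°, 180°), and
`HC = π[3(a+b) − √((3a+b)(a+3b))]` (Ramanujan's approximation, accurate
to ≪0.5% for aspect ratios down to b/a = 0.2) after converting the axes
to millimetres with the pixel size.

## Network and training infrastructure

The model runs on a small reverse-mode autodiff engine written on numpy
(im2col convolutions, batch normalization, bilinear ×2 upsampling,
multi-head self-attention with factorized 2-D positional embeddings
added to the attention logits, softmax/softplus/tanh heads, scatter-add
gathers at ground-truth cells).  Gradients of every operation are
verified against finite differences in the test suite.  Two presets are
provided: `tiny` (96×96 input, base width 24, 2 attention heads, ~0.4 M
parameters — the configuration every test and the acceptance study use)
and `full` (544×800, base width 64, deformable stages requested; full
scale, not exercised here).  Requesting deformable convolution falls
back to standard convolution with a logged warning — no deformable
operator is available in this stack.

The focal loss in the training path is evaluated from pre-sigmoid
logits using `log σ(z) = −softplus(−z)`: the probability-space form
(kept as the reference implementation) loses its gradient permanently
once a float32 sigmoid saturates to exactly 0 or 1 under ε-clipping.

Optimization defaults to Adam (lr 1e-3, global gradient-norm clip 50,
weight decay 1e-4, batch 4, 50-step linear warmup, lr/10 at epoch 8 of
10).  Momentum SGD (lr 0.005, momentum 0.9) is implemented and
selectable — the conventional choice for full-scale detector training —
but at desk scale
it cannot equilibrate the very differently scaled heads within a
10-epoch budget: the SSR decode produces logit gradients roughly two
orders of magnitude larger than the heatmap head's, which saturates the
stage softmaxes under momentum.  The warmup matters: without it a
fraction of seeds collapse early into the all-background minimum of the
focal loss and never recover.

## Synthetic phantoms

The generator emulates the salient features of trans-thalamic
ultrasound: a bright anti-aliased elliptical ring (Gaussian
cross-section, default σ half-thickness 1.5 px) at a random pose with
aspect ratio b/a ∈ [0.6, 1.0]; contiguous arc dropouts (by arc length,
default 20% of the perimeter, mimicking acoustic shadowing); a smooth
low-frequency background field; and unit-mean gamma multiplicative
speckle (default sd 0.25), the standard first-order model of B-mode
texture.  The pixel size is drawn from 0.052–0.6 mm, the documented
clinical range, so HC values in mm span a realistic spread.  The
generating ellipse is the exact annotation, and every sample is
reproducible from its seed.

Negative images are built by the two constructions used for balancing
positive-only datasets: removing the ring and refilling it from
surrounding-background statistics, and random crops accepted only when
their axis-aligned IOU with the ground-truth box is below 0.3.

The phantoms deliberately omit real-ultrasound structure: no
point-spread function or attenuation, no other anatomy (choroid plexus,
midline echo, cavum), no probe-dependent fan geometry, no calipers or
annotation burn-ins.  Passing the recovery study therefore shows that
the detector, losses and codecs are implemented coherently and can be
learned end-to-end — not that the trained weights transfer to clinical
images.

Augmentation reproduces the standard discrete grids — rotation ±30° in
10° steps, scaling 0.85–1.15 in 0.05 steps, gamma 0.5–1.5 in 0.1 steps,
random horizontal flip — with annotations transformed in lockstep (the
rotation handedness is pinned by a mask-overlay test, not assumed; HC in
mm is invariant under scaling because the pixel size co-scales).  Both
one-op-at-a-time and full-product expansion modes exist; the recovery
study below does not use augmentation.

## Evaluation

HC agreement is reported as MAE and signed ME (pred − gt, mm) with
sample standard deviations (`ddof=1`, recorded in config).  Detection
quality is average precision with greedy score-descending matching at
rotated-ellipse IOU ≥ 0.5 — overlap comes from a rasterized membership
oracle (default 4 cells/pixel; doubling the resolution moves values by
<0.005) because rotated-ellipse overlap has no practical closed form —
with all-point interpolation of the precision–recall curve.  The greedy
matcher is tested against exhaustive assignment enumeration.
Bland–Altman analysis reports the mean difference and mean ± 1.96 sd
limits of agreement plus the (mean, difference) pairs for plotting.
The AP threshold and interpolation are package conventions; AP values
here are not claimed comparable to any externally reported number.

## The scaled-down recovery study

`scripts/acceptance.py` (and the corresponding tests) runs the whole
pipeline at desk scale: 270 positive + 30 negative training phantoms
and 50 held-out positives at 96×96 (gap fraction 0.2, speckle 0.25),
tiny preset, 10 epochs — about 2 minutes on one CPU core.  Problem
sizes were chosen as the smallest at which detection-rate and HC-error
statistics over 50 test images are meaningful.  Typical results across
seeds: detection rate 88–100% at score threshold 0.3, median HC relative
error 5–10%, AP(0.5) 0.84–0.98, Bland–Altman mean difference within a
few mm; enabling the KLD term consistently does not worsen (and usually
improves) the median HC error, matching the qualitative role the loss
is designed for.  The angle remains the hardest parameter at this
budget (median error ~30°; near-circular phantoms make it partially
unidentifiable), which bounds AP but barely affects HC, which depends
only on the semi-axes.

## Numerical choices and edge cases

- Degenerate ellipses (`b = 0`) are rejected by the Gaussian embedding
  (singular covariance) and by IOU (zero area); `head_circumference`
  accepts `b = 0` and returns the Ramanujan value, which is ~0.4% below
  the true degenerate perimeter 4a.
- Heatmap splats clamp σ at 1e-3 grid units; a box center outside the
  grid yields an all-zero map with a warning.
- KLD intermediate determinants are floored at 1e-12 and the divergence
  clipped at 0 before the bounded transform.
- Peak ties in the 3×3 maximum filter keep all tied cells and resolve
  by score order, then truncation.
- Checkpoints (.npz) store every parameter and batch-norm buffer plus a
  JSON echo of the model/SSR configs; loading rebuilds the model from
  the echo and refuses mismatched state layouts.

## Known limitations

- The `full`-scale preset is provided but untrained and unbenchmarked
  here; nothing in this repository constitutes a full-scale benchmark,
  and the phantom study is not a clinical validation.
- Attention memory grows with the fourth power of the spatial side at
  stride 4, so `use_mhsa` at full image sizes requires the full-scale
  environment the full-scale configuration assumes.
- One head per image is the default decoding assumption (standard
  planes); `max_peaks` generalizes it but multi-object phantoms are not
  generated.
- The HC18 adapter fits ellipses to contour annotation images by
  algebraic least squares; it is an input convenience, exercised only
  on synthetic contours in the tests.
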