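# Methods

This note documents the models, numerical choices and limitations behind
`vdmnet`: a retinal-vessel segmentation toolkit for OCTA en-face
angiograms built around four components — fast low-rank multi-head
self-attention (FastMHSA), vessel dynamic convolution (VDConv),
multi-scale fusion (MSF) and the weighted asymmetric focal Tversky loss
(WAFT) — plus a connectivity-aware evaluation suite and a synthetic data
generator.

## The segmentation problem

En-face OCTA angiograms show the retinal microvasculature as sparse,
thin, curved, bifurcating and crossing bright structures over a speckled
low-contrast background. Two properties dominate the design space:

* **Class imbalance.** Vessels occupy a small minority of pixels
  (roughly 20% in our synthetic data, less in clinical angiograms), so
  symmetric pixel losses under-train the vessel class.
* **Topology matters.** A segmentation that loses 2% of pixels by
  breaking the tree into fragments is clinically much worse than one
  that loses 2% by uniform thinning. Pure overlap metrics cannot tell
  these apart; the CAL and LCC metrics can.

## Network

The network is a U-shaped encoder/decoder. Per encoder level:
BasicBlock → (VesselTransformerEncoder at the deepest
`transformer_levels` levels) → (MSF) → skip → 2×2 max-pool; a BasicBlock
bottleneck sits below. The decoder mirrors this: at transformer levels
the skip and deeper stream are fused by a VesselTransformerDecoder,
elsewhere by transposed-convolution upsampling, channel concatenation
and a BasicBlock. A 1×1 convolution and sigmoid produce the probability
map.

### FastMHSA

Full self-attention on an H×W feature map costs O(n²d) with n = HW.
Because neighbouring pixels of natural images carry nearly identical
features, the keys and values are average-pooled to an h×w grid
(k = hw ≤ `reduced_size`² = 64 tokens by default) before attention:

    Attention(Q, K̄, V̄) = softmax(Q K̄ᵀ / √d) V̄,   K̄, V̄ ∈ R^{k×d}

which costs O(nkd), linear in n for fixed k. With k = n this is exactly
full attention — the oracle test in the suite exploits that identity.
The encoder block wraps the attention with a depthwise-separable input
convolution, a 1×1 Q/K/V projection and a 3×3 depthwise-separable output
refinement. The decoder block takes two streams; we upsample the
low-resolution stream (nearest-neighbour), concatenate with the skip,
and draw keys/values from the combined features while queries come from
the skip stream alone — concatenation rather than addition was an open
wiring choice, chosen because it preserves both streams' information and
lets the input convolution learn the mixing. The pooled grid size is the
largest divisor of the spatial size not exceeding the target (so 304×304
inputs pool to 8×8 at power-of-two-free levels without remainder).

A stochastic kernel-feature approximation of the attention matrix is
sometimes used to compensate sub-sampling loss; we implement the
deterministic low-rank form above as the normative path and did not add
a random-feature variant, keeping every forward pass reproducible.

### VDConv

Vessel dynamic convolution adapts the sampling geometry and the kernel
content to the input:

1. **Offset prediction.** `O = tanh(GN(Conv_offset(x))) ∈ R^{2K×H×W}`,
   K = 9 taps of a 3×3 grid; tanh bounds normalised offsets to [−1, 1].
   The GroupNorm uses the largest group count ≤ 8 dividing 2K (6 groups
   at K = 9, since 18 is not divisible by 8).
2. **Deformable sampling.** Each tap samples at its regular position
   plus `offset_scale` × offset (default 2 px — the normalisation fixes
   the shape of the field, not its pixel scale, so the scale is an
   explicit knob), with bilinear interpolation and zero padding outside
   the image. With a zero offset field this reduces exactly to a
   standard convolution (second oracle test).
3. **Multi-expert fusion.** N = 4 expert kernel banks (grouped
   convolutions over the sampled features, sharing one offset field)
   are combined as Z = Σ αₙ Yₙ where α = softmax of a gate computed
   from globally average-pooled features — one weight vector per image,
   not per pixel, because the fusion is a single convex combination of
   expert outputs.

### MSF and BasicBlock

MSF runs four parallel branches — 1×1; 3×3 (pad 1); 3×3 dilation 2
(pad 2); 3×3 dilation 3 (pad 3) — each with BatchNorm + LeakyReLU,
concatenates them, compresses back with a 1×1 convolution and adds the
input. The dilated branches see 5×5 and 7×7 neighbourhoods at 3×3 cost,
capturing elongated vessel context without losing resolution.
BasicBlock is (3×3 conv → BN → LeakyReLU) ×2 with a residual (1×1
projection on channel change). LeakyReLU slope is 0.01 everywhere.

### Architecture defaults

The published description leaves level counts, widths and heads open.
Defaults: 4 levels, base 32 channels doubling per level, transformers at
the 2 deepest levels, 4 heads, 4 experts, MLP expansion ratio 4 with a
residual around each transformer sub-block (the standard arrangement
where the block description lists components without wiring). All are
YAML config keys. The tests and examples use a reduced instantiation
(3 levels, 8 base channels, 2 heads, 2 experts, 64×64 images) so the
whole suite runs in minutes on one CPU; the assembly is size-agnostic
and handles the native 304×304 angiogram resolution.

## Losses

All losses act on soft sigmoid probabilities through soft confusion
masses tp = Σ p·g, fn = Σ (1−p)·g, fp = Σ p·(1−g) (background uses
1−p, 1−g). The Tversky index is

    TI = (TP + ε) / (TP + δ·FN + (1−δ)·FP + ε)

and the WAFT loss

    L = α · (1 − TI_bg) + β · (1 − TI_fg)^(1−γ)

with α = 0.2, β = 0.8 (foreground-weighted), δ = 0.7 (missed vessels
cost more than false alarms; the publication prioritises FN reduction
but prints no value), γ = 0.25 and ε = 1e−6. The printed focal term is
typographically ambiguous between (1−TI)·(1−TI)^−γ and a free-standing
exponent; we implement the product reading, i.e. exponent 1−γ ∈ (0, 1),
which magnifies the foreground term as TI_fg → 1 relative to the linear
loss. Because d/dx x^(1−γ) diverges at 0, the complement is floored at ε
before exponentiation; a perfect prediction therefore scores ≈ β·ε^(1−γ)
(∼1e−5) rather than exactly 0. Useful identities, all under test:
δ = 0.5 makes TI the soft Dice of the same counts; γ = 0 collapses WAFT
to the plain weighted asymmetric Tversky loss; AFT = WAFT with α = 0,
β = 1. Comparison losses use their textbook forms: Dice loss
(1 − soft Dice), pixel cross-entropy with 1e−7 clipping, plain Tversky,
unweighted focal with γ_focal = 2.

## Metrics

Dice, Jaccard, balanced accuracy and recall come from the pixel
confusion table. Degenerate conventions are explicit: exact agreement on
an all-background image scores 1; an empty ground truth where a formula
divides by a ground-truth count raises an error; BACC reports only the
defined half when a class is absent.

The CAL metric is the product of three factors in [0, 1], scaled to
[0, 100]:

* C = 1 − min(1, |#comp(GT) − #comp(S)| / #px(GT)) — fragmentation.
  The published rendering omits the absolute value, which would push C
  above 1 for over-fragmented ground truth; we keep |·| as in the
  original formulation of the metric.
* A = |(δ₁S ∩ GT) ∪ (S ∩ δ₁GT)| / |S ∪ GT| — overlap with 1 px
  dilation tolerance.
* L = |(φS ∩ δ₁GT) ∪ (δ₁S ∩ φGT)| / |φS ∪ φGT| — skeleton
  (centerline) coincidence, φ = skeletonisation.

Connected components use 8-connectivity (thin diagonal vessels would
fragment under 4-connectivity); φ is standard two-dimensional thinning
(`skimage.morphology.skeletonize`); the radius-1 "disc" is the
4-connected cross, swappable for a 3×3 square by passing a different
radius/footprint. LCC compares the pixel lengths of the largest
connected skeleton components, 100·(1 − min(1, |ℓ_S − ℓ_GT| / ℓ_GT));
the defining formula yields [0, 1] but the accompanying prose speaks of
values near 100, so the package reports the 0–100 scale for both CAL
and LCC. On small masks the A and L factors are verified against a
literal per-pixel brute-force evaluation of the set expressions.

## Training recipe

Batch size 1 for 100 epochs (defaults), Adam with β₁ = 0.9 (the recipe's
"momentum"; β₂ = 0.999), L2 weight decay 0.001 added to the gradient,
and a polynomial schedule `lr = base_lr·(1 − iter/max_iter)^power`
stepped per iteration. `base_lr` and `power` are unprinted in the
source description; defaults 1e−3 and 0.9 (the near-universal poly
power). Augmentation: independent 50% horizontal/vertical flips and a
uniform rotation in [−10°, 10°] (bilinear image / nearest mask,
re-binarised). Validation selection uses mean validation Dice (loss
selection was the alternative; Dice matches the reported headline
metric). BatchNorm with batch size 1 normalises by per-image statistics
and keeps running averages (momentum 0.1) for eval; this is fragile in
general and the norm layers are isolated so a group-norm switch is a
local change, but the recipe specifies BN and desk-scale training with
it is stable in practice.

## Autodiff engine

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine (`vdmnet.autodiff`, `vdmnet.nn`) — float64
numpy arrays on a dynamic tape, with hand-written vector–Jacobian
products for the structured primitives (im2col convolution with groups/
dilation, 2×2 transposed convolution, max/average pooling, bilinear
deformable sampling) and composed gradients for everything else. Every
primitive is validated against central finite differences; float64 keeps
those checks at 1e−5..1e−4 tolerance. Desk-scale models (≤ ~0.3 M
parameters, 64×64 inputs) train at a few iterations per second on one
CPU.

## Synthetic data generator

The generator emulates the statistics the method targets:

* **Geometry.** Biased random walks from the image border: unit steps, a
  bounded random heading change per step (curvature 0.25 rad), a disc
  stamp whose radius tapers from the maximum (4 px) to the minimum
  (1 px) along the walk, bifurcation with probability 0.08 per step into
  a thinner child (0.7× radius and remaining length, capped at 32
  segments/tree), 3 trees per image, crossings allowed. Random walks
  with disc stamping were chosen over spline-based models as the
  simplest construction giving curvature, tapering, bifurcation and
  crossing in one mechanism.
* **Appearance.** Vessels sit `contrast` = 0.5 above a 0.25 background
  floor; multiplicative speckle `(1 + 0.2·grain)` where the grain field
  is white noise low-pass filtered to a 1.5 px correlation length
  (OCTA speckle is spatially correlated, which is what makes plain
  thresholding imperfect); Gaussian blur σ = 0.7; clip to [0, 1].
* **Determinism.** Every output is a pure function of its parameter
  record including the seed; sample i of a dataset uses base_seed + i,
  so earlier samples never change when n grows.

Calibration measurements behind the frozen defaults (20/10 seeds,
128×128): mean foreground fraction 0.24 (band 0.19–0.30, inside the
sparse regime), Otsu-threshold Dice 0.95–0.99 against the true mask.

**What passing desk-scale tests does and does not show.** The synthetic
images share the class imbalance, thin-structure geometry and correlated
speckle of OCTA angiograms, so they exercise every code path end to end
and make learning non-trivial (a global threshold does not saturate).
They lack pathology (exudates, haemorrhages), the optic disc and
projection artifacts, capillary-density variation across the field, and
annotation noise; desk-scale results here do not predict clinical
benchmark scores, and reproducing published benchmark numbers would
require the original datasets and GPU-scale training, which is out of
scope.

## Numerical and interface conventions

* Probability maps are stored as 16-bit PNG (round(p·65535)) so
  threshold sweeps survive the round trip; masks as 8-bit {0, 255},
  binarised at > 127 on read.
* Max-pool ties resolve to the first maximum; K/V pooling requires the
  reduced grid to divide the input grid.
* `predict` reflect-pads to a multiple of 2^levels and crops back, so
  arbitrary image sizes work.
* CLI exit codes: 0 success, 2 validation error, 3 runtime error.
* Checkpoints are versioned `.npz` archives of the parameter/buffer
  state plus the architecture config; loading rebuilds the model from
  the stored config.

## Known limitations

* Training is single-image mini-batches on one CPU; there is no GPU
  path, mixed precision or multi-processing. Wall-clock cost grows
  quickly beyond ~10⁶ parameters or ~256² inputs.
* BatchNorm at batch size 1 ties eval-mode behaviour to the running-
  average horizon; models evaluated very early in training can lag
  their train-mode quality.
* The expert gate is per-image; spatially varying expert mixtures are
  not expressible.
* The decoder's stream combination assumes the skip grid is a power-of-
  two multiple of the decoder grid.
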