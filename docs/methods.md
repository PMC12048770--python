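# Methods

This note records the models and procedures `vegdet` implements, the
assumptions behind them, the parameter choices that matter, and what the
synthetic experiments do and do not demonstrate.

## Detection model

The detector is an anchor-free, center-based single-stage network.  An
input image (default 640×640, values in [0,1]) passes through:

1. **Backbone** — a convolutional stem (two stride-2 3×3 convolutions)
   followed by three stages producing stride-8/16/32 feature maps.  Each
   stage is a stride-2 convolution plus a cross-stage-partial (CSP) block;
   the stride-16 and stride-32 stages additionally carry one
   window-attention block and one deformable-attention block.  The stride-8
   path stays purely convolutional: small early-stage lesions live there,
   and attention at that resolution would dominate compute without helping
   features that are inherently local.
2. **Neck** — a PAN-style pyramid (top-down fusion, then bottom-up), with
   one CSAAM block after each of the four fusion nodes.
3. **Head** — per-level 3×3 stem plus a 1×1 prediction convolution with
   `4 + 1 + K` channels: four box distances, an objectness logit, and `K`
   class logits.  The head keeps an explicit objectness branch alongside
   the anchor-free design so the loss separates into box / cls / obj terms
   with independent gains; this hybrid is deliberate and configured by the
   loss-gain triple (0.05, 0.5, 1.0).

**Box parameterization.**  A location at stride `s` with center `c`
predicts `t ∈ R⁴`; distances to the four box edges are `d = s·exp(t)`.
Encoding is the exact inverse `t = log(d/s)` (distances clamped at
`0.01 s`), so encode→decode round-trips to float accuracy for any cell
whose center lies inside the box.  During loss computation `t` is clamped
at 8 before exponentiation to keep early-training predictions finite.

**Target assignment.**  Each cell carries a square prior of side
`4 × stride`.  Cells whose prior overlaps a ground-truth box with
IoU ≥ 0.2 (the training-time IoU threshold) become positives for the
best-overlapping box, ties broken by nearest center; every box is
additionally forced onto its single highest-IoU cell so no target is ever
unmatched.

**Loss.**  `L = 0.05·L_box + 0.5·L_cls + 1.0·L_obj`, where `L_box` is the
mean of `1 − IoU` between decoded and target boxes over positives
(differentiable through the autograd core), and `L_cls`, `L_obj` are
binary cross-entropies with positive-sample weights 1.  With no positives
in a batch, `L_box = L_cls = 0` exactly.  Class-weighted training
multiplies each positive's cls term by an inverse-frequency weight
normalized to mean 1.

**Decoding.**  Per-location confidence is `sigmoid(obj)·sigmoid(cls)`;
detections below the confidence threshold (default 0.25) are dropped and
per-class greedy NMS (default IoU 0.45) keeps local maxima.  Both defaults
are conventional for single-stage detectors and exposed in the config.

## Attention modules

**CSAAM.**  Channel gate: global max-pool and average-pool give two
C-vectors; both pass through one shared two-layer MLP (bottleneck
`max(C/16, 4)`), outputs are summed and squashed:
`Yc = σ(MLP(maxpool X) + MLP(avgpool X))`.  Spatial gate: the channel-wise
max and mean planes are stacked and reduced by three 3×3 convolutions
(7×7 effective receptive field, cheaper and more nonlinear than a single
7×7) to one plane, then squashed.  The block computes
`Y = Ys(Yc⊙X)⊙(Yc⊙X) + X` with an identity residual — no learned
projection on the shortcut, since the gated term is already a double
contraction of `X` (both gates lie in (0,1)), which guarantees
`|Y − X| ≤ |X|` elementwise and makes the block safe to insert anywhere.
The MLP and the spatial stack use SiLU between layers: a smooth gate
keeps gradients alive even at the narrow bottleneck widths the reduced
models use.  With all gate weights zero, both sigmoids sit at 0.5 and the
block reduces to `Y = 1.25·X` exactly — a useful initialization-time
invariant that the tests pin down.

**Window attention.**  Multi-head self-attention inside non-overlapping
`w×w` tiles (default `w = 4`), with the cyclic-shift variant (shift
`w/2`) masking cross-boundary pairs; maps not divisible by the window are
zero-padded and the padded cells are masked out of every window's
softmax.  A single window covering the whole map is exactly global
attention, which is the oracle the tests compare against.

**Deformable attention.**  Queries come from every position of the
(layer-normed) map.  A depthwise 3×3 stride-2 convolution + GELU + 1×1
convolution maps the query map to a `⌈H/2⌉×⌈W/2⌉×2` offset field — the
sampling-grid density is half the stage extent per side.  Offsets are
tanh-squashed and scaled by `offset_range_factor` (default 0.5 in
normalized [−1,1] coordinates) and added to a uniform reference grid;
keys/values are linear projections of the map bilinearly sampled at the
deformed points.  Logits receive a continuous relative-position bias,
bilinearly interpolated from a learned 9×9-per-head table
(zero-initialized) because deformed points are non-integer.  The final
1×1 offset convolution starts at 0.01× its random init: sampling begins
near the reference grid without zeroing the gradient path into the
depthwise stage.  With the offset network zeroed the module is exactly
dense attention over grid-sampled keys/values (the test oracle).

The standalone `DATBackbone` follows the same recipe in a four-stage
pyramid: 4×4/stride-4 patch embedding, window attention (alternating
plain/shifted) in stages 1–2, alternating window/deformable blocks in
stages 3–4, channel width doubling and extent halving between stages.
Transformer blocks are pre-norm with an MLP; the MLP expansion ratio
defaults to 2 (rather than the usual 4) to hold the full detector inside
its lightweight parameter budget.

Degenerate-input note: at map extents ≤ 2 the deformable sampling grid
collapses to one point and its softmax becomes constant (gradients to the
query/key projections vanish there); the detector's default strides keep
the grids non-degenerate for inputs ≥ 128 px.

## Training procedure

Two consecutive stages with an Adam optimizer (β₁ = 0.937 doubling as the
momentum knob, β₂ = 0.999, weight decay 5e-4):

* **Stage 1 — domain initialization.**  Backbone and neck are copied from
  any shape-compatible source checkpoint; the head is freshly
  initialized.  Training is restricted to a single-crop class subset.
  Group learning rates: backbone 0.0003, neck 0.001, head 0.001.
  Deformable-attention blocks have no generic pretrained counterpart, so
  when the source checkpoint lacks them they simply remain at random
  initialization.
* **Stage 2 — diversity adaptation.**  All weights carry over (the tests
  verify bit-identical forward outputs before the first update) and the
  full label space is trained at backbone 0.0001 / neck 0.0005 /
  head 0.001, with inverse-frequency balanced sampling and class-weighted
  cls loss.

The schedule ramps each group linearly over the first 3 epochs from 0.1×
its base rate (momentum 0.8 → 0.937), then multiplies by 0.8 every 30
epochs.  A steeper one-shot 0.2 decay coefficient is exposed in the config
for short schedules.  Every parameter belongs to exactly one of the three
groups; an unattributable parameter is an error rather than a silent
default group.

## Synthetic data

The generator emulates the conditions greenhouse disease photos are taken
under: soil-toned noise background, elliptical leaves with per-leaf color
jitter, colored textured elliptical lesions stamped on the primary leaf,
optional foreground occluders, and four lighting regimes (identity,
0.45× darkening, 1.6× clipped brightening, seeded specular highlight
blobs).  Disease stage maps to the lesion-box-to-leaf area fraction:
early ≤ 5%, mid 5–40%, late 40–80% — a quantitative stand-in for the
qualitative small-spots-to-whole-plant progression of real disease.
Boxes are the exact pixel extents of the stamped lesions, and the exact
occlusion fraction applied to each lesion is recorded in its box metadata,
so the occlusion (>85%) and border-visibility (<15%) annotation filters
are testable against known truth.  Everything derives from a single seed;
identical specs give byte-identical images and annotations.

What the generator does **not** emulate: real lesion morphology or
per-pathogen texture (classes differ by palette color, not biology),
leaf venation, perspective and depth-of-field, sensor noise, or label
noise.  Passing tests therefore demonstrate that the pipeline's mechanics
— assignment, optimization, decoding, evaluation — work end to end; they
say nothing about accuracy on real greenhouse images.

## Desk-scale experiment sizes

The bundled experiments are sized for a single CPU: the end-to-end check
trains the quarter-width model (≈0.17 M parameters) on 200 scenes of 4
classes at 128 px for 10 epochs with batch 8 (≈250 updates), and reaches
held-out mAP@0.5 ≈ 0.7 in about a minute; the balanced-sampling comparison
uses a 40:4 two-class training set at 96 px over three seeds.  The easy
configuration (late-stage lesions, distinct palettes, no occlusion,
normal lighting) is intentional: these runs probe the training loop, not
appearance modeling.  At this scale balanced sampling can overshoot —
minority recall ends *above* majority recall — so the comparison asserts
the signed majority-minus-minority gap, averaged over seeds, shrinks
relative to plain sampling.

## Numerical and design choices

* Float32 throughout the network; box encode/decode helpers use float64.
* AP uses continuous all-point interpolation (precision-envelope
  integral), not 11-point sampling; mAP averages only classes with ≥ 1
  ground-truth instance; an IoU threshold of exactly 0 means any-overlap
  matching (strictly positive IoU), treating detection as classification.
* Boxes are stored 0-based half-open in memory and written 1-based
  inclusive in XML (the LabelImg dialect).  "Area at the image edge" is
  interpreted as the clipped-to-canvas area ratio of a border-touching
  box.
* Geometric augmentations map box corners through the same affine map as
  the pixels and drop boxes whose surviving area falls below 15% of the
  transformed area — the same visibility threshold as the border
  annotation filter, reused for internal consistency.  Each augmented
  copy applies one transform drawn from the seven-op pool; parameter
  ranges (rotation ±30°, padding 3–12%, gamma 0.6–1.5, percentile
  contrast stretch 2–98, brightness 0.8–1.4×, blur σ 0.5–1.5) are config
  with these defaults.
* Mosaic uses nearest-neighbour resampling with the per-quadrant affine
  recorded in the output metadata, so pixel-level correspondence is
  exactly checkable.
* Balanced-augmentation targets below the largest class are rejected:
  originals are never deleted, so equalizing is always upward.
* Max-reduction gradients split equally among ties; sampling outside the
  feature grid clamps to the border with the corresponding zero
  subgradient.

## Known limitations

* CPU-only NumPy execution: full-width 640-px training at the published
  200-epoch scale is out of reach; the package targets correctness and
  desk-scale experimentation, not throughput.
* `groups` in convolutions supports only the dense and depthwise cases;
  deformable attention implements a single offset group.
* Checkpoints are NumPy `.npz` archives, not interoperable with other
  frameworks.
* The synthetic benchmark's difficulty is far below real field data; mAP
  numbers obtained on it are not comparable to results on real imagery.
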