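# Methods

This note documents the modeling and numerical choices behind
`woundfusion`: what each component computes, which knobs matter, what
the synthetic data does and does not emulate, and where the design was
genuinely open.

## Problem setting

Wound patches (regions of interest containing a wound and immediate
skin) are classified into up to six categories — background (BG),
normal skin (N), diabetic (D), pressure (P), surgical (S), venous (V).
Each wound sample may carry an anatomical location: an integer ID on a
484-region body map, the numbered atlas used in wound documentation.
Location is clinically informative (wound etiologies concentrate at
characteristic sites), so the classifier can consume it as a second
modality alongside the image.

## Body-map encoding

Only a handful of the 484 region names are public (e.g. 135 = right
fifth toe tip), so the shipped canonical table uses IDs 1..484 with
placeholder names outside the documented examples; a user table (CSV or
JSON) overrides it. All computation depends on IDs and vocabulary size
only. One-hot position is the ID's rank in ascending order rather than
`ID − 1`, so sparse or custom vocabularies encode without holes.
Encoding fails loudly for unregistered IDs: silent misalignment between
manifest and atlas is the dangerous failure mode here. Records without
a location (BG, N) are represented by the all-zero vector when the
location branch is active — "no anatomical site" is itself information
the gate can learn to ignore.

## Dataset splitting

The per-class allocation is `train = ⌊f_tr·n⌋`, `val = ⌊f_val·n⌋`,
test = remainder, with a seed-deterministic within-class shuffle. This
floor rule reproduces, cell for cell, the published per-class subset
counts of the AZH ROI (class totals 100/100/247/185/134/164), AZH
whole-image (156/154/100/128) and Medetec (62/45/109) wound datasets
for both the 70/15/15 and 60/15/25 partitions — the remainder must go
to test, not validation, for every validation cell to match. Products
like `0.7 × 100` are guarded with a `+1e-9` epsilon before flooring
because the binary representation can land a hair under the integer.

Keeping images of the same wound in one subset conflicts in general
with hitting the floor counts exactly, so both behaviors are exposed:
the default ungrouped mode matches the published tables; `group_aware`
packs whole wound groups greedily toward the target counts and reports
the achieved counts in the split metadata. Cross-validation folds are
stratified by class (scikit-learn's seeded `StratifiedKFold`), giving
80–20 per-class partitions at k = 5.

## Augmentation

Training images pass through resize → {rotation ≤ 30°, horizontal and
vertical flips, affine (scale 0.9–1.1, shift ≤ 10%, rotation ≤ 15°),
Gaussian noise (σ = 0.03 on the unit intensity scale), coarse dropout
(≤ 8 holes of 8–32 px)} each fired independently with probability 0.5,
then channel normalization with the ImageNet statistics (the input
convention of the backbone families). The magnitudes are conventional
ranges, exposed as configuration; the method's identity does not depend
on them. Validation and test data get resize + normalization only.
Augmentation happens on the fly per epoch, so split counts stay
meaningful; labels and locations are never touched.

## Network

The numerical substrate is a small reverse-mode autodiff engine over
numpy (float64), written for this package: tape-based, with im2col
convolutions and gradients retained on intermediate tensors (which the
class-activation maps read directly). All parameter initialization is
driven by a single seeded generator per build, so identical seeds give
bitwise-identical networks.

Design choices where the architecture description left room:

* **Backbones.** Pretrained ImageNet backbones require weight downloads
  and are not bundled; the registry ships three desk-scale families —
  plain stacked convolutions, a residual stage, depthwise-separable
  stages — each cut at a mid-depth feature map under a versioned recipe
  (`tiny_a:v1` etc.). Requesting the large pretrained names raises an
  error naming the available recipes. The fusion design is agnostic to
  the exact cut; branches are pooled to a common grid (the smallest
  branch grid, adaptive average pooling) before concatenation.
* **P_scSE merge.** "Max-out and addition" is implemented literally as
  `max(a, b) + (a + b)`; `max`-only and `add`-only merges are selectable
  (`scse_merge`) so the reading is falsifiable. The excitation
  reduction ratio defaults to r = 4: the canonical r = 16 is sized for
  backbones with hundreds of channels, and at the 16 fusion channels of
  the desk-scale configuration it would collapse the bottleneck to a
  single unit (degenerate and dead-ReLU-prone). Ceiling rounding keeps
  any configured ratio at least one unit wide.
* **Axial attention on dense vectors.** A flat F-vector is zero-padded
  to the nearest square g², reshaped to a g×g grid, attended along rows
  then columns (single head; residual connections included), and
  flattened back. This gives "one dimension at a time" a concrete,
  testable form; the wiring is this package's choice, not a claim about
  any reference implementation.
* **Gated MLP wiring.** `u = δ(W_in·loc)` split in halves; gate
  `σ(W_g·axial(u₂))` multiplies `u₁`; output projection to 32 features
  concatenated with the head before the final dense layers. Driving the
  gate bias to ±∞ opens/closes the branch exactly, which the tests use.
* **Conditioning.** The maxout-add merge roughly doubles activation
  scale per aggregation stage and attention residuals add variance, so:
  dense layers use Xavier initialization, convolutions following a
  scSE merge use half-gain Kaiming, attention value projections use
  half gain, the output layer uses gain 0.1 (near-uniform initial
  probabilities), training clips gradients at global norm 5, and an
  optional linear learning-rate warmup (from lr/10) covers the first
  epochs, the phase where attention training is most fragile. Without
  these, desk-scale optimization is unstable.

## Training and evaluation

Adam with cross-entropy on logits (log-softmax path, probabilities
clamped at 1e-12 in the probability-space form). The learning rate
halves after 5 non-improving validation epochs and never drops below
`lr_min` — the reference configuration is lr 1e-4, floor 1e-5, batch
32, 100 epochs at 256×256. The checkpoint with the best validation
accuracy is the one evaluated (the selection rule is this package's
choice). Metric averaging is support-weighted — under weighted
averaging recall equals accuracy algebraically, which the suite asserts
to 1e-9; macro averaging is available via flag. Reported percentages
round to 2 decimals, and k-fold results aggregate as the arithmetic
mean of fold accuracies rounded to 2 decimals.

## Synthetic data

The generator emulates the *statistical* structure the method needs,
not wound photography: class-separable parametric appearance (BG = cool
smooth gradients, N = skin-tone speckle, wound classes = elliptical
lesions on skin with class-specific hue, eccentricity, granularity and
edge darkness) and a tunable class↔location association
(`location_assoc`: probability a wound's location is drawn from its
class's preferred 8-region band rather than uniformly from all 484).
The preferred bands are fixed and disjoint — D 130–137 (the foot band
containing region 135), V 250–257, P 300–307, S 360–367 — small enough
that a desk-scale training set covers its class's location vocabulary.
The `ambiguous_pair` knob renders one class with another's appearance,
making location the only class signal: the fixture for demonstrating
the multi-modal gain. Everything derives from one seeded generator;
identical specs reproduce byte-identical images.

What passing tests on this data do **not** show: robustness to
photographic nuisance (lighting, pose, skin tone, camera), realistic
intra-class variability, or the transfer-learning behavior of large
pretrained backbones. Results on synthetic data demonstrate that the
pipeline and architecture work as specified, not clinical performance.

## Desk-scale study conditions

Tests and the acceptance script run on one CPU core, so they use 32×32
images, small batches (2–4), learning rate 3e-3 with floor 3e-4 (the
same 10:1 ratio as the reference configuration), a 5-epoch warmup, and
short epoch budgets, with augmentation disabled for the optimization
oracles. Two
end-to-end results are computed under these conditions: (1) a tiny
fusion network memorizes 32 separable synthetic samples to 100%
training accuracy within 50 epochs; (2) on ambiguous-appearance data
with `location_assoc = 0.9`, the location-enabled model's mean test
accuracy exceeds the image-only model's over five paired seeds (the
image-only model sits near chance; the fusion model reaches roughly
80–100% depending on seed, bounded above by the 0.9 association).

## Known limitations

* No pretrained weights: the published headline accuracies on the real
  AZH/Medetec photographs depend on GPU-scale transfer learning and are
  out of scope here.
* The numpy engine is single-threaded and eager; it is sized for
  desk-scale experiments, not production training.
* Group-aware splitting is greedy, not optimal; achieved counts can
  deviate from the floor targets when groups are large.
* The 484 region names beyond the documented examples are placeholders;
  analyses must key on IDs.
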