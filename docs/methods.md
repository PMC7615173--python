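# Methods

## The model

The network is an encoder–dual-decoder architecture for binary
segmentation.  Both decoders share the encoder's features (standard
skip-concatenation at every resolution level) but differ in their blocks:

* **Plain block** — two stages of (conv `K=3` → ReLU → norm), spatial shape
  preserved by same padding.  This is the decoder stage of the supervised
  baseline and of the ablation variants.
* **Positive attention shifting block** — the plain main branch is
  multiplied elementwise by `sigmoid(side(x))`, where `side` is a single
  dilated convolution (kernel 3, dilation rate 5, effective footprint 11).
  The gate's effective receptive field (ERF) exceeds the main branch's by
  `(K'/K)·sqrt(1/(1+1/(n+1)))` at feature depth `n`; since the depth
  correction is bounded below by `sqrt(0.5)`, requiring
  `K' > K/sqrt(0.5) ≈ 1.414 K` guarantees enlargement at any depth.  The
  design doubles this bound and rounds up to the nearest odd kernel:
  `K' = 9` for `K = 3`.
* **Negative attention shifting block** — the gate's side branch mirrors
  the main branch but wraps each conv stage in an identity skip (a 1×1
  projection aligns channels when needed).  Treating a residual stack as a
  binomial ensemble of short paths with traversal probability `p`, the
  two-layer ensemble at `p = 0.5` has ERF ratio
  `0.25·sqrt(1/(1+2/n)) + 0.5·sqrt(1/(1+1/(n+1))) + 0.25`, strictly below
  1 for all finite `n` — the gate's ERF is shrunk.

The gating arithmetic is `main ⊙ sigmoid(side)` for both gated blocks; a
`main ⊙ (1 + sigmoid(side))` residual-attention alternative is available
behind `BlockSpec.gate_mode` for ablation.  The source text describing the
design does not write the combination formula; plain multiplication is the
simplest reading of an attention mask and is the default.  The negative
block's side branch has two residual stages, mirroring the two-layer
ensemble in the ratio above.

Each decoder ends in a 1×1 conv + sigmoid head; the fused prediction is
the elementwise average of the two probability maps (probabilities, not
logits, are averaged — the heads' outputs are confidence maps and the
fused map must stay in [0, 1]).  Ablation variants `MM-a/b/c` replace one
or both attention decoders with plain ones.  The 3-D variant swaps every
2-D conv/pool/upsample for its 3-D counterpart, with identical block
topology.

Normalisation defaults to instance norm because the reference training
regime uses batch size 1, where batch statistics degenerate; `norm_kind`
can disable it.

## Losses and training

* **Supervised**: soft Dice loss `1 − (2Σpy + s)/(Σp + Σy + s)` per
  decoder, averaged over the two decoders (both are supervised equally);
  smoothing `s = 1e-6` guards empty masks.
* **Unsupervised**: mean squared error between the decoders' predictions,
  optionally standardised per channel over the whole batch first
  (population statistics over all pixels of the batch; a constant batch
  maps to zeros through a guarded denominator).  At batch size 1 this is
  per-image standardisation.  The term is weighted by `alpha`
  (default 0.002; the combined 3-D preset uses 1.0).
* **Stop-gradient** (default on): the consistency term is computed
  symmetrically with each decoder's prediction frozen as the other's
  target; the value is unchanged but each decoder only receives its own
  branch's gradient.
* **Regimes**: *streaming* interleaves the labelled slices sparsely into
  one pass over the shuffled unlabelled stream per epoch (each labelled
  item exactly once per pass; labelled steps minimise Dice only,
  unlabelled steps `alpha`×consistency only; defaults lr 2e-5, batch 1);
  *combined* draws one labelled and one unlabelled batch per step and
  minimises the sum (defaults lr 1e-2, batch 4); *supervised* uses
  labelled items only and trains the baselines.
* **`alpha = 0` semantics**: an unlabelled streaming step with `alpha = 0`
  carries no gradient, and Adam's moment updates are not free-running, so
  such steps are skipped outright.  Consequently the `alpha = 0`
  trajectory is bit-identical to the supervised schedule under a shared
  seed (the labelled and unlabelled shuffles use separate seeded streams),
  which the tests assert.
* Optimiser is Adam at library-default betas; after training the shipped
  model is the arithmetic mean of the last `k` epoch-end checkpoints
  (default `min(10, epochs)`).  A prediction-ensemble alternative over the
  same checkpoints exists (`predict_ensemble`) since "averaging saved
  models" could be read either way; parameter averaging is the default
  reading.

All of this runs on a deliberately small reverse-mode autodiff engine
(`mismatch.nn`) written on numpy: tensors with recorded backward closures,
N-d same-padding convolution (via strided window views, with dilation),
2× max-pool, 2× nearest upsampling, instance norm, Adam.  Every primitive's
gradient is verified against central finite differences in the test suite.
The engine is float64 throughout and bit-deterministic given seeds.

## ERF measurement

`measure_empirical_erf` backpropagates the central output unit (summed over
channels) of a network to a constant all-ones input and reports the
absolute gradient map, its support area above 1% of the peak, and the RMS
radius of the gradient mass.  Odd spatial extents are required so the
centre is unique; a zero gradient map (possible when every output channel's
centre pre-activation is ReLU-dead) raises a numerical-failure signal.

`erf_block_ordering` compares the three block kinds empirically.  Two
measurement choices matter and are deliberate:

* The probed quantity is each block's *attention pathway* (plain block →
  its output; gated blocks → the side branch producing the gate), because
  the analytic ratios are statements about the side branch's ERF relative
  to the main branch's.  Probing whole gated-block outputs cannot show the
  erosion: with multiplicative gating the output's gradient footprint is a
  superset of the main branch's, and its measured support at random
  initialisation is indistinguishable from the plain block's.
* Each pathway is probed behind a shared one-plain-block prefix.  The
  prefix makes the comparison paired (all three kinds share main-branch
  weights within a seed) and blends the dilated branch's sparse taps (9
  taps spread over an 11×11 extent) into a contiguous field, so the
  thresholded support area reflects the enlarged field rather than the tap
  count.
* Normalisation is disabled in probed blocks: on a constant probe input an
  instance norm collapses near-constant activations and the probe would
  measure the norm's degenerate-variance guard, not the conv topology.

With this protocol the ordering "positive attention > plain > negative
attention" holds per seed for both the support area and (more strongly)
the RMS radius.

## Calibration analysis

Each pixel's predicted class is the more probable of foreground/background,
its confidence `max(p, 1−p) ∈ [0.5, 1]`; a probability of exactly 0.5
counts as foreground.  Confidences fall into `M = 5` equal-width bins over
[0.5, 1]; bins are left-open/right-closed except the first, and a
confidence exactly on an interior edge goes to the lower bin.  ECE is the
count-weighted mean absolute accuracy–confidence gap; empty bins contribute
zero.  Segmentation metrics: IoU and Dice from set counts (empty-vs-empty
defined as perfect), Hausdorff and average surface distance on surface
voxels via exact Euclidean distance transforms scaled by voxel spacing
(one-sided empty cases yield infinite distances with a warning).

The robustness analysis pairs per-image IoU with per-image ECE, fits a
quadratic `IoU = f(ECE)` per model (IoU as the response, per the analysis
it mirrors), and summarises steepness as `|f'(mean ECE)|` — a flatter
trend means accuracy degrades less as calibration worsens.

## Synthetic phantoms and benchmark

`generate_phantom` draws thin tubular foregrounds as rasterised correlated
random walks with jittered radius (vessel-like) or compact random
ellipsoids (tumour-like), in 2-D or 3-D.  The image is
`contrast·mask + N(0, noise_sigma²)`, then case-wise standardised (zero
mean, unit variance over the whole image); channels are replicated for
multi-modal input shapes.  Defaults — contrast 1.0, noise 0.3, radii
1.5–3 px on 64×64 — give a visible but non-trivial task.  The generator
does *not* simulate acquisition physics (partial volume, bias fields,
modality-specific contrast), so passing benchmarks here demonstrates the
learning mechanics, not clinical-grade performance.

Selection rules mirror the real-data protocol: keep slices with strictly
more than `foreground_min` (default 100) foreground pixels; crop fixed-size
patches from the four slice corners (0-based anchors, half-open windows);
draw seeded uniform subvolumes (default 96³) from 3-D cases.

`make_benchmark` builds disjoint labelled/unlabelled/val/test splits; the
labelled split comes from a single synthetic "case" (images sharing
case-level radius/contrast parameters) to emulate the one-labelled-case
regime; unlabelled images span three cases and test five.

The gain benchmark (`mismatch.benchmark`) is the scaled-down stand-in for
the clinical experiments: 64×64 tube phantoms, 5 labelled / 100 unlabelled
slices, width-4 networks, 10 epochs, 3 seeds, streaming regime with
`alpha = 0.002`, against the width-4 supervised baseline trained on the
same labelled slices.  The preset learning rate is 1e-3 rather than the
clinical 2e-5: the benchmark takes ~50 supervised steps in total, two
orders of magnitude fewer than the setting that rate is calibrated to, and
at 2e-5 neither model would leave its initialisation.  These sizes keep the
benchmark a few CPU-minutes; they were chosen once as the package's study
conditions and the magnitude of the gain at this scale is not comparable
with full-scale results (the direction is).

## Known limitations

* Single foreground class only; multi-class heads are out of scope.
* The numpy engine is CPU-only and sized for small experiments, not for
  full-resolution clinical training.
* The IoU-vs-ECE robustness comparison is noisy at benchmark scale: with
  lightly trained models predictions are under-confident and the IoU–ECE
  relation can invert relative to fully trained regimes, so the trend
  comparison is meaningful only in the aggregate, not per run.
* PNG round-trips quantise intensities to 16 bits (the affine rescale is
  recorded in the benchmark manifest); NIfTI round-trips are exact.
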