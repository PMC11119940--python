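# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
and design decisions a maintainer would want written down.

## Compute core

No deep-learning framework is used.  `pestnet.nn` is a reverse-mode
autodiff engine over float64 numpy arrays: closure-based backward passes on
a topologically sorted graph, convolution via im2col matmuls, max pooling
with argmax routing, batch normalisation composed from primitives, and Adam
with per-epoch exponential learning-rate decay.  Float64 keeps the
oracle-equivalence tests (tolerances down to 1e-9) free of single-precision
noise; at the problem sizes the package targets, the cost is irrelevant.
Determinism: every layer draws its initial weights from a
`numpy.random.Generator` threaded through construction, so a (config, seed)
pair rebuilds bit-identical models, and training consumes randomness (batch
order, crop offsets) only from the seeded generator.

## Relation-aware attention

Both submodules score a node from its own embedding *and* its full affinity
pattern to all other nodes.  Affinities are dot products of ReLU-activated
1×1-conv + BN embeddings, so relation matrices are nonnegative by
construction.  The relation vector stacks row block first, then column
block — [R(i,:), R(:,i)] — an order that affects learned parameters but no
invariant.  The scorer is Conv (reduce by `reduction_ratio`) → BN → ReLU →
Conv (→ 1 channel) → BN → sigmoid; weights are therefore strictly inside
(0, 1) and the block re-weights without reshaping.  The attention output is
implemented as per-node broadcast multiplication s_i·x_i, not a sum over
nodes: a literal sum would collapse the spatial map that the channel
submodule consumes next, contradicting the shape-preserving architecture.

Choices left open by the design and fixed here:

- `reduction_ratio` and `embed_ratio` both default to 8 (the usual
  squeeze-ratio convention); both are exposed in the config.  Where 8 does
  not divide a stage's channel count, the network uses the largest divisor
  not exceeding it.
- No spatial downsampling before relation computation; instead the blocks
  are inserted only at stages where N = H·W is moderate (default stages 2
  and 3).  At stage 1 the N×N relation matrix is prohibitively large; at
  stage 4 attention over a 2×2 grid is nearly pointless.
- Because the relation convolutions are sized by the node count, each block
  is built for a fixed (channels, H, W); the network derives these from
  `input_size`.
- Convolutions feeding a BN layer carry no bias (BN subtracts the mean, so
  a bias there is exactly inert).
- For unit tests the BN layers support a `bypass` mode (exact identity) and
  the embeddings an identity initialisation, reducing the relation matrix
  to ReLU(x_i)·ReLU(x_j) — directly checkable by a brute-force double loop.

## Multi-scale fusion

Per-location weight maps rather than one global triple per level: spatial
filtering of conflicting information is the point of adaptive fusion, and a
global scalar would be a strictly weaker mechanism.  Each aligned map is
compressed to 8 channels (configurable), the 24-channel concatenation maps
to 3 logits per location, and a softmax guarantees α+β+γ = 1 — hence the
tested invariants: the fused pre-convolution map lies in the inputs'
pointwise envelope, and fusing three identical maps is the identity for
any parameters.  Rescaling to L4 geometry is by strided 3×3 convolutions
(one per octave, channels projected to L4's count) by default; an
`interpolate` mode (2×2 average pooling + 1×1 projection, optionally
mean-preserving-initialised) exists for exact-arithmetic tests.  The output
3×3 stride-1 convolution preserves the channel count so the head's input
dimension equals L4's.  The fused map replaces the L4 path (it is not
concatenated with it).

## Generalized-mean pooling

Activations are clamped at eps = 1e-6 before exponentiation: the power is
undefined for negatives at fractional p, and exact zeros break the 1/p
root's gradient; post-ReLU activations are nonnegative anyway, so the clamp
is inert in practice (an all-nonpositive map saturates at eps, documented).
The implementation factors out the per-channel max — gem(x) = m·gem(x/m),
an exact identity — so large exponents cannot overflow; p = 1000 reproduces
the max limit within 1%.  The learnable exponent initialises at 3.0
(standard retrieval-literature default), shared across channels with a
per-channel option, and the *layer* clamps p to [1, 100] during
optimisation (between the average and near-max limits); the functional form
only enforces p ≥ 1 so the limit behaviour itself remains testable.

## Losses

BFL weights are α_i = 1 − f_i/10 as the weight-law formula states, giving
α ∈ [0.9, 1] with α = 1 exactly for an absent class.  (The surrounding
prose description — "the maximum frequency corresponds to α = 1" — is
inconsistent with that formula, which yields α = 0.9 at f = 1; the formula
is implemented.)  The histogram defaults to the whole training set's label
counts: with ~100 classes at batch size 32–64, per-batch histograms are
mostly zeros, which would collapse most α to 1 and neutralise the
mechanism; a per-batch mode exists for comparison.  γ defaults to 2.0, the
canonical focusing value.  Reduction is the batch mean (keeps the loss
scale batch-size invariant); p_t is floored at 1e-12 before the log.  The
losses accept logits (computed through a stable log-softmax) or explicit
probability rows.

The imbalance mechanism is probed directly (`pestnet.experiments`): a
linear softmax model on 2-D Gaussian class-conditional features, 200
majority vs 10 minority training samples (20:1), evaluated on a large
balanced test set.  Over 10 paired seeds, BFL's mean minority-class recall
exceeds cross-entropy's — the scaled-down analogue of the loss ablation.

## Metrics

All metrics derive from one accumulated confusion matrix, never per-batch
averaging.  Degenerate-class conventions: a never-predicted class
contributes precision 0 to MPre; a class with no true samples contributes
recall 0.  MF1 is the harmonic mean of MPre and MRec (not the mean of
per-class F1 scores).  GM is the C-th root of the product of per-class
sensitivities; zero sensitivities are replaced by 0.001 so one missed class
penalises GM by orders of magnitude without annihilating it.  The floor
applies to sensitivity only.  Macro precision/recall are cross-checked in
the test suite against scikit-learn to 1e-9.

## Data pipeline and synthetic generator

Preprocessing: shorter side resized to the crop size (bilinear), random
crop for training, deterministic center crop for evaluation;
smaller-than-window images are reflection-padded.  Horizontal flips and
channel normalisation are not applied by default; ImageNet normalisation is
an opt-in flag for use with pretrained weights.  Splits: 70% train
(floor), then the remainder 30/70 into validation/test with round-half-up
on the validation block — the unique simple rounding convention that turns
4508 records into exactly 3155/406/947.

The generator renders one parametric motif family per class (8 shapes ×
distinct hue bands × stripe texture) at random position/scale/rotation over
low-frequency colour fields with distractor blobs.  Class counts follow
n_c = round(max·c^−exponent) (half-up), computed rather than sampled, so
the histogram matches the law exactly; exponent 1.0 by default, mirroring
the heavy head/long tail of field benchmarks.  Default image size is 64 —
CPU-scale study conditions under which every end-to-end property in the
tests is measured.  What the generator deliberately does **not** emulate:
intra-class morphological variation (life stages), inter-class visual
similarity, lighting and occlusion.  A passing smoke test therefore shows
the pipeline learns separable class structure end to end; it says nothing
about accuracy on real field images.

## Training protocol

Adam with β = (0.9, 0.999), initial learning rate 1e-4, exponential decay
0.96 applied per epoch (per step would collapse the rate within one
epoch), up to 100 epochs, batch size 32, 256×256 crops — the full-scale
defaults in `TrainConfig`.  Model selection keeps the best
validation-accuracy state.  No weight decay.  A non-finite loss aborts with
a diagnostic dump.  Tests and the acceptance script scale the same
protocol down (tiny backbone, 64×64 images, 1–10 epochs, ~200 images):
these sizes were chosen as the smallest at which each property is cleanly
observable, and they are stated in each test.

## Known limitations

- The numpy core is single-threaded per op and float64; it is built for
  correctness and CPU-scale experiments, not for full-scale benchmark
  training.
- RGA blocks are geometry-specialised, so a trained model evaluates at the
  crop size it was built for.
- Pretrained backbone weights load from a local `.npz` state file only; no
  download mechanism is provided, and nothing in the package requires them.
- Whether per-location (versus global scalar) fusion weights match any
  particular external implementation is unverifiable from the architecture
  description alone; the per-location choice is recorded above.
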