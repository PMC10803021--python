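# Methods and design notes

## The model

The segmenter is an encoder–decoder for per-pixel classification of
endoscopy frames into background tissue (label 0) and k instrument classes
(labels 1..k; the reference configuration uses k = 2, i.e. three output
channels).

**Encoder.** A four-stage densely connected backbone. The stem is two
stride-2 depthwise-separable 3×3 convolutions (3 → 14 channels), so stage 1
operates at stride 4. Each stage stacks *depth* dual-branch bottlenecks;
depths are fixed at (2, 2, 6, 2), a 1:1:3:1 ratio concentrating capacity in
the stride-16 stage. A bottleneck with input C and growth g runs two
parallel depthwise-separable branches — depthwise 7×7 and depthwise 3×3,
each followed by batch norm + ReLU, a pointwise 1×1 to g channels, and batch
norm + ReLU again — sums the two branch outputs raw (no activation after the
sum) and concatenates the result onto the input: C → C + g. The 7×7 branch
buys receptive field at depthwise prices; the 3×3 branch keeps fine edge
detail. Between stages, a DenseNet-style transition (1×1 compression by 0.5,
BN + ReLU, 2×2 average pooling) halves both channels and resolution. Stage
outputs form the pyramid at strides 4/8/16/32.

**Decoder.** Lateral 1×1 convolutions (+BN+ReLU) bring the four levels to a
common 64-channel width; the standard top-down FPN pathway adds each deeper
level, bilinearly upsampled 2×, into the next shallower lateral. Each merged
level then travels to stride 4 through a chain of upsample blocks (3×3
depthwise-separable conv, 1×1 conv, 2× bilinear upsample): zero blocks for
the stride-4 level (a plain 1×1 projection instead), up to three for the
stride-32 level. The last element of every chain reduces to 16 channels, and
the four aligned maps concatenate channel-wise into the 64-channel fused map
(64×64 spatial for a 256×256 input). Reading the fused width as
4 × 16-channel contributions is a design choice: the architecture only pins
the concatenated size, and equal per-level contribution is the symmetric
reading.

**Criss-cross attention.** On the fused map F (C = 64), three 1×1
convolutions produce Q, K (B = C/8 = 8 channels) and V (C channels). Each
position attends to the H + W − 1 positions sharing its row or column:
affinity scores d_u = Ω_u Q_u, weights A_u = softmax(d_u), output
F′_u = Φ_uᵀ A_u + F_u. Implementation details that the math leaves open,
fixed here:

- The attended position u is counted once. Internally the score tensor has
  H + W entries per position (full row then full column); the duplicate of u
  in the column block is masked with −10⁹ before the softmax, which
  underflows to an exactly-zero weight in float32 — the support is exactly
  H + W − 1.
- Scores are raw dot products (no 1/√B scaling, no positional encoding).
- A single attention pass is applied (no recurrence).
- The efficient path's peak intermediate is H·W·(H + W) scores; it never
  materializes an (H·W)² matrix. A dense masked-attention oracle
  (`dense_attention_oracle`, restricted to H·W ≤ 256) provides the
  independent reference used by the tests.

**Head.** 3×3 depthwise-separable convolution, 1×1 convolution to k + 1
channels (with bias; this is the only convolution carrying a bias outside
the attention projections), 4× bilinear upsample to input resolution.

**Ablation toggles.** `use_fpn=False` replaces the pyramid by a 1×1
projection of the stride-4 level to the fused width; `use_ccam=False` skips
the attention block. The four combinations (baseline / +FPN / +CCAM / full)
build, train and profile through the same interface.

## Width calibration

The stage depths are architectural constants, but the widths are not fully
determined by the design; the binding constraint adopted here is the
efficiency budget of the reference model — 466 K trainable parameters and
0.202 G MACs at 3×256×256. Within the documented structure (stem + four
growth rates, compression 0.5, 64 lateral channels, 16 per-level
contribution channels), a grid search over integer widths selected
stem = 14 and growth rates (14, 14, 38, 200), giving 466,460 parameters and
201,997,824 MACs — both land on the budget under the conventions below. The
large last-stage growth is the expected shape of that trade-off: stride-32
parameters are nearly free in MACs, so the budget pushes capacity deep.

MAC convention: a convolution costs kernel-elements × output-elements
(depthwise: k²·C·H·W; pointwise: C_in·C_out·H·W), criss-cross attention
costs B·(H + W − 1) affinity plus C·(H + W − 1) aggregation MACs per
position plus its three projections, bilinear resizing costs 4 MACs per
output element, and normalization/activation/pooling/addition are free.
Profilers commonly print MAC counts under the name "FLOPs"; the efficiency
report keeps MACs as the headline figure and also prints 2× MACs.

## Loss

Multi-class focal loss, FL(p_t) = −α_t (1 − p_t)^γ log p_t with natural
logarithm, γ = 2 and α = 0.25 by default, mean-reduced over non-ignored
pixels. α is applied on the foreground/background axis — α for any
instrument class, 1 − α for background — the binary convention extended
unchanged to multiple foreground classes. p_t is computed from log-softmax,
so the loss stays finite for arbitrarily confident mistakes. `alpha=None`
switches the balancing weight off (useful for recovering plain
cross-entropy at γ = 0).

## Metrics

All metrics derive from a single global (k+1)×(k+1) pixel confusion matrix
accumulated over a split, making results invariant to batching. Macro means
average over classes including background. A class absent from both
prediction and truth contributes NaN per-class values and is excluded from
the macro means — the pragmatic resolution of the 0/0 case that an
unconditional divide-by-(k+1) mean leaves undefined. Whether published
tables of this kind average per-image or globally is generally unstated;
global accumulation is the common mIoU convention and is used throughout.

## Training protocol

AdamW (initial learning rate 1e-3, decoupled weight decay 1e-2, β = 0.9 /
0.999), 100 epochs by default, batch size 8 at 256×256, validation every two
epochs, and retention of the five best checkpoints by validation mIoU. The
learning rate follows a reduce-on-plateau rule monitoring validation mIoU
(mode max, factor 0.5, patience 5 validations, floor 1e-6); the monitored
quantity is a design choice — selecting checkpoints by mIoU makes mIoU the
natural plateau signal too. Test-set evaluation predicts with each retained
checkpoint and averages the resulting metrics arithmetically. No data
augmentation is applied. PNG decoding fans out over `reader_threads`
(default 16) reader threads. The `mixed_precision` flag is accepted for
interface completeness, but this implementation always computes in float32
single precision — on CPU there is no half-precision path worth taking, and
float32 is the accuracy baseline the tests pin down.

Determinism: all randomness (scene synthesis, splits, parameter
initialization, batch shuffling) flows from explicit integer seeds through
`numpy.random.default_rng`; two runs with identical seeds and configuration
are bitwise-identical.

## The numpy layer stack

The network runs on a purpose-built reverse-mode autograd core
(`ldcnet.nn`): float32 tensors, iterative topological-order backpropagation,
and hand-derived backward passes for each operation. Notable numerical
choices:

- Depthwise convolution is computed by shift-and-accumulate over the k²
  kernel offsets ('same' zero padding), avoiding im2col buffers; stride 2
  requires even spatial sizes.
- Batch norm uses biased batch variance for normalization, running-statistic
  momentum 0.1, eps 1e-5; the training-mode backward includes the full
  mean/variance dependence.
- Bilinear resizing is separable: row-stochastic 1-D interpolation matrices
  built with half-pixel centers (align-corners false) and clamped edges, the
  same convention for the model's upsampling and for image resizing in the
  data pipeline. Mask resizing is nearest-neighbour with source index
  floor((i + 0.5)·S/target).
- Parameters use He-normal initialization (fan-in of the kernel for
  depthwise, input channels for pointwise); norms start at γ=1, β=0.
- Gradient correctness is tested against central finite differences of
  random scalar projections; float32 limits agreement to a few parts per
  hundred at ε = 3e-3, which the tests account for.

## Synthetic scenes

The generator emulates the statistics that matter for this task: a dark
reddish tissue background (base intensity 0.35) with smooth low-frequency
texture, radial vignetting (strength 0.6), one or two elongated instruments
drawn as rotated capsules entering from a frame edge (widths 10–26 px at
256², lengths 0.45–0.85 of the frame) with a metallic brightness gradient
toward the tip, a few specular highlight blobs, and Gaussian pixel noise
(σ = 0.02). Instruments cover roughly 5–15% of pixels, reproducing the
strong class imbalance; labels cycle through 1..k so every class appears.
If a draw would exceed 45% coverage, widths are halved and the same
geometry redrawn.

What the generator does *not* emulate: real optics (depth of field, motion
blur, smoke), soft-tissue deformation and occlusion, instrument
articulation, shadows, blood and debris, or inter-frame correlation. Tests
passing on these scenes therefore demonstrate that the architecture, loss,
metrics and training loop are implemented correctly and can fit
thin-structure segmentation — not that the model reaches any particular
accuracy on real endoscopy data.

## Problem sizes in the tests

The test suite exercises tiny width configurations (stem 4, growths 2)
for shape/semantics checks, 32–64 px scenes for the training-engine tests,
and one full-size capacity check: the reference 256×256 model overfitting 8
synthetic scenes to train mIoU ≥ 0.95 (reached around step 85 of an allowed
300). These sizes are the package's own choice of a fast, deterministic
verification ladder; the full 100-epoch protocol at dataset scale runs
through the same code path via the CLI.

## Known limitations

- CPU-only and modest throughput (~2 s per 8-image 256² training step on one
  core); the design goal is correctness and auditability, not speed.
- The per-stage channel plan is calibrated to the parameter/MAC budget, not
  to accuracy; other width allocations meeting the same budget exist.
- Single-pass attention; no recurrent criss-cross sweeps.
- The focal α is foreground/background only; per-class weights are out of
  scope.
- `SplitSpec` supports exactly the 60/20/20 protocol, unstratified (whether
  the canonical shuffle stratifies by instrument type is unspecified; this
  implementation does not).
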