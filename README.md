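# ldcnet — lightweight endoscopic surgical-instrument segmentation

Semantic segmentation of surgical instruments in endoscopy frames is a
safety-critical component of robot-assisted surgery: the network must find
thin, elongated metallic tools — and especially their small, intricate tips —
against dark, vignetted tissue, fast enough and small enough to deploy on
clinical hardware. This package implements a lightweight encoder–decoder for
that task, together with its training protocol, metric suite, efficiency
profiler, and a synthetic endoscopy scene generator so the entire pipeline is
testable end-to-end without any external dataset or GPU.

The network, in brief:

- **LDCNet encoder** — four densely connected stages (depths 2, 2, 6, 2, a
  1:1:3:1 stacking ratio). Each block is a dual-branch bottleneck: a 7×7 and
  a 3×3 depthwise-separable branch, both mapping the block input to *g*
  (growth-rate) channels; the branch outputs are summed and concatenated with
  the input, DenseNet-style. DenseNet transitions (1×1 compression ×0.5 +
  2×2 average pooling) separate the stages, yielding a feature pyramid at
  strides 4/8/16/32.
- **FPN fusion** — lateral 1×1 convolutions and top-down 2× bilinear merging,
  then per-level upsampling chains concatenated into a single
  64 × 64 × 64 fused map (for a 256 × 256 input).
- **Criss-cross attention (CCAM)** — sparse self-attention in which each
  position *u* attends to the H + W − 1 positions on its row and column:
  d_u = Ω_u Q_u, A_u = softmax(d_u), F′_u = Φ_uᵀ A_u + F_u, with Q, K ∈
  R^{B×H×W} (B < C) and V ∈ R^{C×H×W} from 1×1 convolutions. Global context
  at a small fraction of dense-attention cost; a brute-force masked dense
  oracle ships for testing.
- **Focal loss** — FL(p_t) = −α_t (1 − p_t)^γ log p_t with γ = 2,
  α = 0.25, countering the extreme background/instrument pixel imbalance.
- **Metrics** — precision, recall, F1 and mIoU
  (mean over classes of TP/(TP+FP+FN)) from one global pixel confusion
  matrix per split.

Every convolution in the model is depthwise or pointwise; the reference
configuration has **466 K trainable parameters** and costs
**0.202 G multiply-accumulates** for one 3×256×256 forward pass.

The network is implemented on a small numpy autograd layer stack
(`ldcnet.nn`) written for this package: reverse-mode differentiation over
exactly the operations the model needs (depthwise/pointwise convolution,
batch norm, bilinear resizing, softmax families, einsum contractions), with
AdamW and a reduce-on-plateau schedule. Everything runs on a single CPU.

## Worked example

Profile the reference model (this is the `ldcnet profile` output):

```
parameters                   466,460
parameters (K)                   466
MACs @ 256x256           201,997,824
MACs (G)                       0.202
2 x MACs (G)                   0.404
```

The parameter count sums every trainable element; 466,460 rounds (half-up)
to 466 K. MACs follow the profiler's stated convention — convolutions cost
kernel-elements × output-elements, attention costs (B + C)(H + W − 1) per
position, bilinear resizes 4 per output element — and 201,997,824 prints as
0.202 G. (Profilers often label MACs as "FLOPs"; the 2× figure is printed
for transparency.)

Overfit the full model on eight synthetic 256×256 scenes — a standard
capacity/plumbing check that the encoder, fusion, attention, loss and
optimizer cooperate:

```python
import numpy as np
from ldcnet import ModelConfig, SceneConfig, generate_scene, build_model
from ldcnet.training import overfit

images, masks = zip(*(generate_scene(SceneConfig(seed=100 + i))
                      for i in range(8)))
images = np.stack([im.transpose(2, 0, 1) for im in images])
masks = np.stack(masks).astype(np.int64)

model = build_model(ModelConfig(), seed=0)
history = overfit(model, images, masks, max_steps=300, target_miou=0.95)
```

On one CPU this run reaches train mIoU 0.950 at step 80 and stops at step 85
with mIoU 0.953 and focal loss 0.0027 (from 0.25 at step 1), in about three
and a half minutes — the instruments, including both instrument classes and
their tips, are segmented essentially pixel-perfectly on the training

scenes.

A quick command-line tour (tiny sizes, seconds to run):

```
ldcnet generate-data --n 10 --classes 2 --size 64 --seed 1 --out frames
#  wrote 10 pairs to frames (manifest.csv included)
ldcnet split --n 10 --seed 0 --out split.json
#  split 10 -> train 6 / val 2 / test 2 -> split.json
ldcnet train --config cfg.yaml --data frames/manifest.csv \
             --split split.json --out run
ldcnet evaluate --run run --config cfg.yaml \
                --data frames/manifest.csv --split split.json
```

`train` runs the full protocol — AdamW at 1e-3, ReduceLROnPlateau, focal
loss, validation every two epochs, the five best checkpoints retained —
and `evaluate` predicts the test split with each retained checkpoint and
averages the metrics. (Meaningful accuracy needs the full 100-epoch
protocol on a real training set; a seconds-long demo pass only exercises the
plumbing.)

For the canonical dataset preparation, `split_dataset(2344, seed=...)`
reproduces the 1,406 / 469 / 469 train/val/test partition: validation and
test each take round(0.2·N) items after a seeded shuffle and training keeps
the remainder.

## Layout

```
src/ldcnet/
  nn/            autograd tensor core, layers, optimizers
  synthetic.py   scene generator, 60/20/20 splits, resizing, PNG datasets
  encoder.py     dense dual-branch depthwise-separable backbone
  ccam.py        criss-cross attention + dense oracle
  decoder.py     FPN fusion, segmentation head, full model
  losses.py      multi-class focal loss
  metrics.py     confusion-matrix precision/recall/F1/mIoU
  training.py    AdamW + plateau schedule, top-k checkpoints, evaluation
  profiler.py    parameter / MAC accounting
  cli.py         command-line interface
docs/methods.md  modelling and design notes
```
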