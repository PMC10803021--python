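"""Multi-class focal loss.

FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t), where p_t is the softmax
probability of a pixel's true class.  The modulator (1 - p_t)^gamma shrinks
the contribution of easily classified pixels, concentrating the gradient on
hard ones (instrument edges and tips); alpha balances foreground against
background: alpha_t = alpha for instrument classes (label >= 1) and
1 - alpha for background, the binary convention extended to multiple
foreground classes.  Defaults gamma = 2, alpha = 0.25.

The loss is the mean over non-ignored pixels, computed from log-softmax
probabilities so it stays finite for arbitrarily confident wrong logits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor, as_tensor


@dataclass
class FocalLossConfig:
    gamma: float = 2.0
    alpha: Optional[float] = 0.25   # None disables the balancing weight
    ignore_index: Optional[int] = None

    def validate(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        return self


def focal_loss(logits, target, config: FocalLossConfig = None) -> Tensor:
    """Scalar focal loss of (N,K,H,W) logits against (N,H,W) integer labels.

    Accepts Tensors (gradients flow) or plain arrays.  Labels must lie in
    {0..K-1} apart from ``ignore_index`` pixels, which are excluded from the
    mean.
    """
    config = (config or FocalLossConfig()).validate()
    logits = as_tensor(logits)
    target = np.asarray(target)
    if logits.ndim == 3:  # allow single-image (K,H,W) input
        logits = _expand0(logits)
        target = target[None]
    n, k, h, w = logits.shape
    if target.shape != (n, h, w):
        raise ValueError("target shape must match logits spatial shape")
    valid = np.ones(target.shape, dtype=bool)
    if config.ignore_index is not None:
        valid = target != config.ignore_index
    labels = np.where(valid, target, 0)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("target labels out of range")

    logp = T.log_softmax(logits, axis=1)
    logp_t = T.gather_label(logp, labels)           # (N,H,W)
    p_t = T.exp(logp_t)
    modulator = T.power(T.sub(Tensor(np.float32(1.0)), p_t), config.gamma) \
        if config.gamma > 0 else None
    if config.alpha is not None:
        alpha_map = np.where(labels >= 1, config.alpha,
                             1.0 - config.alpha).astype(np.float32)
    else:
        alpha_map = None

    term = T.neg(logp_t)
    if modulator is not None:
        term = T.mul(term, modulator)
    if alpha_map is not None:
        term = T.mul(term, Tensor(alpha_map))
    mask = None if valid.all() else valid
    return T.masked_mean(term, mask)


def _expand0(t: Tensor) -> Tensor:
    """Prepend a batch axis, keeping the autograd graph intact."""
    def backward(g):
        t._accumulate(g[0])

    return Tensor(t.data[None], requires_grad=t.requires_grad,
                  parents=(t,) if t.requires_grad else (),
                  backward_fn=backward if t.requires_grad else None)
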