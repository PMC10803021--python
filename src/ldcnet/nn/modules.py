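"""Layer abstractions over the autograd tensor core.

Modules own :class:`Parameter` leaves (and, for batch norm, running-statistic
buffers), expose ``named_parameters``/``state_dict`` by walking their
attribute tree, and report multiply-accumulate costs through ``count_macs``
so the profiler can account for a model structurally.

MAC convention: a convolution costs kernel-elements x output-elements; batch
norm, activations, pooling and elementwise additions are free; bilinear
resizing costs 4 MACs per output element.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: attribute-tree traversal, train/eval, state dicts."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- traversal ---------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- mode and gradients ------------------------------------------------
    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -----------------------------------------------------
    def state_dict(self, prefix=""):
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                out[prefix + name] = value.data
        for bname, buf in self._buffers.items():
            out[prefix + bname] = buf
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state):
        mine = dict(self.named_parameters())
        for name, p in mine.items():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for bname in self._buffers:
            self._buffers[bname] = np.asarray(
                state[prefix + bname], dtype=np.float32).copy()
        for name, child in self._children():
            child._load_buffers(state, prefix + name + ".")

    def parameter_count(self):
        return int(sum(p.data.size for p in self.parameters()))

    # -- interface ---------------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def count_macs(self, h, w):
        """Return (macs, h_out, w_out) for an input of spatial size h x w."""
        raise NotImplementedError(type(self).__name__)


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class PointwiseConv(Module):
    """1x1 convolution, channel mixing only."""

    def __init__(self, in_channels, out_channels, rng, bias=False):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_he(rng, (out_channels, in_channels), in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        if self.bias is None:
            del self.bias  # keep the attribute tree clean for traversal

    def forward(self, x):
        b = getattr(self, "bias", None)
        return T.pointwise_conv(x, self.weight, b)

    def count_macs(self, h, w):
        return self.in_channels * self.out_channels * h * w, h, w


class DepthwiseConv(Module):
    """Per-channel k x k convolution with 'same' padding."""

    def __init__(self, channels, kernel_size, rng, stride=1):
        super().__init__()
        self.channels = channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.weight = Parameter(
            _he(rng, (channels, kernel_size, kernel_size), kernel_size ** 2))

    def forward(self, x):
        return T.depthwise_conv(x, self.weight, stride=self.stride)

    def count_macs(self, h, w):
        ho, wo = h // self.stride, w // self.stride
        return self.kernel_size ** 2 * self.channels * ho * wo, ho, wo


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm(x, self.gamma, self.beta,
                            self._buffers["running_mean"],
                            self._buffers["running_var"],
                            self.training, self.momentum, self.eps)

    def count_macs(self, h, w):
        return 0, h, w


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return T.relu(x)

    def count_macs(self, h, w):
        return 0, h, w


class AvgPool2(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return T.avg_pool2(x)

    def count_macs(self, h, w):
        return 0, h // 2, w // 2


class BilinearUpsample(Module):
    def __init__(self, scale, channels):
        super().__init__()
        self.scale = scale
        self.channels = channels

    def forward(self, x):
        _, _, h, w = x.shape
        return T.bilinear_resize(x, h * self.scale, w * self.scale)

    def count_macs(self, h, w):
        ho, wo = h * self.scale, w * self.scale
        return 4 * self.channels * ho * wo, ho, wo


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def count_macs(self, h, w):
        total = 0
        for layer in self.layers:
            m, h, w = layer.count_macs(h, w)
            total += m
        return total, h, w


class DepthwiseSeparable(Sequential):
    """Depthwise k x k then pointwise 1x1, each followed by BN + ReLU."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1):
        super().__init__(
            DepthwiseConv(in_channels, kernel_size, rng, stride=stride),
            BatchNorm2d(in_channels),
            ReLU(),
            PointwiseConv(in_channels, out_channels, rng),
            BatchNorm2d(out_channels),
            ReLU(),
        )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size


def save_state(path, state):
    np.savez(path, **state)


def load_state(path):
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
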