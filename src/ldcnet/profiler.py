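"""Model efficiency accounting: trainable parameters and MAC counts.

Parameter counts sum every trainable element (convolution kernels, biases
where present, normalization affine pairs).  MAC counts follow a stated
convention: each convolution costs kernel-elements x output-elements,
criss-cross attention costs B * (H + W - 1) affinity plus C * (H + W - 1)
aggregation MACs per position, bilinear resizes cost 4 MACs per output
element, and normalization / activations / pooling / additions are free.
Common profilers print MAC counts under the name "FLOPs"; the report keeps
the MAC figure as its headline number and also prints 2x MACs for
transparency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .config import ModelConfig
from .decoder import LDCNetSegmenter, build_model


def round_half_up_thousands(n: int) -> int:
    return int((n + 500) // 1000)


@dataclass
class EfficiencyReport:
    parameter_count: int
    parameter_count_k: int
    mac_count: int
    mac_count_g: float
    flops_2x_g: float
    input_size: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def pretty(self) -> str:
        lines = [
            f"{'parameters':<22}{self.parameter_count:>14,d}",
            f"{'parameters (K)':<22}{self.parameter_count_k:>14,d}",
            f"{'MACs @ {0}x{0}'.format(self.input_size):<22}{self.mac_count:>14,d}",
            f"{'MACs (G)':<22}{self.mac_count_g:>14.3f}",
            f"{'2 x MACs (G)':<22}{self.flops_2x_g:>14.3f}",
        ]
        return "\n".join(lines)


def count_parameters(model_or_config) -> int:
    """Total trainable parameter elements of a model (or freshly built config)."""
    model = _as_model(model_or_config)
    return model.parameter_count()


def count_macs(model_or_config, input_size: int = 256) -> int:
    """Multiply-accumulate count of one forward pass at input_size^2."""
    model = _as_model(model_or_config)
    return model.count_macs(input_size)


def profile(model_or_config, input_size: int = 256) -> EfficiencyReport:
    model = _as_model(model_or_config)
    params = model.parameter_count()
    macs = model.count_macs(input_size)
    return EfficiencyReport(
        parameter_count=params,
        parameter_count_k=round_half_up_thousands(params),
        mac_count=macs,
        mac_count_g=round(macs / 1e9, 3),
        flops_2x_g=round(2 * macs / 1e9, 3),
        input_size=input_size,
    )


def _as_model(model_or_config) -> LDCNetSegmenter:
    if isinstance(model_or_config, LDCNetSegmenter):
        return model_or_config
    if isinstance(model_or_config, ModelConfig):
        return build_model(model_or_config)
    raise TypeError("expected a LDCNetSegmenter or ModelConfig")
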