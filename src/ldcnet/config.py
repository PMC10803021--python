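"""Configuration dataclasses and YAML (de)serialization.

``ModelConfig`` pins everything architectural: the four-stage dense encoder
(stage depths fixed at 2/2/6/2), per-stage growth rates, the FPN / criss-cross
attention toggles used by the ablation, and the class count.  ``TrainConfig``
carries the optimization protocol; ``SceneConfig`` the synthetic-scene
generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class SceneConfig:
    """Parameters of a synthetic endoscopy scene.

    The defaults emulate the statistics of endoscopic instrument frames: a
    dark, vignetted tissue background, one or two thin elongated metallic
    instruments entering from the frame border, specular highlights, and
    strong class imbalance (instruments cover a small fraction of pixels).
    """

    image_size: int = 256
    n_instruments: int = 2
    instrument_classes: int = 2        # labels 1..k; 0 is background tissue
    min_instrument_width: int = 10
    max_instrument_width: int = 26
    background_base_intensity: float = 0.35
    vignette_strength: float = 0.6
    specular_count: int = 3
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self):
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        if self.n_instruments < 0:
            raise ValueError("n_instruments must be >= 0")
        if self.instrument_classes < 1:
            raise ValueError("instrument_classes must be >= 1")
        if self.n_instruments > 0 and self.instrument_classes < 1:
            raise ValueError("cannot draw instruments with zero classes")
        if not 0 < self.min_instrument_width <= self.max_instrument_width:
            raise ValueError("instrument widths must satisfy 0 < min <= max")
        if not 0.0 <= self.background_base_intensity <= 1.0:
            raise ValueError("background_base_intensity must be in [0, 1]")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        return self


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the segmentation network.

    The stage depths (2, 2, 6, 2) follow a 1:1:3:1 stacking ratio.  The
    default widths are calibrated so the full model (FPN + criss-cross
    attention, 3 output classes) lands on a 466 K trainable-parameter budget.
    """

    num_classes: int = 3               # background + k instrument classes
    stem_channels: int = 14
    stage_depths: tuple = (2, 2, 6, 2)
    growth_rates: tuple = (14, 14, 38, 200)
    compression: float = 0.5
    fpn_channels: int = 64
    level_channels: int = 16           # per-level contribution to the fused map
    use_fpn: bool = True
    use_ccam: bool = True
    ccam_reduction: int = 8            # B = max(1, C // ccam_reduction)
    seed: int = 0

    def validate(self):
        if len(self.stage_depths) != 4 or len(self.growth_rates) != 4:
            raise ValueError("exactly four stages are required")
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("stage depths must be >= 1")
        if self.num_classes < 2:
            raise ValueError("need at least background + one class")
        if 4 * self.level_channels != self.fused_channels:
            raise ValueError("four levels must concatenate to the fused width")
        if self.ccam_reduction < 2:
            raise ValueError("ccam_reduction must be >= 2 (B < C)")
        return self

    @property
    def fused_channels(self):
        return 4 * self.level_channels


@dataclass
class TrainConfig:
    """Optimization protocol: AdamW at 1e-3 with ReduceLROnPlateau, focal
    loss, validation every two epochs and retention of the five best
    checkpoints by validation mIoU."""

    epochs: int = 100
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 8
    val_every: int = 2
    top_k_checkpoints: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-6
    gamma: float = 2.0                 # focal-loss focusing parameter
    alpha: float = 0.25                # foreground/background balance
    mixed_precision: bool = False
    reader_threads: int = 16
    seed: int = 0

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.top_k_checkpoints < 1:
            raise ValueError("top_k_checkpoints must be >= 1")
        if self.val_every < 1:
            raise ValueError("val_every must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        return self


def _to_plain(obj):
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_config(path, model: ModelConfig = None, train: TrainConfig = None,
                scene: SceneConfig = None):
    doc = {}
    if model is not None:
        doc["model"] = _to_plain(model)
    if train is not None:
        doc["train"] = _to_plain(train)
    if scene is not None:
        doc["scene"] = _to_plain(scene)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _from_plain(cls, d):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path):
    """Return a dict with whichever of model/train/scene the YAML contains."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "model" in doc:
        out["model"] = _from_plain(ModelConfig, doc["model"]).validate()
    if "train" in doc:
        out["train"] = _from_plain(TrainConfig, doc["train"]).validate()
    if "scene" in doc:
        out["scene"] = _from_plain(SceneConfig, doc["scene"]).validate()
    return out
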