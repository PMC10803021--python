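"""Synthetic endoscopy scenes and dataset preparation.

Scenes emulate the statistics of endoscopic instrument frames without any
claim of photorealism: a dark reddish tissue background with low-frequency
texture and radial vignetting, one or two elongated metallic instruments
drawn as rotated capsules (rectangle plus semicircular tip) entering from a
frame edge with a brightness gradient along the shaft, a few specular
highlights, and Gaussian pixel noise.  Instruments occupy a small fraction
of pixels, reproducing the strong class imbalance of real frames.

Dataset preparation follows the 60/20/20 convention: a seeded shuffle, then
validation and test each take round(0.2 * N) items and training the
remainder — the rule that maps 2,344 frames to 1,406 / 469 / 469.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .config import SceneConfig
from .nn.tensor import resize_matrix

FRACTIONS = (0.6, 0.2, 0.2)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _capsule_mask(size, p0, direction, length, width):
    """Boolean mask of a capsule: points within width/2 of a segment."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    d = direction / np.linalg.norm(direction)
    p1 = p0 + d * length
    rel_y = yy - p0[0]
    rel_x = xx - p0[1]
    t = np.clip(rel_y * d[0] + rel_x * d[1], 0.0, length)
    dy = rel_y - t * d[0]
    dx = rel_x - t * d[1]
    dist2 = dy * dy + dx * dx
    return dist2 <= (width / 2.0) ** 2, t / max(length, 1e-6)


def _draw_instruments(cfg: SceneConfig, rng, min_w, max_w):
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=np.uint8)
    shading = np.zeros((size, size), dtype=np.float32)
    edges = rng.permutation(4)
    for i in range(cfg.n_instruments):
        label = (i % cfg.instrument_classes) + 1
        edge = edges[i % 4]
        pos = rng.uniform(0.15, 0.85) * size
        if edge == 0:    # top
            p0, inward = np.array([0.0, pos]), np.array([1.0, 0.0])
        elif edge == 1:  # bottom
            p0, inward = np.array([size - 1.0, pos]), np.array([-1.0, 0.0])
        elif edge == 2:  # left
            p0, inward = np.array([pos, 0.0]), np.array([0.0, 1.0])
        else:            # right
            p0, inward = np.array([pos, size - 1.0]), np.array([0.0, -1.0])
        angle = rng.uniform(-0.5, 0.5)  # radians around the inward normal
        c, s = np.cos(angle), np.sin(angle)
        d = np.array([c * inward[0] - s * inward[1],
                      s * inward[0] + c * inward[1]])
        length = rng.uniform(0.45, 0.85) * size
        width = rng.uniform(min_w, max_w)
        cap, along = _capsule_mask(size, p0, d, length, width)
        mask[cap] = label
        # brighter toward the tip: mimics metallic shafts catching the light
        shade = 0.55 + 0.30 * along + 0.05 * rng.standard_normal()
        shading[cap] = np.clip(shade[cap], 0.35, 0.95)
    return mask, shading


def generate_scene(config: SceneConfig):
    """Return (image, mask): image (H,W,3) float in [0,1], mask (H,W) uint8.

    Fully determined by ``config.seed``; labels are a subset of
    {0, .., instrument_classes} and instruments cover between 0 and 50% of
    the pixels.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size

    # tissue background: reddish base + smooth texture + vignette
    base = cfg.background_base_intensity
    texture = gaussian_filter(rng.standard_normal((size, size)),
                              sigma=max(2.0, size / 16.0))
    texture = texture / (np.abs(texture).max() + 1e-8)
    lum = np.clip(base * (1.0 + 0.35 * texture), 0.02, 1.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    r2 = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / ((size / 2) ** 2)
    vignette = 1.0 - cfg.vignette_strength * np.clip(r2, 0.0, 1.0)
    lum = lum * vignette
    image = np.stack([lum, lum * 0.45, lum * 0.38], axis=-1)

    # instruments; shrink widths if they would dominate the frame
    mask = np.zeros((size, size), dtype=np.uint8)
    shading = np.zeros((size, size), dtype=np.float32)
    if cfg.n_instruments > 0:
        min_w, max_w = float(cfg.min_instrument_width), float(cfg.max_instrument_width)
        for _ in range(4):
            draw_rng = np.random.default_rng(cfg.seed + 1)
            mask, shading = _draw_instruments(cfg, draw_rng, min_w, max_w)
            if mask.astype(bool).mean() < 0.45:
                break
            min_w, max_w = max(1.0, min_w / 2), max(1.0, max_w / 2)

    fg = mask > 0
    metal = shading[..., None] * np.array([1.0, 1.02, 1.06], dtype=np.float32)
    image = np.where(fg[..., None], metal * vignette[..., None], image)

    # specular highlights: small saturated blobs
    for _ in range(cfg.specular_count):
        cy, cx = rng.uniform(0.1, 0.9, size=2) * size
        rad = rng.uniform(0.01, 0.03) * size
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * rad ** 2)))
        image = image + 0.8 * blob[..., None]

    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0).astype(np.float32), mask


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Disjoint train/val/test index lists covering 0..N-1."""

    train_indices: list
    val_indices: list
    test_indices: list
    seed: int
    fractions: tuple = FRACTIONS

    def sizes(self):
        return (len(self.train_indices), len(self.val_indices),
                len(self.test_indices))

    def validate(self):
        all_idx = (list(self.train_indices) + list(self.val_indices)
                   + list(self.test_indices))
        n = len(all_idx)
        if sorted(all_idx) != list(range(n)):
            raise ValueError("split indices must partition 0..N-1")
        return self


def _round_nearest(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(n_total: int, fractions=FRACTIONS, seed: int = 0) -> SplitSpec:
    """Seeded shuffled 60/20/20 split.

    Validation and test each get round(0.2 * N) items; training takes the
    remainder (1,406 / 469 / 469 for N = 2,344).
    """
    if tuple(fractions) != FRACTIONS:
        raise ValueError("only the 60/20/20 split is supported")
    if n_total < 5:
        raise ValueError("need at least 5 items for non-empty subsets")
    n_val = _round_nearest(0.2 * n_total)
    n_test = _round_nearest(0.2 * n_total)
    n_train = n_total - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split would produce an empty subset")
    perm = np.random.default_rng(seed).permutation(n_total)
    return SplitSpec(
        train_indices=perm[:n_train].tolist(),
        val_indices=perm[n_train:n_train + n_val].tolist(),
        test_indices=perm[n_train + n_val:].tolist(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_pair(image, mask, target_size: int):
    """Resize an (H,W,3) image bilinearly and an (H,W) mask by nearest
    neighbour to target_size x target_size.

    Nearest-neighbour convention: output pixel i samples source index
    floor((i + 0.5) * S / target) (half-pixel centers), so the resized mask's
    labels are a subset of the original's.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask spatial shapes differ")
    h, w = mask.shape
    mh = resize_matrix(target_size, h)
    mw = resize_matrix(target_size, w)
    out_img = np.einsum("Hh,hwc->Hwc", mh, image.astype(np.float32))
    out_img = np.einsum("Ww,hwc->hWc", mw, out_img)
    src_r = nearest_indices(target_size, h)
    src_c = nearest_indices(target_size, w)
    out_mask = mask[np.ix_(src_r, src_c)]
    return np.clip(out_img, 0.0, 1.0), out_mask


def nearest_indices(n_out: int, n_in: int):
    """Source indices of the declared nearest-neighbour convention."""
    return np.minimum((np.floor((np.arange(n_out) + 0.5) * n_in / n_out))
                      .astype(int), n_in - 1)


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Pairs of image/mask PNG paths plus the class count and image size."""

    pairs: list = field(default_factory=list)  # (image_path, mask_path)
    num_classes: int = 2                       # instrument classes k
    image_size: int = 256

    def __len__(self):
        return len(self.pairs)

    def save(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_path", "mask_path"])
            for img, msk in self.pairs:
                writer.writerow([img, msk])

    @classmethod
    def load(cls, path, num_classes=2, image_size=None):
        pairs = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header[:2] != ["image_path", "mask_path"]:
                raise ValueError(f"not a dataset manifest: {path}")
            for row in reader:
                pairs.append((row[0], row[1]))
        if image_size is None and pairs:
            with Image.open(pairs[0][0]) as im:
                image_size = im.size[0]
        return cls(pairs=pairs, num_classes=num_classes,
                   image_size=image_size or 256)

    def validate(self):
        for img, msk in self.pairs:
            if not Path(img).exists():
                raise FileNotFoundError(img)
            if not Path(msk).exists():
                raise FileNotFoundError(msk)
            with Image.open(img) as a, Image.open(msk) as b:
                if a.size != b.size:
                    raise ValueError(f"size mismatch for pair {img} / {msk}")
        return self


def write_dataset(n: int, scene_config: SceneConfig, out_dir) -> DatasetManifest:
    """Write ``n`` image/mask PNG pairs (8-bit RGB / 8-bit label-indexed).

    Per-scene seeds are derived deterministically from the config seed, so
    the same call produces bitwise-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    manifest = DatasetManifest(num_classes=scene_config.instrument_classes,
                               image_size=scene_config.image_size)
    seed_rng = np.random.default_rng(scene_config.seed)
    seeds = seed_rng.integers(0, 2 ** 31 - 1, size=n)
    for i in range(n):
        cfg_i = SceneConfig(**{**scene_config.__dict__, "seed": int(seeds[i])})
        image, mask = generate_scene(cfg_i)
        img_path = out_dir / f"frame_{i:04d}.png"
        msk_path = out_dir / f"frame_{i:04d}_mask.png"
        Image.fromarray((image * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray(mask, mode="L").save(msk_path)
        manifest.pairs.append((str(img_path), str(msk_path)))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_pair(image_path, mask_path):
    """Read one pair back as ((3,H,W) float32 in [0,1], (H,W) int64)."""
    with Image.open(image_path) as im:
        image = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    with Image.open(mask_path) as im:
        mask = np.asarray(im.convert("L"), dtype=np.int64)
    return image.transpose(2, 0, 1), mask
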