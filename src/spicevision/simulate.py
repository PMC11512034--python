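"""Synthetic powder-image generator.

Emulates visible photographs of powdered spice mixed with a light mineral
adulterant (meerschaum, "sea foam") at mass fractions w in {0, 5, 15, 30,
50}%.  An image is a granular mosaic: the frame is partitioned into grains
of characteristic diameter ``grain_scale`` (a jittered-grid Voronoi
tessellation, so grain shape varies but size is controlled); each grain is
adulterant with probability w and base powder otherwise, colored with the
palette mean plus per-grain Gaussian jitter; a smooth zero-mean
multiplicative illumination field and additive Gaussian sensor noise are
applied on top and the result is clipped to [0, 1].

With illumination off, the expected per-channel image mean is the convex
combination (1-w) * base_mean + w * adulterant_mean, so mean brightness
rises and saturation falls monotonically with w when the adulterant is
lighter and less chromatic than the base — the signal the whole detection
pipeline exploits.

Default palettes: the base pepper means anchor to measured pure-powder
reflectances (black pepper ~ (0.55, 0.46, 0.33), gray ~ 0.47); the sea-foam
mean (0.87, 0.85, 0.82) is a calibration default extrapolating the observed
brightening of 50% mixtures to w = 1, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class PowderPalette:
    """Color model of one powdered material."""

    mean_rgb: tuple[float, float, float]
    rgb_jitter_sd: tuple[float, float, float] = (0.05, 0.05, 0.05)
    name: str = "powder"

    def __post_init__(self) -> None:
        if not all(0.0 <= v <= 1.0 for v in self.mean_rgb):
            raise ValueError("mean_rgb components must lie in [0, 1]")
        if not all(0.0 <= v < 0.5 for v in self.rgb_jitter_sd):
            raise ValueError("rgb_jitter_sd must lie in [0, 0.5)")


BLACK_PEPPER = PowderPalette(mean_rgb=(0.55, 0.46, 0.33), name="black_pepper")
RED_PEPPER = PowderPalette(mean_rgb=(0.62, 0.37, 0.10), name="red_pepper")
SEA_FOAM = PowderPalette(mean_rgb=(0.87, 0.85, 0.82),
                         rgb_jitter_sd=(0.03, 0.03, 0.03), name="sea_foam")

DEFAULT_LEVELS: tuple[float, ...] = (0.0, 0.05, 0.15, 0.30, 0.50)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one simulated imaging campaign."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    images_per_level: int = 18
    image_size: tuple[int, int] = (256, 256)
    grain_scale: float = 6.0
    illumination_gradient: float = 0.05
    sensor_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lv = tuple(float(v) for v in self.levels)
        if lv != tuple(sorted(set(lv))):
            raise ValueError("levels must be sorted ascending and unique")
        if not all(0.0 <= v <= 1.0 for v in lv):
            raise ValueError("levels must lie in [0, 1]")
        object.__setattr__(self, "levels", lv)
        if self.images_per_level < 1:
            raise ValueError("images_per_level must be >= 1")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32 x 32")
        if not 0.0 <= self.illumination_gradient <= 0.2:
            raise ValueError("illumination_gradient must lie in [0, 0.2]")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.grain_scale < 1:
            raise ValueError("grain_scale must be >= 1 pixel")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        if "levels" in kwargs:
            kwargs["levels"] = tuple(kwargs["levels"])
        if "image_size" in kwargs:
            kwargs["image_size"] = tuple(kwargs["image_size"])
        return cls(**kwargs)


@dataclass
class LabeledImageSet:
    """Generated images with 1-based class labels and level fractions."""

    images: list[np.ndarray] = field(repr=False)
    labels: list[int] = field(repr=False)
    level_values: list[float] = field(default_factory=list)
    seed_used: int = 0
    material: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels disagree on count")
        k = len(self.level_values)
        if k and not all(1 <= lab <= k for lab in self.labels):
            raise ValueError("labels must lie in 1..K")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def per_sample_levels(self) -> np.ndarray:
        return np.array([self.level_values[lab - 1] for lab in self.labels])


def _grain_labels(shape: tuple[int, int], grain_scale: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Jittered-grid Voronoi tessellation: pixel -> grain index."""
    h, w = shape
    step = max(1.0, float(grain_scale))
    gy = np.arange(step / 2, h, step)
    gx = np.arange(step / 2, w, step)
    cy, cx = np.meshgrid(gy, gx, indexing="ij")
    seeds = np.column_stack([cy.ravel(), cx.ravel()])
    seeds += rng.uniform(-step / 2, step / 2, size=seeds.shape)
    ry, rx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pixels = np.column_stack([ry.ravel(), rx.ravel()]).astype(float)
    _, nearest = cKDTree(seeds).query(pixels, k=1)
    return nearest.reshape(h, w), len(seeds)


def _illumination_field(shape: tuple[int, int], amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + f with f zero-mean, |f| <= amplitude."""
    h, w = shape
    noise = rng.standard_normal((h, w))
    smooth = gaussian_filter(noise, sigma=min(h, w) / 4.0, mode="reflect")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= amplitude / peak
    return 1.0 + smooth


def generate_powder_image(
    base: PowderPalette,
    adulterant: PowderPalette,
    w: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One H x W x 3 image of base powder adulterated at mass fraction w."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"adulterant fraction w must lie in [0, 1], got {w}")
    h, wd = cfg.image_size
    labels, n_grains = _grain_labels((h, wd), cfg.grain_scale, rng)

    is_adult = rng.random(n_grains) < w
    grain_rgb = np.empty((n_grains, 3))
    for pal, mask in ((base, ~is_adult), (adulterant, is_adult)):
        k = int(mask.sum())
        if k:
            jitter = rng.standard_normal((k, 3)) * np.asarray(pal.rgb_jitter_sd)
            grain_rgb[mask] = np.asarray(pal.mean_rgb) + jitter
    grain_rgb = np.clip(grain_rgb, 0.0, 1.0)

    img = grain_rgb[labels]
    if cfg.illumination_gradient > 0:
        img = img * _illumination_field((h, wd), cfg.illumination_gradient, rng)[..., None]
    if cfg.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.sensor_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    base: PowderPalette,
    adulterant: PowderPalette = SEA_FOAM,
    cfg: SimConfig = SimConfig(),
) -> LabeledImageSet:
    """images_per_level images at every adulteration level, reproducibly."""
    rng = np.random.default_rng(cfg.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for class_index, w in enumerate(cfg.levels, start=1):
        for _ in range(cfg.images_per_level):
            images.append(generate_powder_image(base, adulterant, w, cfg, rng))
            labels.append(class_index)
    return LabeledImageSet(images=images, labels=labels,
                           level_values=list(cfg.levels),
                           seed_used=cfg.seed, material=base.name)


def write_dataset(imgset: LabeledImageSet, out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write 8-bit PNGs plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = imgset.seed_used if seed is None else seed
    records = []
    counters: dict[int, int] = {}
    for img, lab in zip(imgset.images, imgset.labels):
        idx = counters.get(lab, 0)
        counters[lab] = idx + 1
        level = imgset.level_values[lab - 1]
        fname = f"{imgset.material or 'powder'}_L{round(level * 100):02d}_{idx:03d}.png"
        iio.imwrite(out_dir / fname, (np.round(img * 255)).astype(np.uint8))
        records.append({"filename": fname, "class_index": lab,
                        "level_fraction": level, "seed": seed})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path, material: str = "") -> LabeledImageSet:
    """Reload a written dataset from its manifest CSV."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    images = [np.asarray(iio.imread(manifest.parent / f), dtype=float) / 255.0
              for f in df["filename"]]
    level_values = sorted(df["level_fraction"].unique())
    return LabeledImageSet(images=images, labels=df["class_index"].tolist(),
                           level_values=[float(v) for v in level_values],
                           seed_used=int(df["seed"].iloc[0]) if len(df) else 0,
                           material=material)
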