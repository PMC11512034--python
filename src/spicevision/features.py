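"""Per-channel color statistics and GLCM texture features.

Each of the 19 channels contributes 14 scalars: nine first-order color
statistics (mean, min, max, median, mode, standard deviation, coefficient
of variation, skewness, kurtosis), a first-order histogram entropy, and
four gray-level co-occurrence (GLCM) texture features (energy, contrast,
correlation, homogeneity) — 266 features per image.

Numerical conventions, chosen to keep feature vectors finite on degenerate
(e.g. perfectly constant) planes:

* std is the sample standard deviation (n-1); cv = std/mean with cv = 0
  when the mean is 0.
* skewness = m3 / m2^1.5 and kurtosis = m4 / m2^2 (non-excess, so a
  Gaussian plane gives ~3), with 1/n central moments; both 0 when m2 = 0.
* mode is the center of the argmax bin of a 256-bin histogram over the
  plane's native range (ties -> lowest bin), reflecting 8-bit provenance.
* entropy is the Shannon entropy in bits of the normalized 256-bin
  histogram (first order, not GLCM entropy).
* GLCM: the plane is quantized to ``levels`` equal-width bins over its own
  [min, max]; co-occurrence counts are accumulated over all offsets into a
  single matrix, symmetrized, and normalized to sum 1.  GLCM correlation is
  defined as 1 when either marginal is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .color import CHANNEL_NAMES, ChannelStack

#: Statistic order inside each channel block of the feature vector.
STAT_NAMES: tuple[str, ...] = (
    "mean", "min", "max", "median", "mode", "std", "cv",
    "skewness", "kurtosis",
    "energy", "entropy", "contrast", "correlation", "homogeneity",
)

#: Default co-occurrence offsets: distance 1 in the four standard
#: directions (0, 45, 90, 135 degrees), accumulated into one matrix.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ch}" for ch in CHANNEL_NAMES for stat in STAT_NAMES
)
N_FEATURES = len(FEATURE_NAMES)  # 19 * 14 = 266


def channel_stats(plane: np.ndarray, hist_bins: int = 256) -> dict[str, float]:
    """The nine first-order color statistics of one scalar plane."""
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("empty plane")
    x = plane.ravel()
    n = x.size
    mean = float(x.mean())
    lo, hi = float(x.min()), float(x.max())
    median = float(np.median(x))
    if lo == hi:
        mode = lo
    else:
        counts, edges = np.histogram(x, bins=hist_bins, range=(lo, hi))
        k = int(np.argmax(counts))
        mode = float(0.5 * (edges[k] + edges[k + 1]))
    std = float(x.std(ddof=1)) if n > 1 else 0.0
    cv = std / mean if mean != 0.0 else 0.0
    d = x - mean
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d ** 3)) / m2 ** 1.5
        kurt = float(np.mean(d ** 4)) / m2 ** 2
    return {
        "mean": mean, "min": lo, "max": hi, "median": median, "mode": mode,
        "std": std, "cv": cv, "skewness": skew, "kurtosis": kurt,
    }


def histogram_entropy(plane: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the plane's normalized histogram."""
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("empty plane")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = plane.ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class GLCM:
    """Normalized joint distribution of quantized gray-level pairs."""

    matrix: np.ndarray = field(repr=False)
    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be levels x levels")
        if abs(self.matrix.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must sum to 1")
        if self.symmetric and not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("symmetric flag set but matrix is not symmetric")


def quantize_plane(plane: np.ndarray, levels: int) -> np.ndarray:
    """Quantize to ``levels`` equal-width bins over the plane's own range."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if lo == hi:
        return np.zeros(plane.shape, dtype=np.intp)
    q = np.floor((plane - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm_compute(
    plane: np.ndarray,
    levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """Gray-level co-occurrence matrix accumulated over all offsets."""
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("empty plane")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize_plane(plane, levels)
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        # single-pixel plane with no valid pairs: put all mass at (0, 0)
        counts[0, 0] = 1.0
        total = 1.0
    return GLCM(matrix=counts / total, levels=levels,
                offsets=tuple(offsets), symmetric=symmetric)


def glcm_features(g: GLCM) -> dict[str, float]:
    """Energy, contrast, correlation and homogeneity of a GLCM."""
    p = g.matrix
    idx = np.arange(g.levels, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    energy = float((p * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    var_i = float(((idx - mu_i) ** 2 * pi).sum())
    var_j = float(((idx - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 1.0
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum() / denom)
    return {
        "energy": energy, "contrast": contrast,
        "correlation": correlation, "homogeneity": homogeneity,
    }


def extract_features(
    stack: ChannelStack,
    glcm_levels: int = 8,
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    hist_bins: int = 256,
) -> dict[str, float]:
    """The full 266-entry named feature vector of one channel stack."""
    out: dict[str, float] = {}
    for name, plane in stack:
        stats = channel_stats(plane, hist_bins=hist_bins)
        tex = glcm_features(glcm_compute(plane, levels=glcm_levels, offsets=glcm_offsets))
        ent = histogram_entropy(plane, bins=hist_bins)
        block = {**stats, **tex, "entropy": ent}
        for stat in STAT_NAMES:
            out[f"{stat}_{name}"] = block[stat]
    assert len(out) == N_FEATURES
    return out


@dataclass
class FeatureTable:
    """n_samples x 266 feature matrix with class labels.

    ``labels`` are 1-based class indices; ``levels`` optionally carries the
    adulterant mass fraction of each sample.
    """

    features: pd.DataFrame = field(repr=False)
    labels: np.ndarray = field(repr=False)
    levels: np.ndarray | None = field(default=None, repr=False)
    material: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree on sample count")
        if self.levels is not None:
            self.levels = np.asarray(self.levels, dtype=float)
            if len(self.levels) != len(self.labels):
                raise ValueError("levels and labels disagree on sample count")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def take(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices)
        return FeatureTable(
            features=self.features.iloc[indices].reset_index(drop=True),
            labels=self.labels[indices],
            levels=None if self.levels is None else self.levels[indices],
            material=self.material,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.features.copy()
        df.insert(0, "class_index", self.labels)
        if self.levels is not None:
            df.insert(1, "level_fraction", self.levels)
        df.insert(0, "sample_id", [f"{self.material or 'sample'}_{i:03d}"
                                   for i in range(len(df))])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, material: str = "") -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("class_index").to_numpy()
        levels = df.pop("level_fraction").to_numpy() if "level_fraction" in df else None
        df = df.drop(columns=["sample_id"], errors="ignore")
        return cls(features=df, labels=labels, levels=levels, material=material)


def build_feature_table(
    images: list[np.ndarray],
    labels: np.ndarray,
    levels: np.ndarray | None = None,
    material: str = "",
    crop_keep: float = 1.0,
    **feature_kwargs,
) -> FeatureTable:
    """Crop, decompose and featurize a list of RGB images into one table."""
    from .color import crop_center, to_channels

    rows = []
    for img in images:
        if crop_keep < 1.0:
            img = crop_center(img, crop_keep)
        rows.append(extract_features(to_channels(img), **feature_kwargs))
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return FeatureTable(features=df, labels=np.asarray(labels),
                        levels=levels, material=material)
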