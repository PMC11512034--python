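"""Crop preprocessing and decomposition of an RGB image into 19 scalar channels.

A powder photograph is reduced to one :class:`ChannelStack` holding the
R, G, B planes plus the derived CIELAB (L*, a*, b*), HSV, chromaticity
(NR, NG, NB), opponent-offset (Cr, Cg, Cb), Ohta (I1, I2, I3) and luma
(gray) planes — 19 planes in total, each the same shape as the source.

Conventions
-----------
* Input images are H x W x 3 float arrays with values in [0, 1], channel
  order R, G, B.
* gray uses the ITU-R BT.601 luma weights 0.2989 / 0.5870 / 0.1140.
* H, S, V are all scaled to [0, 1]; L* is on the usual 0-100 scale with
  sRGB companding and the D65 white point.
* Chromaticity at black pixels (R+G+B = 0) is defined as (1/3, 1/3, 1/3)
  so that image statistics never see NaN.
* Cr, Cg, Cb are the per-pixel deviations from the unweighted RGB mean:
  Cr = R - (R+G+B)/3 and cyclically, so Cr + Cg + Cb = 0 identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

#: Canonical channel order used everywhere downstream (feature names,
#: CSV columns, selection indices).
CHANNEL_NAMES: tuple[str, ...] = (
    "R", "G", "B",
    "Lstar", "astar", "bstar",
    "H", "S", "V",
    "NR", "NG", "NB",
    "Cr", "Cg", "Cb",
    "I1", "I2", "I3",
    "gray",
)

#: BT.601 luma weights.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("RGB values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


@dataclass
class ChannelStack:
    """The 19 named scalar planes derived from one RGB image."""

    planes: dict[str, np.ndarray] = field(repr=False)
    source_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        missing = set(CHANNEL_NAMES) - set(self.planes)
        extra = set(self.planes) - set(CHANNEL_NAMES)
        if missing or extra:
            raise ValueError(f"channel set mismatch: missing={missing}, extra={extra}")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError("all planes must share one shape")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.planes[name]

    def __iter__(self):
        for name in CHANNEL_NAMES:
            yield name, self.planes[name]


def crop_center(img: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Return the centered ``keep_fraction`` window of an image.

    Output dimensions are ``floor(keep_fraction * H) x floor(keep_fraction * W)``;
    on an odd remainder the window sits one pixel closer to the top/left.
    """
    img = _as_rgb(img)
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    h0, w0 = img.shape[:2]
    h = int(np.floor(h0 * keep_fraction))
    w = int(np.floor(w0 * keep_fraction))
    if h < 1 or w < 1:
        raise ValueError("crop would produce an empty image")
    r0 = (h0 - h) // 2
    c0 = (w0 - w) // 2
    return img[r0:r0 + h, c0:c0 + w]


def to_channels(img: np.ndarray) -> ChannelStack:
    """Decompose an RGB image into the 19 canonical scalar planes."""
    img = _as_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    s = r + g + b

    hsv = _skcolor.rgb2hsv(img)
    hsv = np.nan_to_num(hsv, nan=0.0)
    lab = _skcolor.rgb2lab(img)

    with np.errstate(divide="ignore", invalid="ignore"):
        nr = np.where(s > 0, r / s, 1.0 / 3.0)
        ng = np.where(s > 0, g / s, 1.0 / 3.0)
        nb = np.where(s > 0, b / s, 1.0 / 3.0)

    i1 = s / 3.0
    i2 = (r - b) / 2.0
    i3 = (2.0 * g - r - b) / 4.0

    gray = GRAY_WEIGHTS[0] * r + GRAY_WEIGHTS[1] * g + GRAY_WEIGHTS[2] * b

    planes = {
        "R": r, "G": g, "B": b,
        "Lstar": lab[..., 0], "astar": lab[..., 1], "bstar": lab[..., 2],
        "H": hsv[..., 0], "S": hsv[..., 1], "V": hsv[..., 2],
        "NR": nr, "NG": ng, "NB": nb,
        "Cr": r - i1, "Cg": g - i1, "Cb": b - i1,
        "I1": i1, "I2": i2, "I3": i3,
        "gray": gray,
    }
    return ChannelStack(planes={k: np.ascontiguousarray(v) for k, v in planes.items()},
                        source_shape=img.shape[:2])
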