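"""Replicate averaging, color-space conversions, per-fruit feature extraction.

Each fruit is photographed several times under identical settings; the
per-pixel mean of the replicate stack suppresses sensor noise (variance of
the mean scales as 1/m).  From the averaged image and a foreground mask the
per-fruit predictors used by the sugar models are computed:

* ``x_p`` -- foreground fraction, a proxy for fruit size/volume;
* ``x_h`` -- mean HSI hue over the foreground, kept in radians (the raw
  arccos angle; citrus hues fall around 0.36-0.71 rad, red to yellow);
* ``x_g`` -- mean green channel / 255;
* ``x_y`` -- mean of the synthetic yellow channel ``Y = (G + R) / 2``,
  divided by 255.

Raw channel means, HSI saturation/intensity means and CIELAB means are also
reported.  Normalisations are fixed physical ones (divide by 255; fractions
of the frame) so that fitted model parameters stay comparable across
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from skimage import color as _skcolor

from .errors import InvalidInputError
from .segmentation import BinaryMask

__all__ = [
    "FeatureVector",
    "average_images",
    "rgb_to_hsi",
    "rgb_to_lab",
    "compute_features",
]

TWO_PI = 2.0 * np.pi


@dataclass
class FeatureVector:
    """Per-fruit predictors and auxiliary color statistics (all foreground means)."""

    x_p: float
    x_h: float
    x_g: float
    x_y: float
    r_mean: float
    g_mean: float
    b_mean: float
    s_mean: float
    i_mean: float
    l_mean: float
    a_mean: float
    b_lab_mean: float
    x_w: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_p <= 1.0:
            raise InvalidInputError(f"x_p must lie in [0, 1], got {self.x_p}")
        if not 0.0 <= self.x_h < TWO_PI:
            raise InvalidInputError(f"x_h must lie in [0, 2*pi), got {self.x_h}")
        for name in ("x_g", "x_y"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
        if self.x_w is not None and not self.x_w > 0:
            raise InvalidInputError(f"weight x_w must be positive, got {self.x_w}")


def _check_rgb(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise InvalidInputError(f"expected a trailing RGB axis of size 3, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("channel values must lie in [0, 255]")
    return arr


def average_images(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel, per-channel mean of a replicate stack, rounded half-up.

    All images must share the same shape.  A five-consecutive-shot protocol
    is typical; any m >= 1 is accepted.
    """
    if len(stack) == 0:
        raise InvalidInputError("image stack is empty")
    arrs = [np.asarray(a) for a in stack]
    shape = arrs[0].shape
    for k, a in enumerate(arrs):
        if a.shape != shape:
            raise InvalidInputError(f"image {k} has shape {a.shape}, expected {shape}")
    mean = np.mean([a.astype(np.float64) for a in arrs], axis=0)
    return np.floor(mean + 0.5).astype(np.uint8)  # round half-up


def rgb_to_hsi(rgb: Sequence[float]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB (0-255) to the HSI model used for the hue predictor.

    * ``I = (R + G + B) / 3`` (gray value);
    * ``S = 1 - 3 min(R, G, B) / (R + G + B)`` (0 for a black pixel);
    * ``H``: the angle ``theta = arccos{[(R-G) + (R-B)] /
      (2 sqrt((R-G)^2 + (R-B)(G-B)))}`` in radians, reflected to
      ``2*pi - theta`` when ``B > G``.  Achromatic pixels (R = G = B) have
      no defined hue and return ``H = 0``.

    Accepts a single ``(R, G, B)`` triple or any array with a trailing RGB
    axis; returns (H, S, I) with the leading shape preserved (scalars for a
    triple).
    """
    arr = _check_rgb(np.asarray(rgb, dtype=np.float64))
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    i = total / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
    num = (r - g) + (r - b)
    rad = (r - g) ** 2 + (r - b) * (g - b)
    achromatic = rad <= 0  # rad == 0 iff R = G = B
    denom = 2.0 * np.sqrt(np.where(achromatic, 1.0, rad))
    cosang = np.clip(np.where(achromatic, 1.0, num) / denom, -1.0, 1.0)
    theta = np.arccos(cosang)
    h = np.where(b > g, TWO_PI - theta, theta)
    h = np.where(achromatic, 0.0, h)
    if arr.ndim == 1:
        return float(h), float(s), float(i)
    return h, s, i


def rgb_to_lab(rgb: Sequence[float]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard sRGB (D65) -> CIELAB conversion of 0-255 channel values.

    Thin wrapper over :func:`skimage.color.rgb2lab`; accepts a triple or an
    array with a trailing RGB axis.
    """
    arr = _check_rgb(np.asarray(rgb, dtype=np.float64))
    lab = _skcolor.rgb2lab(arr / 255.0)
    if arr.ndim == 1:
        return float(lab[0]), float(lab[1]), float(lab[2])
    return lab[..., 0], lab[..., 1], lab[..., 2]


def compute_features(
    image: np.ndarray,
    mask: BinaryMask,
    weight: Optional[float] = None,
    hue_mode: Literal["per_pixel", "mean_rgb"] = "per_pixel",
) -> FeatureVector:
    """Extract the per-fruit feature vector from a segmented image.

    Channel means are taken over foreground pixels only and kept at full
    floating precision.  The hue mean excludes achromatic pixels (their hue
    is undefined); if every foreground pixel is achromatic, ``x_h = 0``.
    ``hue_mode="mean_rgb"`` instead converts the mean RGB triple to HSI and
    takes its hue.  Note the hue mean is an arithmetic mean of angles, which
    is adequate because fruit hues sit far from the 0/2*pi wrap.
    """
    arr = _check_rgb(np.asarray(image))
    if arr.ndim != 3:
        raise InvalidInputError("expected an HxWx3 image")
    if mask.values.shape != arr.shape[:2]:
        raise InvalidInputError(
            f"mask shape {mask.values.shape} does not match image {arr.shape[:2]}"
        )
    nf = mask.nf
    if nf == 0:
        raise InvalidInputError("mask is empty: no foreground pixels to summarise")

    fg = arr[mask.values]  # (Nf, 3)
    r_mean, g_mean, b_mean = (float(m) for m in fg.mean(axis=0))

    h, s, i = rgb_to_hsi(fg)
    chromatic = ~((fg[:, 0] == fg[:, 1]) & (fg[:, 1] == fg[:, 2]))
    if hue_mode == "mean_rgb":
        x_h = rgb_to_hsi((r_mean, g_mean, b_mean))[0]
    elif hue_mode == "per_pixel":
        x_h = float(h[chromatic].mean()) if chromatic.any() else 0.0
    else:
        raise InvalidInputError(f"unknown hue_mode {hue_mode!r}")

    l, a, b_lab = rgb_to_lab(fg)

    return FeatureVector(
        x_p=nf / (arr.shape[0] * arr.shape[1]),
        x_h=x_h,
        x_g=g_mean / 255.0,
        x_y=(g_mean + r_mean) / (2.0 * 255.0),
        r_mean=r_mean,
        g_mean=g_mean,
        b_mean=b_mean,
        s_mean=float(np.mean(s)),
        i_mean=float(np.mean(i)),
        l_mean=float(np.mean(l)),
        a_mean=float(np.mean(a)),
        b_lab_mean=float(np.mean(b_lab)),
        x_w=weight,
    )
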