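"""Coefficient-of-determination (R^2) window segmentation.

A reference window around a user-chosen point inside the fruit serves as
the *target region*.  For every pixel of the image, the gray values inside
the ``(2i+1) x (2i+1)`` window centred on that pixel are correlated with
the target region (windows are paired offset by offset), and the squared
correlation

    R^2 = Cov^2(x, y) / (Var(x) * Var(y))

is compared with a threshold: pixels whose window correlates with the
target region more strongly than the threshold are labelled foreground.
Because R^2 is invariant under affine rescaling of either window, the
decision depends on local *pattern*, not on absolute brightness.

Segmentation quality is quantified by the percent error

    Er = 100 * (Nf / Nt - 1)

where ``Nf`` is the segmented foreground pixel count and ``Nt`` the true
one; ``Er > 0`` means background leaked into the foreground, ``Er < 0``
means foreground was lost.  ``threshold_sweep`` maps Er across a grid of
thresholds and locates the *threshold slowness section* -- the band of
thresholds over which the error is nearly flat and precision stays high,
which is the recommended operating region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "MaskSpec",
    "SegmentationConfig",
    "BinaryMask",
    "SweepResult",
    "coefficient_of_determination",
    "extract_region",
    "segment_by_r2",
    "r_squared_map",
    "segmentation_error",
    "threshold_sweep",
]

Channel = Literal["gray", "red", "green", "blue"]

#: Weights of the ITU-R BT.601 luma transform used for the default
#: "gray" comparison channel.
_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class MaskSpec:
    """Square sliding window of half-width ``i`` covering ``(2i+1)**2`` pixels."""

    i: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.i, (int, np.integer)) or self.i < 1:
            raise InvalidInputError(f"mask half-width i must be a positive integer, got {self.i!r}")

    @property
    def n(self) -> int:
        """Number of pixels in the window, ``(2i+1)**2``."""
        return (2 * self.i + 1) ** 2

    @property
    def side(self) -> int:
        return 2 * self.i + 1


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of one segmentation run.

    ``target_point`` is the (row, col) pixel the user would click inside the
    fruit; the window around it must fit entirely in the image.  ``memoize``
    selects the traversal that reuses the previous pixel's label whenever the
    current window is element-wise identical to the previous one (an
    exactness-preserving shortcut); the default vectorised traversal produces
    the same mask.
    """

    target_point: Tuple[int, int]
    mask: MaskSpec = field(default_factory=MaskSpec)
    threshold: float = 0.25
    compare_channel: Channel = "gray"
    memoize: bool = False

    def validate_for(self, image: np.ndarray) -> None:
        h, w = image.shape[:2]
        r, c = self.target_point
        i = self.mask.i
        if not (0 <= r < h and 0 <= c < w):
            raise InvalidInputError(f"target_point {self.target_point} outside {h}x{w} image")
        if not (i <= r < h - i and i <= c < w - i):
            raise InvalidInputError(
                f"window of half-width {i} around target_point {self.target_point} "
                f"does not fit inside the {h}x{w} image"
            )
        if self.compare_channel not in ("gray", "red", "green", "blue"):
            raise InvalidInputError(f"unknown compare_channel {self.compare_channel!r}")


@dataclass
class BinaryMask:
    """Dense boolean foreground indicator aligned with an image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidInputError("mask must be a 2-D boolean grid")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def nf(self) -> int:
        """Foreground pixel count ``Nf``."""
        return int(self.values.sum())


@dataclass
class SweepResult:
    """Per-threshold segmentation errors and the detected slowness interval."""

    thresholds: np.ndarray
    errors: np.ndarray  # Er, percent, signed
    precisions: np.ndarray  # 100 - |Er|
    slowness_interval: Optional[Tuple[float, float]]


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise InvalidInputError("image must be at least 3x3 for segmentation")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("channel values must lie in [0, 255]")
    return arr


def channel_values(image: np.ndarray, channel: Channel = "gray") -> np.ndarray:
    """Scalar comparison signal per pixel.

    ``gray`` is the rounded luma ``0.299 R + 0.587 G + 0.114 B``; the raw
    channels are available for experimentation.  Returns float64 with
    integer values, so exact constant-window detection is reliable.
    """
    arr = _validate_image(image).astype(np.float64)
    if channel == "gray":
        wr, wg, wb = _LUMA
        return np.rint(wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2])
    idx = {"red": 0, "green": 1, "blue": 2}[channel]
    return arr[..., idx]


def coefficient_of_determination(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared correlation ``Cov^2(x, y) / (Var(x) Var(y))`` of two vectors.

    Population moments are used (the normalisation cancels).  Degenerate
    (zero-variance) vectors are resolved by a fixed rule rather than an
    error: two constant vectors with the same value are perfectly related
    (R^2 = 1); if either vector is constant otherwise the vectors carry no
    joint variation and R^2 = 0.  A flat background patch therefore never
    matches a flat but differently-valued target region.
    """
    xv = np.asarray(x, dtype=np.float64).ravel()
    yv = np.asarray(y, dtype=np.float64).ravel()
    if xv.size != yv.size:
        raise InvalidInputError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise InvalidInputError("vectors must have length >= 2")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise InvalidInputError("vectors must be finite")
    xm = xv - xv.mean()
    ym = yv - yv.mean()
    varx = float(xm @ xm)
    vary = float(ym @ ym)
    scale = max(1.0, float(np.abs(xv).max()), float(np.abs(yv).max()))
    tol = (1e-12 * scale) ** 2 * xv.size
    if varx <= tol or vary <= tol:
        if varx <= tol and vary <= tol:
            return 1.0 if abs(xv.mean() - yv.mean()) <= 1e-12 * scale else 0.0
        return 0.0
    cov = float(xm @ ym)
    return float(min(1.0, cov * cov / (varx * vary)))


def _window_offsets(i: int):
    return [(dr, dc) for dr in range(-i, i + 1) for dc in range(-i, i + 1)]


def extract_region(
    image: np.ndarray,
    center: Tuple[int, int],
    mask: MaskSpec = MaskSpec(),
    compare_channel: Channel = "gray",
) -> np.ndarray:
    """Channel values of the window around ``center``, clipped to the image.

    Values are returned in raster order of the window offsets; offsets that
    fall outside the image are dropped (no padding is invented), so corner
    windows are shorter than interior ones.
    """
    chan = channel_values(image, compare_channel)
    h, w = chan.shape
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise InvalidInputError(f"center {center} outside {h}x{w} image")
    vals = [
        chan[r + dr, c + dc]
        for dr, dc in _window_offsets(mask.i)
        if 0 <= r + dr < h and 0 <= c + dc < w
    ]
    return np.asarray(vals, dtype=np.float64)


def r_squared_map(image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Per-pixel R^2 of each window against the target region.

    Windows are paired by identical offset; offsets clipped away at image
    borders are dropped from both vectors.  The computation is vectorised
    over shifted copies of the channel plane; because the channel values are
    integers in [0, 255] and window sizes are small, the moment sums are
    exact in float64 and constant windows are detected exactly.
    """
    config.validate_for(_validate_image(image))
    chan = channel_values(image, config.compare_channel)
    h, w = chan.shape
    tr, tc = config.target_point
    i = config.mask.i

    n = np.zeros((h, w))
    sx = np.zeros((h, w))
    sy = np.zeros((h, w))
    sxx = np.zeros((h, w))
    syy = np.zeros((h, w))
    sxy = np.zeros((h, w))
    for dr, dc in _window_offsets(i):
        t_val = chan[tr + dr, tc + dc]
        shifted = np.full((h, w), np.nan)
        rs0, rs1 = max(0, -dr), min(h, h - dr)
        cs0, cs1 = max(0, -dc), min(w, w - dc)
        shifted[rs0:rs1, cs0:cs1] = chan[rs0 + dr : rs1 + dr, cs0 + dc : cs1 + dc]
        valid = ~np.isnan(shifted)
        v = np.where(valid, shifted, 0.0)
        n += valid
        sx += v
        sxx += v * v
        sy += valid * t_val
        syy += valid * (t_val * t_val)
        sxy += v * t_val

    # scaled (by n^2) population variances/covariance; exact for integer input
    varx = n * sxx - sx * sx
    vary = n * syy - sy * sy
    cov = n * sxy - sx * sy
    varx = np.maximum(varx, 0.0)
    vary = np.maximum(vary, 0.0)

    both_const = (varx == 0) & (vary == 0)
    either_const = (varx == 0) | (vary == 0)
    denom = varx * vary
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (cov * cov) / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = np.minimum(r2, 1.0)
    # degenerate rule: either window constant -> 0, unless both are constant
    # and carry the same value (sx == sy with equal n) -> 1
    r2[either_const] = 0.0
    r2[both_const & (sx == sy)] = 1.0
    return r2


def _segment_memoized(image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Raster traversal that reuses the previous label for identical windows."""
    chan = channel_values(image, config.compare_channel)
    h, w = chan.shape
    i = config.mask.i
    tr, tc = config.target_point
    offsets = _window_offsets(i)
    target = {
        (dr, dc): chan[tr + dr, tc + dc] for dr, dc in offsets
    }
    out = np.zeros((h, w), dtype=bool)
    prev_region: Optional[tuple] = None
    prev_label = False
    for r in range(h):
        for c in range(w):
            region = tuple(
                (dr, dc, chan[r + dr, c + dc])
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w
            )
            if prev_region is not None and region == prev_region:
                out[r, c] = prev_label
            else:
                xs = [v for _, _, v in region]
                ys = [target[(dr, dc)] for dr, dc, _ in region]
                r2 = coefficient_of_determination(xs, ys)
                out[r, c] = r2 > config.threshold
            prev_region, prev_label = region, out[r, c]
    return out


def segment_by_r2(image: np.ndarray, config: SegmentationConfig) -> BinaryMask:
    """Label every pixel whose window R^2 against the target region exceeds
    the threshold as foreground.

    The comparison is strict (``R^2 > threshold``); the target point itself
    is always foreground.  ``config.memoize`` switches to the sequential
    traversal with the identical-window shortcut; both paths produce the
    same mask.
    """
    arr = _validate_image(image)
    config.validate_for(arr)
    if config.memoize:
        values = _segment_memoized(arr, config)
    else:
        values = r_squared_map(arr, config) > config.threshold
    values[config.target_point] = True
    return BinaryMask(values)


def segmentation_error(nf: int, nt: int) -> float:
    """Percent segmentation error ``Er = 100 (Nf / Nt - 1)``.

    Positive Er: background leaked into the foreground; negative Er:
    foreground was lost to the background.
    """
    if nt <= 0:
        raise InvalidInputError(f"true foreground count Nt must be positive, got {nt}")
    if nf < 0:
        raise InvalidInputError(f"segmented foreground count Nf must be >= 0, got {nf}")
    return 100.0 * (nf / nt - 1.0)


def threshold_sweep(
    image: np.ndarray,
    truth: BinaryMask,
    config: SegmentationConfig,
    thresholds: Sequence[float],
    precision_floor: float = 95.0,
    max_delta: float = 2.0,
) -> SweepResult:
    """Segment at each threshold and locate the threshold slowness section.

    The slowness section is the widest contiguous run (length >= 2) of
    thresholds where precision ``100 - |Er|`` stays at or above
    ``precision_floor`` and successive ``|Er|`` values change by at most
    ``max_delta`` percentage points.  Returns the run's (low, high)
    threshold pair, or ``None`` when no qualifying run exists.
    """
    arr = _validate_image(image)
    if truth.values.shape != arr.shape[:2]:
        raise InvalidInputError(
            f"truth mask shape {truth.values.shape} does not match image {arr.shape[:2]}"
        )
    th = np.asarray(thresholds, dtype=np.float64)
    if th.size == 0:
        raise InvalidInputError("thresholds must be non-empty")
    if np.any(np.diff(th) <= 0):
        raise InvalidInputError("thresholds must be strictly increasing")
    if th.min() < 0 or th.max() > 1:
        raise InvalidInputError("thresholds must lie in [0, 1]")

    nt = truth.nf
    r2 = r_squared_map(arr, config)
    errors = np.empty(th.size)
    for j, t in enumerate(th):
        values = r2 > t
        values[config.target_point] = True
        errors[j] = segmentation_error(int(values.sum()), nt)
    precisions = 100.0 - np.abs(errors)

    ok = precisions >= precision_floor
    best: Optional[Tuple[int, int]] = None
    start: Optional[int] = None
    for j in range(th.size):
        if not ok[j]:
            start = None
            continue
        if start is None:
            start = j
        elif abs(abs(errors[j]) - abs(errors[j - 1])) > max_delta:
            start = j
        if best is None or j - start > best[1] - best[0]:
            best = (start, j)
    slowness = None
    if best is not None and best[1] > best[0]:
        slowness = (float(th[best[0]]), float(th[best[1]]))
    return SweepResult(th, errors, precisions, slowness)
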