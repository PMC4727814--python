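"""Ground-truthed synthetic citrus images and feature/sugar datasets.

The acquisition conditions this module emulates: a single fruit photographed five
consecutive times on a fixed rig (so replicates differ only by sensor
noise); an orange-hued convex fruit on a color-distinct panel; fruit hue in
the 0.36-0.71 rad band (blood orange to yellow); sugar content spread over
9-18 Brix % in three sweetness classes; fruit weight roughly linear in the
image foreground fraction.

The image generator renders an ellipse whose surface carries a fine
dimple lattice (a +-amplitude checkerboard in brightness, an idealised
citrus-peel texture) on top of a radial brightness gradient; the panel
behind it carries a smooth directional brushed texture (a long-period
triangular wave, locally planar).  Within any 3x3 window a planar patch is
exactly orthogonal to the checkerboard lattice, so the window-correlation
segmentation separates the two surfaces by local pattern -- the property
real peel/panel contrast provides in actual frames.  The truth
mask is exact ellipse membership.

The dataset generator draws a sweetness class, class-consistent color and
size features (greener and larger fruit in the lower classes), evaluates
the chosen model form with that class's dummy pair plus Gaussian noise,
and rejection-samples the observed sugar into the class interval so that
observed-value dummy assignment agrees with the generating class --
measured Brix provides this coherence for free in real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .color_features import rgb_to_hsi
from .errors import ConfigError, InvalidInputError
from .segmentation import BinaryMask
from .sugar_model import (
    LOWER_BOUND,
    UPPER_BOUND,
    ModelForm,
    SugarModel,
    _evaluate,
    label_for_dummies,
    resolve_form,
)

__all__ = [
    "ImageSimConfig",
    "DatasetSimConfig",
    "TRUE_COEFFICIENTS",
    "gen_citrus_image",
    "gen_feature_dataset",
    "split_dataset",
    "true_model",
]


@dataclass(frozen=True)
class ImageSimConfig:
    """Scene parameters of one synthetic citrus frame.

    Channel units are 8-bit gray values.  The defaults render a fruit
    covering about a third of a 160x120 frame, peel hue inside the
    0.36-0.71 rad citrus band, +-20 gray dimple contrast, a 36-gray panel
    texture and sensor noise of 3 gray per replicate -- five replicates as
    in a consecutive-shot acquisition protocol.
    """

    height: int = 120
    width: int = 160
    center: Tuple[int, int] = (60, 80)  # (row, col)
    axes: Tuple[int, int] = (42, 52)  # (row semi-axis, col semi-axis)
    fruit_red: float = 230.0
    fruit_blue: float = 10.0
    fruit_green_range: Tuple[float, float] = (100.0, 138.0)
    gradient_amplitude: float = 18.0
    texture_amplitude: float = 40.0  # peak-to-peak dimple contrast
    background_color: Tuple[float, float, float] = (70.0, 80.0, 95.0)
    background_texture_amplitude: float = 36.0
    background_texture_period: float = 18.0  # phase units of the triangular wave
    noise_sd: float = 3.0
    replicates: int = 5
    seed: int = 0

    def validate(self) -> None:
        cr, cc = self.center
        ar, ac = self.axes
        if ar < 1 or ac < 1:
            raise InvalidInputError("ellipse semi-axes must be positive")
        if not (cr - ar >= 0 and cr + ar < self.height and cc - ac >= 0 and cc + ac < self.width):
            raise InvalidInputError("ellipse must lie fully inside the image")
        if self.noise_sd < 0:
            raise InvalidInputError("noise sd must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("need at least one replicate")


def _triangle(phase: np.ndarray, period: float) -> np.ndarray:
    """Symmetric triangular wave in [-1, 1] with the given period."""
    frac = np.mod(phase / period, 1.0)
    return 4.0 * np.abs(frac - 0.5) - 1.0


def gen_citrus_image(config: ImageSimConfig = ImageSimConfig()) -> Tuple[list, BinaryMask]:
    """Render the replicate stack and the exact truth mask.

    Returns ``(stack, truth)`` where ``stack`` is a list of
    ``config.replicates`` uint8 H x W x 3 images differing only by
    independent Gaussian sensor noise (clamped to [0, 255] and quantised),
    and ``truth`` marks exact ellipse membership.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    cr, cc = config.center
    ar, ac = config.axes

    rows, cols = np.mgrid[0:h, 0:w]
    rho2 = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2
    fg = rho2 <= 1.0

    # panel: base color plus a locally planar brushed texture (diagonal
    # triangular wave), identical in all channels
    phase = rows * 1.0 + cols * 0.5
    panel = config.background_texture_amplitude * _triangle(phase, config.background_texture_period)
    scene = np.empty((h, w, 3))
    for ch, base in enumerate(config.background_color):
        scene[..., ch] = base + panel

    # fruit: orange base whose green channel varies radially within the
    # citrus hue band, a radial brightness gradient (brighter at the apex)
    # and the dimple lattice; brightness terms are added to all channels
    # equally, which leaves the arccos hue untouched
    g_lo, g_hi = config.fruit_green_range
    green = g_lo + (g_hi - g_lo) * np.clip(rho2, 0.0, 1.0)
    brightness = config.gradient_amplitude * (1.0 - rho2)
    dimples = (config.texture_amplitude / 2.0) * np.where((rows + cols) % 2 == 0, 1.0, -1.0)
    lum = brightness + dimples
    scene[..., 0] = np.where(fg, config.fruit_red + lum, scene[..., 0])
    scene[..., 1] = np.where(fg, green + lum, scene[..., 1])
    scene[..., 2] = np.where(fg, config.fruit_blue + lum, scene[..., 2])

    stack = []
    for _ in range(config.replicates):
        noisy = scene + rng.normal(0.0, config.noise_sd, scene.shape) if config.noise_sd > 0 else scene.copy()
        stack.append(np.clip(np.rint(noisy), 0, 255).astype(np.uint8))
    return stack, BinaryMask(fg)


#: Per-class draw ranges for the dataset generator.  Greener (higher G) and
#: larger (higher x_p) fruit populate the lower sweetness classes.
_CLASS_G_RANGE = {0: (125.0, 145.0), 1: (108.0, 128.0), 2: (92.0, 112.0)}
_CLASS_XP_RANGE = {0: (0.21, 0.30), 1: (0.16, 0.24), 2: (0.115, 0.18)}
_CLASS_DUMMIES = {0: (1, 0), 1: (0, 1), 2: (1, 1)}

#: Class-consistent true coefficient sets (a, g, h, c, p0, p1, p2) per
#: combinator with the x_p slot: chosen so that the deterministic model
#: value of a typical class draw lands inside that class's Brix interval.
TRUE_COEFFICIENTS: Dict[str, Tuple[float, ...]] = {
    "ratio": (6.2, -3.0, 3.0, -5.0, 1.79, -0.02, 0.07),
    "linear": (18.6, -3.0, 3.0, -5.0, -37.2, 15.2, 22.7),
    "mult": (4.95, -0.15, 0.10, -0.30, -0.341, -0.044, -0.131),
    "addpower": (7.0, 0.5, -0.3, 0.4, -0.393, -0.12, -0.557),
}

#: Weight link: grams per unit foreground fraction, plus Gaussian scatter.
WEIGHT_SLOPE = 430.0
WEIGHT_NOISE_SD = 6.0


@dataclass(frozen=True)
class DatasetSimConfig:
    """Statistical parameters of one simulated feature/sugar dataset."""

    n: int = 60
    form: "ModelForm | str" = "ratio_xp"
    coefficients: Optional[Tuple[float, ...]] = None  # defaults per combinator
    noise_sd: float = 0.5  # Brix %
    sugar_range: Tuple[float, float] = (9.0, 18.0)
    class_margin: float = 0.0  # keep observed y this far from class borders
    weight_slope: float = WEIGHT_SLOPE
    weight_noise_sd: float = WEIGHT_NOISE_SD
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise InvalidInputError("need n >= 10 samples")
        lo, hi = self.sugar_range
        if not (0.0 <= lo < hi <= 53.0):
            raise InvalidInputError("sugar range must lie within the meter's 0-53 Brix span")
        if self.noise_sd < 0 or self.weight_noise_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")
        if self.class_margin < 0:
            raise InvalidInputError("class_margin must be >= 0")


def true_model(config: DatasetSimConfig = DatasetSimConfig()) -> SugarModel:
    """The generating model of a dataset configuration, as a SugarModel."""
    form = resolve_form(config.form)
    coefs = config.coefficients or TRUE_COEFFICIENTS[form.combinator]
    if len(coefs) != 7:
        raise InvalidInputError("coefficients must be a 7-tuple (a, g, h, c, p0, p1, p2)")
    a, g, h, c, p0, p1, p2 = coefs
    return SugarModel(form=form, a=a, g=g, h=h, c=c, p0=p0, p1=p1, p2=p2)


def _class_intervals(config: DatasetSimConfig):
    lo, hi = config.sugar_range
    m = config.class_margin
    return {
        0: (lo + m, LOWER_BOUND - m),
        1: (LOWER_BOUND + m, UPPER_BOUND - m),
        2: (UPPER_BOUND + m, hi - m),
    }


def draw_class_features(classes: np.ndarray, rng: np.random.Generator,
                        config: DatasetSimConfig = DatasetSimConfig()) -> pd.DataFrame:
    """Class-consistent feature draws (vectorised over samples).

    Mean R and B get independent jitter so that x_y is not an affine
    function of x_g; G and x_p come from the class's range; x_h derives
    from the drawn mean RGB triple through the HSI conversion.
    """
    n = classes.size
    r = rng.uniform(222.0, 238.0, n)
    b = rng.uniform(4.0, 16.0, n)
    g = np.empty(n)
    xp = np.empty(n)
    for cls, (g_lo, g_hi) in _CLASS_G_RANGE.items():
        sel = classes == cls
        g[sel] = rng.uniform(g_lo, g_hi, int(sel.sum()))
    for cls, (p_lo, p_hi) in _CLASS_XP_RANGE.items():
        sel = classes == cls
        xp[sel] = rng.uniform(p_lo, p_hi, int(sel.sum()))
    h, s, i = rgb_to_hsi(np.column_stack([r, g, b]))
    xw = config.weight_slope * xp + rng.normal(0.0, config.weight_noise_sd, n)
    return pd.DataFrame({
        "x_p": xp, "x_h": h, "x_g": g / 255.0, "x_y": (g + r) / 510.0,
        "r_mean": r, "g_mean": g, "b_mean": b, "x_w": xw,
    })


def gen_feature_dataset(config: DatasetSimConfig = DatasetSimConfig()) -> pd.DataFrame:
    """Simulate a feature/sugar dataset with coherent class structure.

    Per sample: draw a class (equal thirds), class-consistent features, and
    an observed sugar value from the generating model (that class's dummy
    pair) plus Gaussian noise; accept only when the observed value falls in
    the class's Brix interval intersected with the overall sugar range,
    shrunk by ``class_margin`` on each side.  Raises ``ConfigError`` when
    the acceptance rate collapses (infeasible configuration).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = true_model(config)
    intervals = _class_intervals(config)
    for cls, (lo, hi) in intervals.items():
        if lo >= hi:
            raise ConfigError(f"class {cls} interval {lo, hi} is empty; reduce class_margin")

    n = config.n
    classes = rng.integers(0, 3, n)
    rows = []
    proposals = 0
    cap = 10_000 * n
    pending = list(range(n))
    accepted: Dict[int, pd.Series] = {}
    while pending:
        idx = np.array(pending)
        feats = draw_class_features(classes[idx], rng, config)
        k1 = np.array([_CLASS_DUMMIES[c][0] for c in classes[idx]], dtype=float)
        k2 = np.array([_CLASS_DUMMIES[c][1] for c in classes[idx]], dtype=float)
        coefs = [model.a, model.g, model.h, model.c, model.p0, model.p1, model.p2]
        y_det = _evaluate(model.form, coefs,
                          feats["x_g"].to_numpy(), feats["x_h"].to_numpy(),
                          feats["x_y"].to_numpy(),
                          feats[model.form.slot].to_numpy(), k1, k2)
        y = y_det + (rng.normal(0.0, config.noise_sd, idx.size) if config.noise_sd > 0 else 0.0)
        proposals += idx.size
        lo = np.array([intervals[c][0] for c in classes[idx]])
        hi = np.array([intervals[c][1] for c in classes[idx]])
        ok = (y >= lo) & (y <= hi)
        for j, sample, good in zip(idx, range(idx.size), ok):
            if good and j not in accepted:
                row = feats.iloc[sample].copy()
                row["y"] = y[sample]
                accepted[j] = row
        pending = [j for j in pending if j not in accepted]
        if pending and proposals >= cap:
            rate = (n - len(pending)) / proposals
            raise ConfigError(
                f"acceptance rate {rate:.2%} after {proposals} proposals; "
                "the configuration cannot place sugar values in their class intervals"
            )
        if pending and proposals >= cap // 100 and (n - len(pending)) / proposals < 0.01:
            raise ConfigError("acceptance rate below 1%; infeasible configuration")

    df = pd.DataFrame([accepted[j] for j in range(n)]).reset_index(drop=True)
    df.insert(0, "sample_id", np.arange(n))
    df["class_true"] = classes
    df["label_true"] = [label_for_dummies(_CLASS_DUMMIES[c]) for c in classes]
    df["k1"] = [_CLASS_DUMMIES[c][0] for c in classes]
    df["k2"] = [_CLASS_DUMMIES[c][1] for c in classes]
    return df


def split_dataset(dataset: pd.DataFrame, n_fit: int = 45,
                  seed: int = 0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform split into fitting and validation subsets.

    Draws ``n_fit`` rows without replacement for fitting; the remainder is
    the validation set.  The two parts partition the dataset exactly.
    """
    n = len(dataset)
    if not 0 < n_fit < n:
        raise InvalidInputError(f"n_fit must be in (0, {n}), got {n_fit}")
    rng = np.random.default_rng(seed)
    fit_idx = np.sort(rng.choice(n, size=n_fit, replace=False))
    val_idx = np.setdiff1d(np.arange(n), fit_idx)
    return dataset.iloc[fit_idx].reset_index(drop=True), dataset.iloc[val_idx].reset_index(drop=True)
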