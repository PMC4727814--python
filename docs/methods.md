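# Methods

This note documents the models and procedures implemented by
`citrusbrix`, the parameters that matter, the synthetic data the tests
run on, and the design choices made where the design was genuinely open.

## Window-correlation segmentation

Segmentation treats a user-chosen *target region* — the `(2i+1)×(2i+1)`
window around a point inside the fruit — as a pattern template. For every
pixel, the window around it is paired with the target region offset by
offset, and the coefficient of determination

    R² = Cov²(x, y) / (Var(x)·Var(y))

is computed over the paired gray values (population moments; the
normalisation cancels). Pixels with `R² > t` (strict) are foreground; the
target point itself is always foreground. The default window is 3×3
(`i = 1`): larger windows widen the misclassified border band and cost
quadratically more (a 31×31 window covers 961 pixels), while 3×3 already
captures the local texture the statistic discriminates on.

Choices a user can change:

* **Comparison signal** (`compare_channel`, default `gray`): the rounded
  BT.601 luma `0.299R + 0.587G + 0.114B`. Single channels are available
  for experimentation. The luma is rounded to an integer so that
  constant-window detection is exact.
* **Degenerate windows.** R² is 0/0 when either window is constant. Rule:
  two constant windows with the same value → 1; any other constant window
  → 0. A flat background patch must not match a flat but
  differently-valued target.
* **Borders.** Windows are clipped to the image and the pairing drops
  offsets missing from either vector; no padding values are invented.
  Corner windows therefore compare as few as 4 values.
* **Traversal.** The default computation is vectorised over shifted
  image planes. `memoize=True` selects the sequential raster traversal
  that reuses the previous pixel's label whenever the current window is
  element-wise identical to the previous one; this is
  exactness-preserving, and both paths produce identical masks (tested
  against an independent per-pixel loop).
* **Target point.** An explicit (row, col) argument; the window around it
  must fit entirely inside the image. There is no interactive picking.

Error metric: `Er = 100·(Nf/Nt − 1)` (positive = background leaked in,
negative = foreground lost), precision `100 − |Er|`. `threshold_sweep`
segments at a grid of thresholds and reports the *threshold slowness
section*: the widest contiguous run (length ≥ 2) with precision at or
above a floor (default 95) and successive `|Er|` changes at most a delta
(default 2 points). Because the per-pixel R² does not depend on the
threshold, foreground sets are exactly nested across thresholds and `Nf`
is monotone non-increasing.

## Color features

Replicate frames taken under identical settings are averaged per pixel
and channel (rounded half-up) before anything else; with m frames the
noise variance drops by 1/m (m = 5 by default, matching a five-shot
acquisition protocol).

From the averaged image and a foreground mask:

* `x_p` — foreground fraction of the frame, in [0, 1]; a proxy for fruit
  size and hence volume/weight under a fixed rig.
* `x_h` — mean HSI hue over the foreground, **in radians**, where hue is
  the raw arccos angle
  `θ = arccos{[(R−G)+(R−B)] / (2·sqrt((R−G)² + (R−B)(G−B)))}`,
  reflected to `2π − θ` when B > G. Citrus peel falls around
  0.36–0.71 rad (blood-orange to yellow). The hue is *not* divided by 2π.
  Achromatic pixels (R = G = B) have no hue and are excluded from the
  mean (all-achromatic foreground → `x_h = 0`). The mean is an arithmetic
  mean of angles, not a circular mean — adequate because fruit hues sit
  far from the 0/2π wrap; this is a documented limitation for hues near
  red. An option converts the mean RGB triple instead
  (`hue_mode="mean_rgb"`).
* `x_g = g_mean/255`, `x_y = (g_mean + r_mean)/510` where the synthetic
  yellow channel is `Y = (G+R)/2` exactly.
* Auxiliary HSI (S, I) and CIELAB means, computed per pixel and averaged.
  CIELAB uses the standard sRGB (D65) transform via scikit-image. Note
  the published rounded sRGB matrix leaves ~1e-3 residual a*/b* on the
  gray axis; white and black anchors are exact.

Normalisations are fixed physical ones (divide by 255, fractions of the
frame) rather than dataset min–max, so fitted coefficients remain
comparable across datasets. Channel means are kept at full float
precision; only averaged images are integer-rounded.

## Sugar models

Three sweetness levels partition the Brix axis: semisweet `y < 11`,
sweet `11 ≤ y ≤ 14` (closed on both ends), verysweet `y > 14`. The
corresponding dummy pairs are (1,0), (0,1) and (1,1); they modulate one
coefficient `θ = p0 + p1·k1 + p2·k2`. With `x` the slotted predictor
(`x_p`, or `x_w` in grams when a scale is available):

    ratio:     y = a + g·x_g + h·x_h + c·x_y + θ/x
    linear:    y = a + g·x_g + h·x_h + c·x_y + θ·x
    mult:      y = a · x_g^g · x_h^h · x_y^c · x^θ
    addpower:  y = a + x_g^g·x_h^h·x_y^c + x^θ

Any combinator pairs with either slot. The reduced form of each model
pins `k1 = k2 = 0`, collapsing θ to a single coefficient.

**Fitting** (`fit_model`, `fit_reduced`): dummies are assigned from the
*observed* sugar values (an explicit dummy sequence can be passed when the
true class is known, e.g. in simulations). Ratio/linear forms are exact
least squares on the expanded regressors `(1, x_g, x_h, x_y, z, k1·z,
k2·z)` with `z = 1/x` or `x`. Collinearity among the base feature columns
raises an error naming the offending columns; deficiency confined to the
dummy columns (a class absent from the data — e.g. constant y) falls back
to the minimum-norm solution, which zeroes the unidentifiable slopes.
`mult` is fitted by Levenberg–Marquardt least squares warm-started from
the exact log-linear solve. `addpower` has genuine local minima whose
residuals are tiny but whose coefficients are far off; it is therefore
solved from a fixed, deterministic ladder of nine starting points (four
trial offsets `a0 ∈ {min(y)−1, min(y)−2, 0, mean(y)/2}` each with
power-term coefficients warm-started by regressing `log(y − a0)` on
`log x` and its dummy interactions, at two exponent inits, plus a flat
start), keeping the lowest-SSE solution. No random restarts; the solver
cap is 10,000 evaluations at tolerance 1e-10. `fit_r2 = 1 − SSE/SST`,
defined as 0 when SST = 0.

**Two-stage prediction**: evaluate the reduced model with (0,0) dummies;
assign (k1, k2) from that estimate; evaluate the full model with those
dummies. The returned label and dummy pair always derive from the stage-1
estimate, even when the stage-2 value crosses a class boundary.

**Validation**: `e̅ = (1/n)Σ(yᵢ−ŷᵢ)`, `δ² = (1/(n−1))Σ(yᵢ−ŷᵢ)²`
(literally as printed — a raw scaled residual sum of squares, not the
variance about e̅), `mse = e̅² + δ²`, and the combined root error
`sqrt(e̅² + δ²)` — the scale on which validation tables are usually
reported. The validation R² is the squared Pearson correlation of
observed and predicted values (the fitting R² is 1 − SSE/SST; the two
coincide only for an unbiased linear fit).

**Model selection** (`rank_models`): each of the four indicators
(fitting R², validation e̅, combined root error, validation R²) is ranked
across models, best = 1, ties sharing the best rank; the residual
indicators are ranked by *magnitude* — a large negative mean residual is
as bad as a large positive one. The model with the lowest rank total
wins; ties break by fitting R², then declaration order.

## Synthetic data

The generators define the conditions the tests and the acceptance script
run under.

**Scenes** (`gen_citrus_image`). A 160×120 frame holds an ellipse
(semi-axes 42×52 px, ~36% of the frame) on a blue-gray panel. The peel
carries a ±20-gray checkerboard dimple lattice (an idealised citrus-peel
micro-texture) over a radial brightness gradient; its green channel
varies radially so per-pixel hue spans the citrus band. The panel
carries a 36-gray triangular wave along a diagonal — a brushed texture
that is locally planar. Within any 3×3 window a planar patch has exactly
zero covariance with the checkerboard lattice, so the window-correlation
statistic separates the two surfaces cleanly by pattern; this is the
idealisation of the peel/panel texture contrast that makes the method
work on real frames. Brightness terms are added to all channels equally,
which leaves the arccos hue invariant. Each of the five replicates adds
independent Gaussian sensor noise (sd 3 gray), then clamps and quantises
to 8-bit. The truth mask is exact ellipse membership. These defaults were
fixed once, by calibrating the scene against the generator's documented
contract (precision ≥ 95% at the 3×3 window, threshold 0.3 operating
point), and not revisited.

What the scene does **not** model: shading from directed light, specular
highlights, shadows cast on the panel, lens distortion, defocus, and
natural peel blemishes. Passing tests therefore demonstrate the
algorithmic properties (pattern discrimination, nestedness, error
behaviour), not robustness to those real-world effects.

**Datasets** (`gen_feature_dataset`). Per sample: a sweetness class is
drawn (equal thirds); class-consistent features are drawn — greener
(G-range per class) and larger (`x_p` range per class) fruit in the lower
classes, with independent jitter on mean R and B so `x_y` is not an
affine function of `x_g`; hue derives from the drawn RGB triple through
the HSI conversion (always inside 0.36–0.71 rad); weight is
`430·x_p + N(0, 6)` grams (about 50–130 g over the size range). The
observed sugar value is the generating model evaluated with the class's
dummy pair plus `N(0, σ)` Brix noise (σ = 0.5 by default), accepted only
if it falls inside the class's interval intersected with the overall
9–18 range (optionally shrunk by a `class_margin`). This rejection step
ties the observed value to its generating class, so that observed-value
dummy assignment during fitting agrees with the generating class —
measured Brix provides this coherence for free in real data. An
acceptance rate below 1% raises a configuration error.

The true coefficient sets per combinator were derived once, analytically,
by requiring the deterministic model value of a typical class draw to
land inside that class's interval given the class feature ranges (e.g.
ratio: a = 6.2, g = −3, h = 3, c = −5, θ ≈ 1.8 with small dummy
adjustments), and frozen.

Note the truncation induced by rejection makes the observed noise
slightly non-Gaussian near class borders; the estimator-unbiasedness test
therefore draws open-ended noise with known-class dummies, isolating the
least-squares property it checks.

## Problem sizes

Scenes are 160×120 (small-scene tests 48×64 and 40×56); datasets are 60
samples split 45/15; the unbiasedness check uses 200 Monte-Carlo
replicates; the end-to-end accuracy check pools 20 seeds × 15 validation
fruit. These sizes keep the full suite in the seconds-to-a-minute range
while leaving every statistical check well-powered.

## Known limitations

* The arithmetic hue mean breaks down for hues near the 0/2π wrap
  (deep reds); use `hue_mode="mean_rgb"` or a circular mean if that
  matters for your data.
* The ratio and power forms are undefined at `x ≤ 0`; an empty or
  near-empty foreground cannot be graded.
* Between-class coefficient identifiability requires all three classes in
  the fitting data; with a class absent the corresponding dummy slope is
  reported as 0 by the minimum-norm convention.
* The segmentation statistic keys on texture contrast; a panel whose
  texture correlates with the peel pattern (or a heavily blurred image)
  will defeat it regardless of threshold.
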