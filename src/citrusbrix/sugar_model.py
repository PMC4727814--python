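"""Dummy-variable regression of citrus sugar content (Brix %).

Sugar content ``y`` is modelled from the color predictors ``x_g`` (green),
``x_h`` (hue, radians), ``x_y`` (yellow), and either the foreground
fraction ``x_p`` or the fruit weight ``x_w`` (grams).  Two binary dummy
variables encode the three sweetness levels,

    y < 11        -> (k1, k2) = (1, 0)   "semisweet"
    11 <= y <= 14 -> (k1, k2) = (0, 1)   "sweet"
    y > 14        -> (k1, k2) = (1, 1)   "verysweet"

and modulate a single coefficient ``theta = p0 + p1 k1 + p2 k2``.  The
model family combines the predictors in four ways (``x`` is the slotted
predictor, ``x_p`` or ``x_w``):

    ratio:     y = a + g x_g + h x_h + c x_y + theta / x
    linear:    y = a + g x_g + h x_h + c x_y + theta * x
    mult:      y = a * x_g^g * x_h^h * x_y^c * x^theta
    addpower:  y = a + x_g^g * x_h^h * x_y^c + x^theta

Fitting assigns dummies from the *observed* sugar values.  Prediction of a
new fruit is two-stage: the reduced model (dummies pinned to zero, theta
collapsed to one coefficient) gives a first estimate, that estimate sets
(k1, k2), and the full model with those dummies gives the final value and
the sweetness label.

Validation follows the residual summaries

    e_bar  = (1/n) sum (y_i - yhat_i)
    delta2 = (1/(n-1)) sum (y_i - yhat_i)^2
    mse    = e_bar^2 + delta2

plus the combined root error ``sqrt(e_bar^2 + delta2)`` and a squared-
correlation validation R^2.  Competing models are compared by rank-scoring
four indicators and selecting the lowest total score.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FittingError, InvalidInputError

__all__ = [
    "DummyPair",
    "ModelForm",
    "SugarModel",
    "ErrorReport",
    "ScoreCard",
    "FORMS",
    "assign_dummies",
    "classify_sweetness",
    "predict",
    "fit_model",
    "fit_reduced",
    "two_stage_predict",
    "error_analysis",
    "combined_error",
    "rank_models",
]

#: Sweetness class boundaries in Brix %; the middle interval is closed.
LOWER_BOUND = 11.0
UPPER_BOUND = 14.0

LABELS = ("semisweet", "sweet", "verysweet")

DummyPair = Tuple[int, int]

#: Solver settings for the nonlinear forms (deterministic, no restarts).
_NLS_MAX_ITER = 10_000
_NLS_XTOL = 1e-10


@dataclass(frozen=True)
class ModelForm:
    """A combinator (how predictors enter) paired with a predictor slot."""

    combinator: str  # "ratio" | "linear" | "mult" | "addpower"
    slot: str = "x_p"  # "x_p" | "x_w"

    def __post_init__(self) -> None:
        if self.combinator not in ("ratio", "linear", "mult", "addpower"):
            raise InvalidInputError(f"unknown combinator {self.combinator!r}")
        if self.slot not in ("x_p", "x_w"):
            raise InvalidInputError(f"unknown predictor slot {self.slot!r}")

    @property
    def name(self) -> str:
        return f"{self.combinator}_{'xp' if self.slot == 'x_p' else 'xw'}"


#: Named forms of the family.  ``ratio_xp_alt`` is an alias kept so that
#: model tables can carry the two historically separate ratio fits.
FORMS: Dict[str, ModelForm] = {
    "ratio_xp": ModelForm("ratio", "x_p"),
    "ratio_xp_alt": ModelForm("ratio", "x_p"),
    "linear_xp": ModelForm("linear", "x_p"),
    "mult_xp": ModelForm("mult", "x_p"),
    "addpower_xp": ModelForm("addpower", "x_p"),
    "ratio_xw": ModelForm("ratio", "x_w"),
    "linear_xw": ModelForm("linear", "x_w"),
    "mult_xw": ModelForm("mult", "x_w"),
    "addpower_xw": ModelForm("addpower", "x_w"),
}

_COEF_NAMES = ("a", "g", "h", "c", "p0", "p1", "p2")


def resolve_form(form: "ModelForm | str") -> ModelForm:
    if isinstance(form, ModelForm):
        return form
    try:
        return FORMS[form]
    except KeyError:
        raise InvalidInputError(
            f"unknown model form {form!r}; known: {sorted(FORMS)}"
        ) from None


@dataclass
class SugarModel:
    """A fitted (or constructed) member of the model family.

    ``p0, p1, p2`` are the dummy-modulated coefficients; for weight-slot
    models they play the role conventionally written ``w0, w1, w2``.  A
    reduced model has ``reduced=True`` and ``p1 = p2 = 0``.
    """

    form: ModelForm
    a: float
    g: float
    h: float
    c: float
    p0: float
    p1: float = 0.0
    p2: float = 0.0
    reduced: bool = False
    fit_r2: Optional[float] = None

    def __post_init__(self) -> None:
        self.form = resolve_form(self.form)
        for name in _COEF_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise InvalidInputError(f"coefficient {name} is not finite")

    @property
    def coefficients(self) -> Dict[str, float]:
        return {name: float(getattr(self, name)) for name in _COEF_NAMES}

    def to_dict(self) -> dict:
        d = {"form": self.form.name, "slot": self.form.slot, "reduced": self.reduced,
             "coefficients": self.coefficients, "fit_r2": self.fit_r2}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SugarModel":
        coefs = d["coefficients"]
        return cls(form=resolve_form(d["form"]), reduced=bool(d.get("reduced", False)),
                   fit_r2=d.get("fit_r2"), **{k: float(coefs[k]) for k in _COEF_NAMES})


@dataclass
class ErrorReport:
    """Validation residual summaries."""

    e_bar: float
    delta2: float
    mse: float
    rmse_combined: float
    val_r2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScoreCard:
    """Rank-scoring of competing models over four validation indicators."""

    names: List[str]
    ranks: pd.DataFrame  # index: model names, columns: indicator names
    totals: pd.Series
    selected: str


def assign_dummies(y: float) -> DummyPair:
    """Dummy pair (k1, k2) for a sugar value per the three-level coding."""
    if not np.isfinite(y):
        raise InvalidInputError(f"sugar value must be finite, got {y}")
    if y < LOWER_BOUND:
        return (1, 0)
    if y <= UPPER_BOUND:
        return (0, 1)
    return (1, 1)


def classify_sweetness(y: float) -> str:
    """Sweetness label for a sugar value; same partition as the dummies."""
    if not np.isfinite(y):
        raise InvalidInputError(f"sugar value must be finite, got {y}")
    if y < LOWER_BOUND:
        return "semisweet"
    if y <= UPPER_BOUND:
        return "sweet"
    return "verysweet"


def label_for_dummies(k: DummyPair) -> str:
    return {(1, 0): "semisweet", (0, 1): "sweet", (1, 1): "verysweet"}[tuple(k)]


def _as_columns(features, form: ModelForm):
    """Extract x_g, x_h, x_y and the slotted predictor as float arrays."""
    if isinstance(features, pd.DataFrame):
        get = lambda k: features[k].to_numpy(dtype=np.float64)  # noqa: E731
    elif isinstance(features, (Mapping, pd.Series)):
        get = lambda k: np.asarray(features[k], dtype=np.float64)  # noqa: E731
    else:  # FeatureVector-like object
        get = lambda k: np.asarray(getattr(features, k), dtype=np.float64)  # noqa: E731
    try:
        xg, xh, xy, x = get("x_g"), get("x_h"), get("x_y"), get(form.slot)
    except (KeyError, AttributeError) as exc:
        raise InvalidInputError(f"features are missing a required column: {exc}") from None
    if np.asarray(x, dtype=np.float64).dtype.kind not in "fiu" or np.any(~np.isfinite(np.asarray(x, float))):
        raise InvalidInputError(f"predictor {form.slot} contains non-finite values")
    return xg, xh, xy, x


def _evaluate(form: ModelForm, coefs: Sequence[float], xg, xh, xy, x, k1, k2):
    a, g, h, c, p0, p1, p2 = coefs
    theta = p0 + p1 * np.asarray(k1, dtype=np.float64) + p2 * np.asarray(k2, dtype=np.float64)
    comb = form.combinator
    if comb in ("ratio", "mult", "addpower") and np.any(np.asarray(x) <= 0):
        raise DomainError(f"{comb} form requires {form.slot} > 0")
    if comb in ("mult", "addpower") and (np.any(np.asarray(xg) <= 0) or np.any(np.asarray(xh) <= 0) or np.any(np.asarray(xy) <= 0)):
        raise DomainError(f"{comb} form requires positive x_g, x_h, x_y")
    if comb == "ratio":
        return a + g * xg + h * xh + c * xy + theta / x
    if comb == "linear":
        return a + g * xg + h * xh + c * xy + theta * x
    if comb == "mult":
        return a * xg**g * xh**h * xy**c * x**theta
    return a + xg**g * xh**h * xy**c + x**theta  # addpower


def predict(model: SugarModel, features, k: DummyPair = (0, 0)):
    """Evaluate the model at a feature vector (or DataFrame) with fixed dummies.

    ``k = (0, 0)`` is the reduced-model convention.  Ratio and power forms
    require the slotted predictor (and, for the power forms, every used
    feature) to be strictly positive.
    """
    xg, xh, xy, x = _as_columns(features, model.form)
    k1, k2 = k
    coefs = [model.a, model.g, model.h, model.c, model.p0, model.p1, model.p2]
    out = _evaluate(model.form, coefs, xg, xh, xy, x, k1, k2)
    if np.ndim(out) == 0:
        return float(out)
    return np.asarray(out, dtype=np.float64)


def _design_matrix(form: ModelForm, xg, xh, xy, x, k1, k2, reduced: bool):
    """Expanded regressors for the linear-in-parameters combinators."""
    z = 1.0 / x if form.combinator == "ratio" else x
    cols = [np.ones_like(xg), xg, xh, xy, z]
    names = ["1", "x_g", "x_h", "x_y", "z"]
    if not reduced:
        cols += [k1 * z, k2 * z]
        names += ["k1*z", "k2*z"]
    return np.column_stack(cols), names


def _check_rank(design: np.ndarray, names: List[str], n_base: int = 5) -> None:
    """Reject collinear *feature* columns, naming the offenders.

    Deficiency confined to the dummy-expanded columns (a class absent from
    the data, e.g. constant y) is tolerated: the minimum-norm least-squares
    solution then zeroes the unidentifiable slopes.
    """
    base = design[:, :n_base]
    if np.linalg.matrix_rank(base) < n_base:
        collinear = []
        for j in range(1, n_base):
            if np.linalg.matrix_rank(base[:, : j + 1]) <= np.linalg.matrix_rank(base[:, :j]):
                collinear.append(names[j])
        raise FittingError(f"rank-deficient design; collinear columns: {collinear}")


def _fit_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def _prepare_fit(form, dataset, dummies):
    form = resolve_form(form)
    if not isinstance(dataset, pd.DataFrame):
        raise InvalidInputError("dataset must be a pandas DataFrame")
    if "y" not in dataset.columns:
        raise InvalidInputError("dataset must contain an observed sugar column 'y'")
    y = dataset["y"].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise InvalidInputError("observed sugar values must be finite")
    xg, xh, xy, x = _as_columns(dataset, form)
    if dummies is None:
        pairs = [assign_dummies(v) for v in y]
    else:
        pairs = [tuple(p) for p in dummies]
        if len(pairs) != len(y):
            raise InvalidInputError("dummies length does not match dataset")
    k1 = np.array([p[0] for p in pairs], dtype=np.float64)
    k2 = np.array([p[1] for p in pairs], dtype=np.float64)
    return form, y, xg, xh, xy, x, k1, k2


def _fit(form: ModelForm, dataset: pd.DataFrame, reduced: bool,
         dummies: Optional[Sequence[DummyPair]]) -> SugarModel:
    form, y, xg, xh, xy, x, k1, k2 = _prepare_fit(form, dataset, dummies)
    n_params = 5 if reduced else 7
    if len(y) < n_params:
        raise InvalidInputError(f"need at least {n_params} samples, got {len(y)}")
    if reduced:
        k1 = np.zeros_like(k1)
        k2 = np.zeros_like(k2)

    comb = form.combinator
    if comb in ("ratio", "linear"):
        if comb == "ratio" and np.any(x <= 0):
            raise DomainError(f"ratio form requires {form.slot} > 0")
        design, names = _design_matrix(form, xg, xh, xy, x, k1, k2, reduced)
        _check_rank(design, names)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        a, g, h, c, p0 = beta[:5]
        p1, p2 = (0.0, 0.0) if reduced else (beta[5], beta[6])
        yhat = design @ beta
    else:
        if np.any(x <= 0) or np.any(xg <= 0) or np.any(xh <= 0) or np.any(xy <= 0):
            raise DomainError(f"{comb} form requires positive predictors")
        if comb == "mult":
            if np.any(y <= 0):
                raise DomainError("mult form requires positive sugar values")
            # log-linear warm start: ln y = ln a + g ln xg + h ln xh + c ln xy + theta ln x
            design, names = _design_matrix(
                ModelForm("linear", form.slot), np.log(xg), np.log(xh), np.log(xy),
                np.log(x), k1, k2, reduced)
            _check_rank(design, names)
            beta, *_ = np.linalg.lstsq(design, np.log(y), rcond=None)
            starts = [np.concatenate([[np.exp(beta[0])], beta[1:]])]
        else:
            # addpower has genuine local minima whose residuals are tiny but
            # whose coefficients are far off; a fixed, deterministic ladder of
            # starting points is solved and the lowest-SSE solution kept.
            # Power-term coefficients are warm-started from a log-linear solve
            # of the response shifted by a trial offset a0.
            z = np.log(x)
            cols = [np.ones_like(z), z] + ([] if reduced else [k1 * z, k2 * z])
            a_design = np.column_stack(cols)
            starts = []
            for a0 in (float(np.min(y)) - 1.0, float(np.min(y)) - 2.0, 0.0,
                       float(np.mean(y)) / 2.0):
                bz, *_ = np.linalg.lstsq(a_design, np.log(np.maximum(y - a0, 1e-6)),
                                         rcond=None)
                for ex in (1.0, 0.5):
                    starts.append(np.array([a0, ex, ex, ex, bz[1]]
                                           + ([] if reduced else [bz[2], bz[3]])))
            starts.append(np.array([float(np.mean(y)), 1.0, 1.0, 1.0, 1.0]
                                   + ([] if reduced else [0.0, 0.0])))

        def residuals(p):
            full = np.concatenate([p, [0.0, 0.0]]) if reduced else p
            with np.errstate(over="ignore", invalid="ignore"):
                out = _evaluate(form, full, xg, xh, xy, x, k1, k2) - y
            return np.nan_to_num(out, nan=1e12, posinf=1e12, neginf=-1e12)

        sol = None
        for start in starts:
            cand = least_squares(residuals, start, method="lm",
                                 xtol=_NLS_XTOL, ftol=_NLS_XTOL, gtol=_NLS_XTOL,
                                 max_nfev=_NLS_MAX_ITER)
            if sol is None or cand.cost < sol.cost:
                sol = cand
        if not sol.success:
            raise FittingError(f"nonlinear fit of {form.name} did not converge: {sol.message}")
        p = sol.x
        a, g, h, c, p0 = p[:5]
        p1, p2 = (0.0, 0.0) if reduced else (p[5], p[6])
        full = np.array([a, g, h, c, p0, p1, p2])
        yhat = _evaluate(form, full, xg, xh, xy, x, k1, k2)

    return SugarModel(form=form, a=float(a), g=float(g), h=float(h), c=float(c),
                      p0=float(p0), p1=float(p1), p2=float(p2), reduced=reduced,
                      fit_r2=_fit_r2(y, yhat))


def fit_model(form, dataset: pd.DataFrame,
              dummies: Optional[Sequence[DummyPair]] = None) -> SugarModel:
    """Fit the full (dummy-modulated) model.

    Dummies are assigned from the observed sugar column ``y`` unless an
    explicit sequence is supplied (useful when the true class of each sample
    is known, e.g. in simulation studies).  Linear-in-parameter combinators
    are solved by least squares on the expanded regressors; ``mult`` by
    nonlinear least squares warm-started from a log-linear solve;
    ``addpower`` by nonlinear least squares from the documented fixed
    initialisation.
    """
    return _fit(form, dataset, reduced=False, dummies=dummies)


def fit_reduced(form, dataset: pd.DataFrame,
                dummies: Optional[Sequence[DummyPair]] = None) -> SugarModel:
    """Fit the reduced model (k1 = k2 = 0; theta collapsed to ``p0``)."""
    return _fit(form, dataset, reduced=True, dummies=dummies)


def two_stage_predict(reduced: SugarModel, full: SugarModel, features):
    """Two-stage prediction of a new fruit.

    Stage 1 evaluates the reduced model with (0, 0) dummies; the resulting
    estimate assigns (k1, k2).  Stage 2 evaluates the full model with those
    dummies; the returned label and dummy pair always derive from the
    stage-1 estimate, even when the stage-2 value falls in a different
    interval.
    """
    if reduced.form.combinator != full.form.combinator or reduced.form.slot != full.form.slot:
        raise InvalidInputError(
            f"reduced ({reduced.form.name}) and full ({full.form.name}) models "
            "must share combinator and predictor slot"
        )
    y0 = predict(reduced, features, (0, 0))
    if np.ndim(y0) == 0:
        k = assign_dummies(y0)
        y = predict(full, features, k)
        return float(y), label_for_dummies(k), k
    ks = [assign_dummies(v) for v in y0]
    k1 = np.array([k[0] for k in ks])
    k2 = np.array([k[1] for k in ks])
    xg, xh, xy, x = _as_columns(features, full.form)
    coefs = [full.a, full.g, full.h, full.c, full.p0, full.p1, full.p2]
    y = _evaluate(full.form, coefs, xg, xh, xy, x, k1, k2)
    labels = [label_for_dummies(k) for k in ks]
    return np.asarray(y), labels, ks


def error_analysis(y_obs: Sequence[float], y_pred: Sequence[float]) -> ErrorReport:
    """Validation residual summaries.

    ``e_bar`` is the signed mean residual; ``delta2`` the residual sum of
    squares over ``n - 1``; ``mse = e_bar^2 + delta2``; the combined
    root error is its square root (the scale on which model tables usually
    report it); ``val_r2`` the squared Pearson correlation of observed and
    predicted values (0 when either side is constant).
    """
    yo = np.asarray(y_obs, dtype=np.float64).ravel()
    yp = np.asarray(y_pred, dtype=np.float64).ravel()
    if yo.size != yp.size:
        raise InvalidInputError(f"length mismatch: {yo.size} vs {yp.size}")
    if yo.size < 2:
        raise InvalidInputError("need at least two validation samples")
    resid = yo - yp
    e_bar = float(resid.mean())
    delta2 = float(np.sum(resid**2) / (yo.size - 1))
    mse = e_bar**2 + delta2
    if np.std(yo) == 0.0 or np.std(yp) == 0.0:
        val_r2 = 0.0
    else:
        val_r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    return ErrorReport(e_bar=e_bar, delta2=delta2, mse=mse,
                       rmse_combined=float(np.sqrt(mse)), val_r2=val_r2, n=int(yo.size))


def combined_error(e_bar: float, delta2: float) -> float:
    """Combined root error ``sqrt(e_bar^2 + delta2)`` from residual summaries."""
    if not (np.isfinite(e_bar) and np.isfinite(delta2)) or delta2 < 0:
        raise InvalidInputError("e_bar must be finite and delta2 a finite non-negative value")
    return float(np.sqrt(e_bar**2 + delta2))


#: Indicator orientation for rank scoring: True = higher is better.
_INDICATORS = {"fit_r2": True, "e_bar": False, "rmse_combined": False, "val_r2": True}


def rank_models(table: Mapping[str, Mapping[str, float]]) -> ScoreCard:
    """Rank-score competing models and select the lowest total.

    Each of the four indicators (fitting R^2, validation mean residual,
    combined root error, validation R^2) is ranked across models, best = 1,
    ties sharing the best rank.  The two R^2 indicators rank higher-better;
    the residual indicators rank smaller-magnitude-better.  The model with
    the minimal rank total wins; ties break by fitting R^2, then by
    declaration order.
    """
    if len(table) == 0:
        raise InvalidInputError("need at least one model to rank")
    names = list(table.keys())
    df = pd.DataFrame({m: {k: float(table[m][k]) for k in _INDICATORS} for m in names}).T
    if not np.all(np.isfinite(df.to_numpy())):
        raise InvalidInputError("all indicator values must be finite")
    ranks = pd.DataFrame(index=names, columns=list(_INDICATORS), dtype=float)
    for ind, higher_better in _INDICATORS.items():
        vals = df[ind]
        if not higher_better:
            vals = vals.abs()
        ranks[ind] = vals.rank(method="min", ascending=not higher_better)
    totals = ranks.sum(axis=1)
    best_total = totals.min()
    candidates = [m for m in names if totals[m] == best_total]
    if len(candidates) > 1:
        best_r2 = max(df.loc[m, "fit_r2"] for m in candidates)
        candidates = [m for m in candidates if df.loc[m, "fit_r2"] == best_r2]
    return ScoreCard(names=names, ranks=ranks, totals=totals, selected=candidates[0])
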