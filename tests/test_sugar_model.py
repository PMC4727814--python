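"""Dummy-variable sugar models: coding, fitting, prediction, error analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citrusbrix import (
    DatasetSimConfig,
    ModelForm,
    SugarModel,
    assign_dummies,
    classify_sweetness,
    combined_error,
    error_analysis,
    fit_model,
    fit_reduced,
    gen_feature_dataset,
    predict,
    rank_models,
    two_stage_predict,
)
from citrusbrix.errors import DomainError, FittingError, InvalidInputError
from citrusbrix.synthetic import TRUE_COEFFICIENTS, true_model

brix = st.floats(min_value=0.0, max_value=53.0, allow_nan=False)


def make_model(comb="ratio", slot="x_p", **kw):
    coefs = dict(a=0.0, g=0.0, h=0.0, c=0.0, p0=0.0, p1=0.0, p2=0.0)
    coefs.update(kw)
    return SugarModel(form=ModelForm(comb, slot), **coefs)


FEATURES = {"x_g": 0.45, "x_h": 0.5, "x_y": 0.66, "x_p": 0.5, "x_w": 100.0}


class TestDummyCoding:
    @pytest.mark.parametrize(
        "y, pair, label",
        [
            (10.0, (1, 0), "semisweet"),
            (10.5, (1, 0), "semisweet"),
            (11.0, (0, 1), "sweet"),  # closed lower boundary of the middle class
            (13.7, (0, 1), "sweet"),
            (14.0, (0, 1), "sweet"),  # closed upper boundary
            (14.0001, (1, 1), "verysweet"),
            (18.0, (1, 1), "verysweet"),
        ],
    )
    def test_boundaries(self, y, pair, label):
        assert assign_dummies(y) == pair
        assert classify_sweetness(y) == label

    @given(y=brix)
    @settings(max_examples=300, derandomize=True)
    def test_labels_and_dummies_induce_same_partition(self, y):
        pair = assign_dummies(y)
        label = classify_sweetness(y)
        assert {(1, 0): "semisweet", (0, 1): "sweet", (1, 1): "verysweet"}[pair] == label

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            assign_dummies(float("nan"))
        with pytest.raises(InvalidInputError):
            classify_sweetness(float("inf"))


class TestPredict:
    def test_constant_model(self):
        m = make_model("linear", a=12.5)
        assert predict(m, FEATURES, (1, 1)) == 12.5

    def test_ratio_hand_value(self):
        # 10 + 2 / 0.5 = 14
        m = make_model("ratio", a=10.0, p0=2.0)
        assert predict(m, FEATURES, (0, 0)) == pytest.approx(14.0)

    def test_reduced_ratio_hand_evaluation(self):
        # a realistic reduced ratio model evaluated by independent arithmetic
        a, g, h, c, p0 = 19.0976, -4.7363, 4.3117, -42.4450, 44.8600
        m = make_model("ratio", a=a, g=g, h=h, c=c, p0=p0)
        f = {"x_g": 0.45, "x_h": 0.5, "x_y": 0.66, "x_p": 4.0}
        expected = a + g * 0.45 + h * 0.5 + c * 0.66 + p0 / 4.0
        assert predict(m, f, (0, 0)) == pytest.approx(expected, abs=1e-12)

    def test_dummies_modulate_theta(self):
        m = make_model("linear", p0=1.0, p1=2.0, p2=3.0)
        x = FEATURES["x_p"]
        assert predict(m, FEATURES, (0, 0)) == pytest.approx(1.0 * x)
        assert predict(m, FEATURES, (1, 0)) == pytest.approx(3.0 * x)
        assert predict(m, FEATURES, (0, 1)) == pytest.approx(4.0 * x)
        assert predict(m, FEATURES, (1, 1)) == pytest.approx(6.0 * x)

    def test_mult_and_addpower_forms(self):
        f = {"x_g": 0.5, "x_h": 0.5, "x_y": 0.5, "x_p": 0.25}
        m = make_model("mult", a=2.0, g=1.0, h=0.0, c=0.0, p0=-1.0)
        assert predict(m, f, (0, 0)) == pytest.approx(2.0 * 0.5 * 4.0)
        m = make_model("addpower", a=1.0, g=1.0, h=1.0, c=1.0, p0=0.5)
        assert predict(m, f, (0, 0)) == pytest.approx(1.0 + 0.125 + 0.5)

    def test_weight_slot_reads_x_w(self):
        m = make_model("ratio", slot="x_w", p0=50.0)
        assert predict(m, FEATURES, (0, 0)) == pytest.approx(0.5)

    def test_nonpositive_predictor_rejected_in_ratio(self):
        m = make_model("ratio", a=10.0, p0=1.0)
        with pytest.raises(DomainError):
            predict(m, {**FEATURES, "x_p": 0.0}, (0, 0))

    def test_vectorized_over_dataframe(self):
        m = make_model("linear", a=1.0, p0=2.0)
        df = pd.DataFrame({"x_g": [0.4, 0.5], "x_h": [0.5, 0.6], "x_y": [0.6, 0.7],
                           "x_p": [0.1, 0.2]})
        out = predict(m, df, (0, 0))
        assert np.allclose(out, [1.2, 1.4])


class TestFitModel:
    @pytest.mark.parametrize("comb", ["ratio", "linear", "mult", "addpower"])
    def test_noise_free_recovery(self, comb):
        cfg = DatasetSimConfig(form=f"{comb}_xp", noise_sd=0.0, seed=3)
        df = gen_feature_dataset(cfg)
        m = fit_model(cfg.form, df)
        truth = np.array(TRUE_COEFFICIENTS[comb])
        est = np.array([m.a, m.g, m.h, m.c, m.p0, m.p1, m.p2])
        rel = np.max(np.abs(est - truth) / np.abs(truth))
        assert rel < 1e-6
        assert m.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # independent normal-equations solve on a small linear-form fixture
        rng = np.random.default_rng(5)
        n = 10
        df = pd.DataFrame({
            "x_g": rng.uniform(0.3, 0.6, n), "x_h": rng.uniform(0.4, 0.7, n),
            "x_y": rng.uniform(0.6, 0.8, n), "x_p": rng.uniform(0.1, 0.3, n),
        })
        df["y"] = rng.uniform(9.0, 18.0, n)
        k = np.array([assign_dummies(v) for v in df["y"]], dtype=float)
        z = df["x_p"].to_numpy()
        design = np.column_stack([np.ones(n), df["x_g"], df["x_h"], df["x_y"],
                                  z, k[:, 0] * z, k[:, 1] * z])
        beta = np.linalg.solve(design.T @ design, design.T @ df["y"].to_numpy())
        m = fit_model("linear_xp", df)
        est = np.array([m.a, m.g, m.h, m.c, m.p0, m.p1, m.p2])
        assert np.allclose(est, beta, rtol=1e-8)

    def test_residuals_orthogonal_to_design(self, ratio_dataset):
        m = fit_model("ratio_xp", ratio_dataset)
        df = ratio_dataset
        y = df["y"].to_numpy()
        k = np.array([assign_dummies(v) for v in y], dtype=float)
        z = 1.0 / df["x_p"].to_numpy()
        design = np.column_stack([np.ones(len(df)), df["x_g"], df["x_h"], df["x_y"],
                                  z, k[:, 0] * z, k[:, 1] * z])
        yhat = np.array([predict(m, row, tuple(int(v) for v in kk))
                         for (_, row), kk in zip(df.iterrows(), k)])
        assert np.max(np.abs(design.T @ (y - yhat))) < 1e-8 * np.abs(y).sum()

    def test_constant_target_degenerate(self):
        rng = np.random.default_rng(2)
        n = 12
        df = pd.DataFrame({
            "x_g": rng.uniform(0.3, 0.6, n), "x_h": rng.uniform(0.4, 0.7, n),
            "x_y": rng.uniform(0.6, 0.8, n), "x_p": rng.uniform(0.1, 0.3, n),
            "y": np.full(n, 12.0),
        })
        m = fit_model("linear_xp", df)
        assert m.fit_r2 == 0.0  # SST = 0 by convention
        assert predict(m, df.iloc[0], (0, 1)) == pytest.approx(12.0, abs=1e-6)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(3)
        n = 12
        xg = rng.uniform(0.3, 0.6, n)
        df = pd.DataFrame({
            "x_g": xg, "x_h": rng.uniform(0.4, 0.7, n),
            "x_y": 0.5 * xg + 0.1,  # exactly affine in x_g
            "x_p": rng.uniform(0.1, 0.3, n), "y": rng.uniform(9, 18, n),
        })
        with pytest.raises(FittingError, match="x_y"):
            fit_model("linear_xp", df)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"x_g": [0.4], "x_h": [0.5], "x_y": [0.6], "x_p": [0.2], "y": [12.0]})
        with pytest.raises(InvalidInputError):
            fit_model("ratio_xp", df)


class TestFitReduced:
    def test_zero_dummy_recovery(self):
        coefs = (6.2, -3.0, 3.0, -5.0, 1.82, 0.0, 0.0)
        cfg = DatasetSimConfig(form="ratio_xp", noise_sd=0.0, seed=5, coefficients=coefs)
        df = gen_feature_dataset(cfg)
        red = fit_reduced("ratio_xp", df)
        est = np.array([red.a, red.g, red.h, red.c, red.p0])
        rel = np.max(np.abs(est - np.array(coefs[:5])) / np.abs(np.array(coefs[:5])))
        assert rel < 1e-6
        assert red.p1 == 0.0 and red.p2 == 0.0 and red.reduced

    def test_reduced_never_beats_full(self, ratio_dataset):
        full = fit_model("ratio_xp", ratio_dataset)
        red = fit_reduced("ratio_xp", ratio_dataset)
        assert red.fit_r2 <= full.fit_r2 + 1e-12


class TestTwoStagePredict:
    def test_constant_chain(self):
        red = make_model("linear", a=12.0)
        red.reduced = True
        full = make_model("linear", a=12.0)
        y, label, k = two_stage_predict(red, full, FEATURES)
        assert y == 12.0 and label == "sweet" and k == (0, 1)

    def test_label_comes_from_stage_one(self):
        # stage 1 lands in "sweet"; stage 2 value is pushed above 14 but the
        # returned dummies and label stay stage-1's
        red = make_model("linear", a=12.0)
        full = make_model("linear", a=12.0, p0=0.0, p2=10.0)
        y, label, k = two_stage_predict(red, full, FEATURES)
        assert y == pytest.approx(12.0 + 10.0 * FEATURES["x_p"])
        assert k == (0, 1) and label == "sweet"

    def test_mismatched_family_rejected(self):
        with pytest.raises(InvalidInputError):
            two_stage_predict(make_model("linear"), make_model("ratio", a=1.0, p0=1.0), FEATURES)

    def test_low_noise_label_accuracy(self):
        from citrusbrix import split_dataset

        hits = total = 0
        for seed in range(5):
            cfg = DatasetSimConfig(noise_sd=0.3, class_margin=0.3, seed=seed)
            df = gen_feature_dataset(cfg)
            fit_df, val_df = split_dataset(df, 45, seed=seed)
            full = fit_model(cfg.form, fit_df)
            red = fit_reduced(cfg.form, fit_df)
            _, labels, _ = two_stage_predict(red, full, val_df)
            hits += int(np.sum(np.array(labels) == val_df["label_true"].to_numpy()))
            total += len(val_df)
        assert hits / total >= 0.90


class TestErrorAnalysis:
    def test_perfect_prediction(self):
        rep = error_analysis([10, 12, 14], [10, 12, 14])
        assert rep.e_bar == 0.0 and rep.delta2 == 0.0 and rep.mse == 0.0

    def test_hand_arithmetic(self):
        rep = error_analysis([1, 2, 3], [1, 1, 1])
        assert rep.e_bar == pytest.approx(1.0)
        assert rep.delta2 == pytest.approx(5 / 2)
        assert rep.mse == pytest.approx(7 / 2)

    def test_combined_error_reference_cells(self):
        # the combined root error reproduces reported validation cells to 4 dp
        assert combined_error(0.1072, 0.3764) == pytest.approx(0.6228, abs=5e-5)
        assert combined_error(0.0832, 0.3875) == pytest.approx(0.6280, abs=5e-5)

    def test_identities(self, rng):
        yo = rng.uniform(9, 18, 20)
        yp = yo + rng.normal(0, 0.6, 20)
        rep = error_analysis(yo, yp)
        assert rep.mse == pytest.approx(rep.e_bar**2 + rep.delta2, abs=1e-12)
        assert rep.rmse_combined**2 == pytest.approx(rep.mse, abs=1e-12)
        assert rep.rmse_combined == pytest.approx(combined_error(rep.e_bar, rep.delta2), abs=1e-15)

    def test_val_r2_is_squared_correlation(self, rng):
        yo = rng.uniform(9, 18, 15)
        yp = 0.8 * yo + rng.normal(0, 0.5, 15)
        rep = error_analysis(yo, yp)
        assert rep.val_r2 == pytest.approx(np.corrcoef(yo, yp)[0, 1] ** 2, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(InvalidInputError):
            error_analysis([1.0], [1.0])


def brute_force_ranks(values, higher_better):
    """Sorting oracle: rank = 1 + number of strictly better entries."""
    out = []
    for v in values:
        better = sum(1 for w in values if (w > v if higher_better else w < v))
        out.append(1 + better)
    return out


class TestRankModels:
    def test_single_model(self):
        card = rank_models({"only": dict(fit_r2=0.9, e_bar=0.1, rmse_combined=0.5, val_r2=0.85)})
        assert card.totals["only"] == 4.0
        assert card.selected == "only"

    def test_dominant_model_selected(self):
        card = rank_models({
            "weak": dict(fit_r2=0.7, e_bar=0.3, rmse_combined=0.9, val_r2=0.6),
            "strong": dict(fit_r2=0.9, e_bar=0.1, rmse_combined=0.5, val_r2=0.9),
            "mid": dict(fit_r2=0.8, e_bar=0.2, rmse_combined=0.7, val_r2=0.7),
        })
        assert card.totals["strong"] == 4.0
        assert card.selected == "strong"

    def test_matches_sorting_oracle(self):
        table = {
            "m1": dict(fit_r2=0.85, e_bar=0.11, rmse_combined=0.62, val_r2=0.89),
            "m2": dict(fit_r2=0.83, e_bar=0.18, rmse_combined=0.69, val_r2=0.87),
            "m3": dict(fit_r2=0.85, e_bar=0.08, rmse_combined=0.63, val_r2=0.89),
        }
        card = rank_models(table)
        for ind, hb in [("fit_r2", True), ("e_bar", False), ("rmse_combined", False), ("val_r2", True)]:
            expected = brute_force_ranks([abs(table[m][ind]) if not hb else table[m][ind]
                                          for m in table], hb)
            assert list(card.ranks[ind]) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            rank_models({"m": dict(fit_r2=float("nan"), e_bar=0.1, rmse_combined=0.5, val_r2=0.8)})


class TestWeightSubstitution:
    def test_proportional_weight_rescales_theta_only(self, ratio_dataset):
        # exact proportionality x_w = alpha * x_p: theta coefficients scale by
        # alpha and predictions are unchanged (ratio form)
        alpha = 430.0
        df = ratio_dataset.copy()
        df["x_w"] = alpha * df["x_p"]
        mp = fit_model("ratio_xp", df)
        mw = fit_model("ratio_xw", df)
        assert np.allclose([mw.p0, mw.p1, mw.p2],
                           [alpha * mp.p0, alpha * mp.p1, alpha * mp.p2], rtol=1e-9)
        assert np.allclose([mw.a, mw.g, mw.h, mw.c], [mp.a, mp.g, mp.h, mp.c], rtol=1e-9)
        k = (0, 1)
        yp = predict(mp, df, k)
        yw = predict(mw, df, k)
        assert np.allclose(yp, yw, atol=1e-9)


class TestSerialization:
    def test_roundtrip(self):
        m = make_model("ratio", a=6.2, g=-3.0, h=3.0, c=-5.0, p0=1.79, p1=-0.02, p2=0.07)
        m.fit_r2 = 0.93
        m2 = SugarModel.from_dict(m.to_dict())
        assert m2.coefficients == m.coefficients
        assert m2.form == m.form and m2.fit_r2 == 0.93

    def test_generating_model_consistency(self):
        tm = true_model(DatasetSimConfig())
        assert tm.form.name == "ratio_xp"
        assert (tm.a, tm.p0) == (6.2, 1.79)
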