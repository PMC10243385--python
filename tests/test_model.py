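"""Ridge fitting, fit statistics and the SRM complexity score."""

import math

import numpy as np
import pandas as pd
import pytest

import asmod
from asmod.model import (
    ModelConfig,
    anova_f,
    design_matrix,
    effective_params,
    fit_ridge,
    r_squared,
    srm_score,
)


class TestDesignMatrix:
    def test_single_block_rows_sum_to_one(self, design24):
        subs = asmod.model.build_structure([(("plga_pct", "speed_rpm"), (3, 3))])
        X = design_matrix(subs, design24.to_frame()[list(asmod.INPUT_COLUMNS)])
        assert X.shape == (24, 9)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_two_blocks_sum_to_two(self, design24):
        subs = asmod.model.build_structure(
            [(("drug_pct", "plga_pct"), (2, 2)), (("pva_pct",), (3,))]
        )
        X = design_matrix(subs, design24.to_frame()[list(asmod.INPUT_COLUMNS)])
        assert X.shape == (24, 7)
        assert np.allclose(X.sum(axis=1), 2.0)

    def test_design_rows_are_one_hot(self, design24):
        subs = asmod.model.build_structure([(("plga_pct", "speed_rpm"), (3, 3))])
        X = design_matrix(subs, design24.to_frame()[list(asmod.INPUT_COLUMNS)])
        assert np.all(np.isin(X, [0.0, 1.0]))

    def test_empty_structure_rejected(self, design24):
        with pytest.raises(ValueError):
            design_matrix([], design24.to_frame())


class TestFitRidge:
    def test_saturated_fit_equals_cell_means(self, design24, size_results):
        """Group-mean oracle: a saturated one-hot basis fits within-cell means."""
        frame = design24.to_frame()
        oracle = frame.groupby(["plga_pct", "speed_rpm"])["size_um"].transform("mean")
        assert np.allclose(
            size_results.fittedvalues, oracle.to_numpy(), rtol=1e-3
        )
        # the (plga=20, speed=1000) cell is the single run at 827.60
        assert size_results.predict(
            {"plga_pct": 20.0, "speed_rpm": 1000.0}
        ) == pytest.approx(827.60, rel=1e-3)

    def test_huge_ridge_shrinks_to_zero(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        w = fit_ridge(X, y, ridge_factor=1e12)
        assert np.max(np.abs(w)) < 1e-6

    def test_duplicate_column_still_solvable(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        y = x[:, 0] * 2.0
        w = fit_ridge(X, y, ridge_factor=1e-6)
        assert np.all(np.isfinite(w))
        assert np.allclose(X @ w, y, atol=1e-4)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            fit_ridge(rng.normal(size=(10, 2)), rng.normal(size=8), 1e-6)


class TestRSquared:
    def test_perfect_fit_is_100(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == pytest.approx(100.0)

    def test_mean_predictor_is_zero(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(10), np.ones(10))


class TestAnova:
    def test_df_identity_across_paper_models(
        self, size_results, dl_results, uniformity_results, ee_results
    ):
        for res, (df1, df2) in [
            (size_results, (9, 14)),
            (uniformity_results, (13, 10)),
            (ee_results, (11, 4)),
            (dl_results, (4, 19)),
        ]:
            a = res.anova
            assert (a.df1, a.df2) == (df1, df2)
            assert a.df1 + a.df2 == res.nobs - 1

    def test_perfect_fit_reports_infinite_f(self, rng):
        y = rng.normal(size=12)
        report = anova_f(y, y, p_params=3)
        assert math.isinf(report.f_ratio)
        assert report.alpha_band == "<0.01"

    def test_no_residual_df_rejected(self, rng):
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            anova_f(y, y, p_params=4)


class TestSrm:
    def test_p_zero_closed_form(self):
        n = 24
        s = srm_score(1.0, 0, n)
        assert s.penalty == pytest.approx(1.0 / (1.0 - math.sqrt(math.log(n) / (2 * n))))
        assert s.penalty > 1.0

    def test_monotone_in_p_until_collapse(self):
        n = 24
        penalties = [srm_score(1.0, p, n).penalty for p in range(0, n + 1)]
        finite = [p for p in penalties if math.isfinite(p)]
        assert all(b > a for a, b in zip(finite, finite[1:]))
        assert math.isinf(penalties[-1])  # p = n

    @pytest.mark.parametrize("n", [8, 16, 24])
    def test_p_at_least_n_is_infinite(self, n):
        assert math.isinf(srm_score(0.5, n, n).score)
        assert math.isinf(srm_score(0.5, n + 3, n).score)

    def test_score_is_mse_times_penalty(self):
        s = srm_score(2.5, 4, 24)
        assert s.score == pytest.approx(s.mse * s.penalty)


class TestEffectiveParams:
    def test_shared_constant_discount(self):
        subs = asmod.model.build_structure(
            [
                (("drug_pct", "speed_rpm"), (2, 3)),
                (("pva_pct",), (2,)),
                (("time_s", "ow_ratio"), (3, 2)),
                (("dilution_ratio",), (2,)),
            ]
        )
        assert sum(s.basis_size for s in subs) == 16
        assert effective_params(subs) == 13


class TestModelFit:
    def test_nested_density_increase_never_lowers_r2(self, design24):
        r2 = []
        for dens in [(2, 2), (3, 2), (3, 3)]:
            res = asmod.NeurofuzzyModel.from_dataset(
                design24, "size_um", [(("plga_pct", "speed_rpm"), dens)]
            ).fit()
            r2.append(res.rsquared)
        assert r2[0] <= r2[1] + 1e-9 <= r2[2] + 2e-9

    def test_noise_free_bilinear_coefficient_recovery(self):
        corners = np.array([[0.0, 1.0], [2.0, 5.0]])
        gt = asmod.GroundTruth(
            terms=((("drug_pct", "plga_pct"), corners),), noise_sd=0.0, seed=3
        )
        ds = asmod.simulate_dataset(gt, n_runs=24)
        frame = ds.to_frame()
        res = asmod.NeurofuzzyModel(
            endog=frame["size_um"].to_numpy(),
            exog=frame[list(asmod.INPUT_COLUMNS)],
            submodels=[(("drug_pct", "plga_pct"), (2, 2))],
        ).fit()
        assert np.allclose(res.params, corners.ravel(), atol=1e-6)

    def test_zero_coefficients_predict_zero(self, size_results):
        res = asmod.NeurofuzzyResults(
            model=size_results.model, params=np.zeros_like(size_results.params)
        )
        assert res.predict({"plga_pct": 13.0, "speed_rpm": 2600.0}) == 0.0

    def test_prediction_requires_all_inputs(self, size_results):
        with pytest.raises(KeyError):
            size_results.predict({"plga_pct": 15.0})

    def test_out_of_domain_prediction_respects_clamp_flag(self, design24):
        config = ModelConfig(clamp_out_of_domain=False)
        res = asmod.NeurofuzzyModel.from_dataset(
            design24, "size_um", [(("plga_pct", "speed_rpm"), (3, 3))], config=config
        ).fit()
        with pytest.raises(ValueError, match="outside domain"):
            res.predict({"plga_pct": 25.0, "speed_rpm": 2000.0})

    def test_summary_mentions_structure_and_quality(self, size_results):
        text = size_results.summary()
        assert "plga_pct" in text and "speed_rpm" in text
        assert "92.90" in text

    def test_serialization_contains_statistics(self, dl_results):
        import json

        d = json.loads(dl_results.to_json())
        assert d["n_obs"] == 24
        assert d["p_params"] == 4
        assert d["anova"]["df2"] == 19
        assert len(d["coefficients"]) == 4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(ridge_factor=0.0)
        with pytest.raises(ValueError):
            ModelConfig(allowed_densities=(1, 2))
        with pytest.raises(ValueError):
            ModelConfig(selection_criterion="bic")
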