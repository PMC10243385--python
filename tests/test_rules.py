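"""Rule extraction, decision trees and partial-effect grids."""

import numpy as np
import pytest

import asmod
from asmod.rules import (
    extract_rules,
    partial_effect_grid,
    rules_from_tree,
    rules_table,
    to_decision_tree,
)


class TestExtractRules:
    def test_size_model_has_nine_rules(self, size_results):
        rules = extract_rules(size_results)
        assert len(rules) == 9
        assert [r.rule_id for r in rules] == list(range(1, 10))

    def test_big_particle_corner_has_degree_one(self, size_results):
        rules = extract_rules(size_results)
        top = max(rules, key=lambda r: r.membership_degree)
        assert dict(top.antecedents) == {"plga_pct": "HIGH", "speed_rpm": "LOW"}
        assert top.consequent_label == "HIGH"
        assert top.membership_degree == pytest.approx(1.0)
        assert top.corner_value == pytest.approx(827.60, rel=1e-3)

    def test_degrees_span_unit_interval(self, size_results, uniformity_results):
        for res in (size_results, uniformity_results):
            for k in range(len(res.model.submodels)):
                degs = [
                    r.membership_degree
                    for r in extract_rules(res)
                    if r.submodel_id == k
                ]
                assert min(degs) == pytest.approx(0.0)
                assert max(degs) == pytest.approx(1.0)
                assert all(0.0 <= d <= 1.0 for d in degs)

    def test_rule_count_matches_density_products(self, uniformity_results):
        # submodels 2x3 + 2 + 3x2 + 2 -> 6 + 2 + 6 + 2 = 16 rules
        assert len(extract_rules(uniformity_results)) == 16

    def test_monotone_univariate_submodel_has_increasing_degrees(self, design24):
        res = asmod.NeurofuzzyModel.from_dataset(
            design24, "dl_pct", [(("drug_pct",), (3,))], missing_policy="zero_fill"
        ).fit()
        rules = extract_rules(res)
        degs = [r.membership_degree for r in rules]
        assert degs == sorted(degs)  # loading grows with drug fraction

    def test_degrees_invariant_to_affine_response_rescale(self, design24):
        base = asmod.NeurofuzzyModel.from_dataset(
            design24, "size_um", [(("plga_pct", "speed_rpm"), (3, 3))]
        ).fit()
        frame = design24.to_frame()
        scaled_model = asmod.NeurofuzzyModel(
            endog=3.0 * frame["size_um"].to_numpy() + 100.0,
            exog=frame[list(asmod.INPUT_COLUMNS)],
            submodels=[(("plga_pct", "speed_rpm"), (3, 3))],
        )
        scaled = scaled_model.fit()
        d1 = [r.membership_degree for r in extract_rules(base)]
        d2 = [r.membership_degree for r in extract_rules(scaled)]
        # exact up to the tiny ridge term, which is not affine-equivariant
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_degenerate_submodel_flagged_at_half_degree(self, design24):
        frame = design24.to_frame()
        res = asmod.NeurofuzzyModel(
            endog=np.full(24, 5.0) + 1e-9 * np.arange(24),  # nearly constant
            exog=frame[list(asmod.INPUT_COLUMNS)],
            submodels=[(("pva_pct",), (2,))],
        ).fit()
        rules = extract_rules(res)
        assert all(r.degenerate for r in rules)
        assert all(r.membership_degree == 0.5 for r in rules)

    def test_rules_table_layout(self, size_results):
        text = rules_table(extract_rules(size_results), "size_um")
        assert "IF" in text and "THEN" in text
        assert text.count("\n") >= 10


class TestDecisionTree:
    def test_density_two_input_splits_at_domain_midpoint(self, dl_results):
        tree = to_decision_tree(dl_results)
        (subtree,) = tree.subtrees
        assert subtree.thresholds == ((1.0,), (15.0,))  # midpoints of (0,2), (10,20)

    def test_three_set_speed_splits_at_1500_and_2500(self, size_results):
        tree = to_decision_tree(size_results)
        (subtree,) = tree.subtrees
        assert subtree.thresholds[1] == pytest.approx((1500.0, 2500.0))

    def test_routes_big_particle_corner_to_maximum_band_leaf(self, size_results):
        tree = to_decision_tree(size_results)
        leaf = tree.subtrees[0].route({"plga_pct": 20.0, "speed_rpm": 1000.0})
        top = max(tree.subtrees[0].leaves, key=lambda l: l.band[1])
        assert leaf is top
        corner = size_results.predict({"plga_pct": 20.0, "speed_rpm": 1000.0})
        assert leaf.band[0] - 1e-9 <= corner <= leaf.band[1] + 1e-9

    @pytest.mark.parametrize("fixture", ["size_results", "uniformity_results"])
    def test_band_contains_model_prediction(self, fixture, request, rng):
        res = request.getfixturevalue(fixture)
        tree = to_decision_tree(res)
        domains = res.model.input_domains
        for _ in range(200):
            point = {
                name: float(rng.uniform(*domains[name]))
                for name in asmod.INPUT_COLUMNS
            }
            lo, hi = tree.predict_band(point)
            value = res.predict(point)
            assert lo - 1e-9 <= value <= hi + 1e-9

    def test_round_trip_preserves_labels_and_degrees(self, uniformity_results):
        rules = extract_rules(uniformity_results)
        rebuilt = rules_from_tree(to_decision_tree(uniformity_results))
        assert len(rebuilt) == len(rules)
        for a, b in zip(rules, rebuilt):
            assert a.rule_id == b.rule_id
            assert a.consequent_label == b.consequent_label
            assert a.membership_degree == pytest.approx(b.membership_degree)
            assert a.antecedents == b.antecedents

    def test_dot_export_is_valid_ish(self, size_results):
        dot = to_decision_tree(size_results).to_dot()
        assert dot.startswith("digraph")
        assert dot.rstrip().endswith("}")
        assert dot.count("->") >= 12


class TestPartialEffectGrid:
    def test_design_level_grid_reproduces_cell_means(self, design24, size_results):
        grid = partial_effect_grid(size_results, ("plga_pct", "speed_rpm"), resolution=3)
        oracle = (
            design24.to_frame()
            .groupby(["plga_pct", "speed_rpm"])["size_um"]
            .mean()
            .unstack()
            .to_numpy()
        )
        assert grid.values == pytest.approx(oracle, rel=1e-3)

    def test_resolution_one_evaluates_midpoint(self, size_results):
        grid = partial_effect_grid(size_results, "plga_pct", resolution=1)
        assert grid.axes[0] == pytest.approx([15.0])
        assert grid.values.shape == (1,)
        expected = size_results.predict({"plga_pct": 15.0, "speed_rpm": 2000.0})
        assert grid.values[0] == pytest.approx(expected)

    def test_transpose_symmetry(self, size_results):
        ab = partial_effect_grid(size_results, ("plga_pct", "speed_rpm"), resolution=7)
        ba = partial_effect_grid(size_results, ("speed_rpm", "plga_pct"), resolution=7)
        assert ab.values == pytest.approx(ba.values.T)

    def test_unknown_input_rejected(self, size_results):
        with pytest.raises(KeyError):
            partial_effect_grid(size_results, "pva_pct")

    def test_additive_offset_submodels_contribute_their_mean(self, uniformity_results):
        grid = partial_effect_grid(uniformity_results, "pva_pct", resolution=5)
        res = uniformity_results
        own = [k for k, s in enumerate(res.model.submodels) if "pva_pct" in s.inputs]
        others = sum(
            res.mean_contribution(k)
            for k in range(len(res.model.submodels))
            if k not in own
        )
        manual = others + res.submodel_contribution(own[0], {"pva_pct": grid.axes[0]})
        assert grid.values == pytest.approx(manual)

    def test_long_frame_export(self, size_results):
        grid = partial_effect_grid(size_results, ("plga_pct", "speed_rpm"), resolution=4)
        frame = grid.to_frame()
        assert list(frame.columns) == ["plga_pct", "speed_rpm", "predicted"]
        assert len(frame) == 16
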