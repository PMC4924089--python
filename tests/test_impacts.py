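"""Condition construction, permutation testing, effect sizes, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import otogrowth as og
from otogrowth.exceptions import EmptyCellError, InsufficientDataError


def crossed_table(a_vals, b_vals, response=1.0):
    rows = [
        {"temperature": a, "tide": b, "waves": 0.0, "turbidity": 0.0,
         "gi_s": response}
        for a in a_vals
        for b in b_vals
    ]
    return pd.DataFrame(rows)


class TestBuildConditions:
    def test_bruteforce_binning(self):
        """Values 1..8 crossed: 16 of 64 rows land in each corner cell."""
        table = crossed_table(range(1, 9), range(1, 9))
        design, assigned = og.build_conditions(
            table, ("temperature", "tide"), {"temperature": -1, "tide": -1}
        )
        lo, hi = np.quantile(np.arange(1, 9), [0.25, 0.75])
        assert design.cuts["temperature"] == (lo, hi)
        # brute-force oracle: low = {1, 2}, high = {7, 8} under linear
        # quantiles, so each corner cell holds 2 x 2 = 4 of the 64 rows
        assert {v for v in range(1, 9) if v <= lo} == {1, 2}
        assert {v for v in range(1, 9) if v >= hi} == {7, 8}
        counts = assigned["condition"].value_counts()
        assert sorted(counts) == [4, 4, 4, 4]
        # exhaustive & exclusive over retained rows
        assert counts.sum() == len(assigned)
        assert set(assigned["condition"]) == set(og.impacts.CONDITIONS)

    def test_negative_sign_puts_control_at_low(self):
        table = crossed_table(range(1, 9), range(1, 9))
        design, _ = og.build_conditions(
            table, ("temperature", "tide"), {"temperature": -1, "tide": -1}
        )
        assert design.labels["control"] == ("low", "low")
        assert design.labels["combined"] == ("high", "high")

    def test_mixed_signs_orient_control(self):
        """Negative temperature and positive waves: control = low temp, high waves."""
        table = crossed_table(range(1, 9), range(1, 9)).rename(
            columns={"tide": "waves_x"}
        )
        table["waves"] = table.pop("waves_x")
        design, _ = og.build_conditions(
            table, ("temperature", "waves"), {"temperature": -1, "waves": +1}
        )
        assert design.orientation == {"temperature": "low", "waves": "high"}
        assert design.labels["control"] == ("low", "high")
        assert design.labels["combined"] == ("high", "low")

    def test_empty_cell_named(self):
        # temperature and tide perfectly associated: no low/high corner rows
        rows = [
            {"temperature": v, "tide": v, "waves": 0.0, "turbidity": 0.0,
             "gi_s": 1.0}
            for v in range(1, 9)
            for _ in range(4)
        ]
        with pytest.raises(EmptyCellError, match="individual"):
            og.build_conditions(
                pd.DataFrame(rows), ("temperature", "tide"),
                {"temperature": -1, "tide": -1},
            )


class TestPermutationTest:
    def test_complete_separation_attains_minimum_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        y = rng.normal(10 * np.std(x) + 10, 1, 20)
        res = og.permutation_test([x, y], n_resamples=999, seed=1)
        assert res["p_value"] == pytest.approx(1 / (1 + 999))

    def test_identical_data_p_one(self):
        x = np.ones(10)
        res = og.permutation_test([x, x.copy()], n_resamples=200, seed=2)
        assert res["p_value"] == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 15), rng.normal(0.7, 1, 15), rng.normal(0, 1, 15)]
        r1 = og.permutation_test(groups, n_resamples=500, seed=7)
        r2 = og.permutation_test(
            [5.0 + 2.0 * g for g in groups], n_resamples=500, seed=7
        )
        assert r1["p_value"] == r2["p_value"]
        assert r1["statistic"] == pytest.approx(r2["statistic"], rel=1e-10)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        g = {"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 12)}
        r1 = og.permutation_test(g, n_resamples=500, seed=9)
        r2 = og.permutation_test(
            {"zz": g["a"], "aa": g["b"]}, n_resamples=500, seed=9
        )
        assert r1["p_value"] == r2["p_value"]

    def test_pairwise_holm_monotone(self):
        rng = np.random.default_rng(5)
        groups = {
            "control": rng.normal(1.0, 0.1, 25),
            "weak": rng.normal(0.97, 0.1, 25),
            "strong": rng.normal(0.5, 0.1, 25),
        }
        res = og.permutation_test(groups, n_resamples=999, seed=11)
        pw = res["pairwise"]
        assert pw.loc["control", "strong"] < 0.01
        assert (pw.to_numpy()[~np.isnan(pw.to_numpy())] <= 1).all()

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            og.permutation_test([[1.0], [2.0, 3.0]], n_resamples=10, seed=0)


def oracle_cohens_d(condition, control):
    """Hand-coded pooled-SD d, independent of the implementation."""
    n1, n2 = len(control), len(condition)
    m1 = sum(control) / n1
    m2 = sum(condition) / n2
    v1 = sum((v - m1) ** 2 for v in control) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in condition) / (n2 - 1)
    sp = (((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)) ** 0.5
    return (m1 - m2) / sp


class TestCohensD:
    def test_equal_means_zero(self):
        assert og.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_one_pooled_sd(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        y = x + np.std(x, ddof=1)  # means exactly one pooled SD apart
        assert og.cohens_d(y, x) == pytest.approx(-1.0, abs=1e-12)
        assert og.cohens_d(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        control = [1.2, 1.0, 1.1, 0.9]
        condition = [0.9, 0.7, 0.8, 0.6]
        assert og.cohens_d(condition, control) == pytest.approx(
            oracle_cohens_d(condition, control), rel=1e-12
        )
        # depressed condition gives positive d
        assert og.cohens_d(condition, control) > 0

    def test_antisymmetry_and_self_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.normal(0, 1, 10), rng.normal(0.4, 1.3, 12)
            assert og.cohens_d(x, y) == pytest.approx(-og.cohens_d(y, x), rel=1e-12)
            assert og.cohens_d(x, x) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            og.cohens_d([1.0, 1.0], [1.0, 1.0])


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "d_a, d_b, d_c, tol, expected",
        [
            # printed effect-size triples for the two covariate pairs: the sum
            # of the individual effects exceeds the combined effect
            (0.58, 1.19, 1.54, 0.0, "antagonistic"),
            (0.79, 1.10, 1.07, 0.0, "antagonistic"),
            (0.5, 0.5, 1.0, 0.0, "additive"),
            (0.5, 0.5, 1.0, 0.3, "additive"),
            (0.3, 0.3, 1.0, 0.1, "synergistic"),
            (0.5, 0.5, 0.7, 0.1, "antagonistic"),
        ],
    )
    def test_rule(self, d_a, d_b, d_c, tol, expected):
        assert og.classify_interaction(d_a, d_b, d_c, tolerance=tol) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(InsufficientDataError):
            og.classify_interaction(np.nan, 0.1, 0.2)

    finite_d = st.floats(-5, 5, allow_nan=False)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(d_a=finite_d, d_b=finite_d, d_c=finite_d,
           tol=st.floats(0, 1, allow_nan=False))
    def test_properties(self, d_a, d_b, d_c, tol):
        """Classification is exhaustive, symmetric in the individual effects,
        and exact equality is always additive."""
        cls = og.classify_interaction(d_a, d_b, d_c, tolerance=tol)
        assert cls in {"additive", "synergistic", "antagonistic"}
        assert cls == og.classify_interaction(d_b, d_a, d_c, tolerance=tol)
        assert (
            og.classify_interaction(d_a, d_b, d_a + d_b, tolerance=tol)
            == "additive"
        )
        if cls == "synergistic":
            assert d_c > d_a + d_b
        elif cls == "antagonistic":
            assert d_c < d_a + d_b


class TestConditionGroupsEndToEnd:
    @pytest.mark.parametrize(
        "interaction_d, expected",
        [(0.0, "additive"), (1.0, "synergistic"), (-1.0, "antagonistic")],
    )
    def test_generated_surface_classified(self, interaction_d, expected):
        hits = 0
        for seed in range(15):
            groups = og.simulate_condition_groups(
                d_a=0.8, d_b=0.8, interaction_d=interaction_d, rng_seed=seed
            )
            d_a = og.cohens_d(groups["individual_a"], groups["control"])
            d_b = og.cohens_d(groups["individual_b"], groups["control"])
            d_c = og.cohens_d(groups["combined"], groups["control"])
            hits += og.classify_interaction(d_a, d_b, d_c) == expected
        assert hits > 15 / 2

    def test_full_analysis_report(self, small_aligned):
        res = og.cumulative_impact_analysis(
            small_aligned,
            ("temperature", "tide"),
            {"temperature": -1.0, "tide": -1.0},
            n_resamples=499,
            seed=21,
        )
        assert 0 < res.p_omnibus <= 1
        assert res.interaction_class in {"additive", "synergistic", "antagonistic"}
        assert res.d_sum == pytest.approx(res.d_individual_a + res.d_individual_b)
        assert set(res.condition_stats.index) == set(og.impacts.CONDITIONS)
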