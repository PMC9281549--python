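"""Outlet indicators: health weight, TUHII/HII/UHII, Z-scores, quartiles, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from opfe.errors import DegenerateInputError, InvalidInputError, StateError
from opfe.indicators import (
    compute_outlet_indicators,
    group_difference_test,
    health_weight,
    hii,
    quartile_labels,
    tuhii,
    uhii,
    z_standardize,
)


class TestHealthWeight:
    def test_bounds_and_ratio(self):
        assert health_weight([0, 0, 0]) == 1.0
        assert health_weight([1, 2, 3, 1]) == 0.0
        assert health_weight([0] * 5 + [1] * 5) == 0.5

    def test_empty_outlet_raises(self):
        with pytest.raises(InvalidInputError):
            health_weight([])

    def test_adding_meals_moves_w_the_right_way(self, rng):
        ls = list(rng.integers(0, 4, size=20))
        w0 = health_weight(ls)
        assert health_weight(ls + [2]) < w0 or w0 == 0.0
        assert health_weight(ls + [0]) >= w0


class TestImpactSums:
    def test_hand_worked_values(self):
        assert tuhii([1], [0.5], [10]) == pytest.approx(5.0)
        assert tuhii([0, 0], [1.0, 0.5], [9, 9]) == 0.0
        assert tuhii([2, 1], [0.5, 1.0], [3, 4]) == pytest.approx(7.0)
        assert hii([1.0], [7]) == pytest.approx(7.0)
        assert hii([0.5, 1.0], [4, 2]) == pytest.approx(4.0)
        assert uhii([1.0, 0.5], [3, 2], w=0.5) == pytest.approx(4.0)
        assert uhii([0.25], [8], w=0.0) == pytest.approx(2.0)

    def test_uhii_includes_healthy_meals_terms(self):
        # no l factor: the healthy meal's sales still count
        with_healthy = uhii([1.0, 0.5], [3, 2], w=0.5)
        only_unhealthy = uhii([1.0], [3], w=0.5)
        assert with_healthy == pytest.approx(only_unhealthy + 0.5 * 2)

    def test_partition_preconditions(self):
        with pytest.raises(InvalidInputError):
            hii([1.0], [1], w=0.5)
        with pytest.raises(InvalidInputError):
            uhii([1.0], [1], w=1.0)

    def test_unnormalized_scores_are_a_state_error(self):
        with pytest.raises(StateError):
            tuhii([1], [np.nan], [1])

    def test_vectorized_equals_per_meal_loop(self, rng):
        for _ in range(200):
            n = rng.integers(1, 30)
            l = rng.integers(0, 4, n)
            r = rng.uniform(0.01, 1.0, n)
            d = rng.uniform(0.01, 1.0, n)
            s = rng.integers(0, 500, n)
            assert tuhii(l, r, s) == pytest.approx(
                sum(l[i] * r[i] * s[i] for i in range(n)), abs=1e-9
            )
            assert uhii(r, s, w=0.0) == pytest.approx(
                sum(r[i] * s[i] for i in range(n)), abs=1e-9
            )
            assert hii(d, s) == pytest.approx(
                sum(d[i] * s[i] for i in range(n)), abs=1e-9
            )

    def test_tuhii_monotone_in_unhealthy_meals(self):
        base = tuhii([1, 2], [0.5, 0.5], [5, 5])
        assert tuhii([1, 2, 1], [0.5, 0.5, 0.2], [5, 5, 3]) > base
        assert tuhii([1, 2, 0], [0.5, 0.5, 0.2], [5, 5, 3]) == pytest.approx(base)


class TestZStandardize:
    def test_two_point_example(self):
        np.testing.assert_allclose(
            z_standardize([1, 3]), [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_mean_zero_sd_one_and_idempotent(self, rng):
        x = rng.normal(3, 7, 100)
        z = z_standardize(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)
        np.testing.assert_allclose(z_standardize(z), z, atol=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            z_standardize([2, 2, 2])


class TestQuartileLabels:
    def test_w_scheme_hand_case(self):
        assert quartile_labels([0.1, 0.4, 0.6, 0.9], "W").tolist() == ["uH", "ruH", "rH", "H"]

    def test_indicator_scheme_hand_case(self):
        assert quartile_labels([1, 2, 3, 4]).tolist() == ["Q1", "Q2", "Q3", "Q4"]

    def test_constant_collapses_to_top_with_warning(self):
        with pytest.warns(UserWarning):
            labels = quartile_labels([1.0] * 8, "W")
        assert set(labels) == {"H"}

    def test_too_few_values_raise(self):
        with pytest.raises(DegenerateInputError):
            quartile_labels([1, 2, 3])


class TestGroupDifference:
    def test_identical_groups_give_null_f(self):
        vals = np.tile(np.arange(10.0), 2)
        res = group_difference_test(vals, ["a"] * 10 + ["b"] * 10)
        assert res["F"] == pytest.approx(0, abs=1e-12)
        assert res["p"] == pytest.approx(1, abs=1e-9)

    def test_separated_groups_detected_with_classic_anova(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        res = group_difference_test(vals, ["a"] * 50 + ["b"] * 50)
        assert res["anova_kind"] == "anova"
        assert res["p"] < 0.001
        # cross-check against the reference routine
        from scipy.stats import f_oneway

        f_ref, p_ref = f_oneway(vals[:50], vals[50:])
        assert res["F"] == pytest.approx(float(f_ref))
        assert res["p"] == pytest.approx(float(p_ref))

    def test_heteroscedastic_groups_use_welch(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 10, 50)])
        res = group_difference_test(vals, ["a"] * 50 + ["b"] * 50)
        assert res["anova_kind"] == "welch"
        assert res["levene_p"] < 0.05

    def test_small_groups_dropped_then_error(self, rng):
        vals = np.array([1.0, 2.0, 3.0, 9.0])
        with pytest.warns(UserWarning):
            res = group_difference_test(
                np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10), [5.0]]),
                ["a"] * 10 + ["b"] * 10 + ["c"],
            )
        assert res["n_groups"] == 2
        with pytest.raises(DegenerateInputError):
            group_difference_test(vals, ["a", "a", "b", "c"])


class TestOutletTable:
    def test_two_outlet_fixture_hand_checked(self, scored_two_outlets, taxonomy):
        out = compute_outlet_indicators(scored_two_outlets, taxonomy).set_index("outlet_id")
        # outlet A: all healthy -> W=1, TUHII=0, HII defined
        assert out.loc["A", "W"] == 1.0
        assert out.loc["A", "TUHII"] == 0.0
        assert out.loc["A", "HII"] == pytest.approx(1.0 * 10 + 0.5 * 5)
        assert np.isnan(out.loc["A", "UHII"])
        # outlet B: W=1/3, UHII sums over ALL meals incl. the healthy one
        assert out.loc["B", "W"] == pytest.approx(1 / 3)
        assert out.loc["B", "TUHII"] == pytest.approx(2 * 1.0 * 3 + 1 * 0.5 * 2)
        assert out.loc["B", "UHII"] == pytest.approx(1.0 * 3 + 0.5 * 4 + 0.5 * 2)
        assert np.isnan(out.loc["B", "HII"])
        assert out.loc["A", "category"] == "1-2"
        assert out.loc["B", "category"] == "1-1"

    def test_hii_uhii_partition(self, rng, taxonomy):
        from opfe.synthetic import default_paperlike_config, generate
        from opfe.scoring import score_meals
        from opfe.taxonomy import classify_meal

        data = generate(default_paperlike_config(seed=11, n_outlets=60))
        meals = data["meals"]
        for col in ("fried", "sugar_beverage", "high_salt"):
            meals[col] = meals[col].astype(bool)
        meals["category"] = [classify_meal([c], taxonomy) for c in meals["composition"]]
        out = compute_outlet_indicators(score_meals(meals), taxonomy)
        has_hii = out["HII"].notna()
        has_uhii = out["UHII"].notna()
        assert (has_hii ^ has_uhii).all()  # exactly one defined per outlet
        assert (has_hii == (out["W"] == 1.0)).all()
        assert (out.loc[out["W"] == 1.0, "TUHII"] == 0).all()
        assert out["z_TUHII"].mean() == pytest.approx(0, abs=1e-9)
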