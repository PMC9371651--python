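"""Deletion orders, effect sizes, the independence matrix and the ANOVA."""

import numpy as np
import pytest

from dgpop.deletion import (
    DeletionCurve,
    compare_orders_anova,
    deletion_curves,
    deletion_order,
    effect_size_matrix,
    pairwise_effect_size,
    _retained,
)

LEVELS = np.arange(100, 0, -10, dtype=float)


def make_curve(name, performance):
    return DeletionCurve(
        order_name=name,
        percent_remaining=LEVELS.copy(),
        performance=np.asarray(performance, float),
        metric_name="mae",
    )


class TestOrders:
    def test_descending_deletes_top_scorer_first(self, rng):
        scores = {"spatial_info": rng.random(30)}
        seq = deletion_order("spatial_info_desc", scores, 30, rng)
        assert seq[0] == np.argmax(scores["spatial_info"])

    def test_ascending_deletes_bottom_scorer_first(self, rng):
        scores = {"spatial_info": rng.random(30)}
        seq = deletion_order("spatial_info_asc", scores, 30, rng)
        assert seq[0] == np.argmin(scores["spatial_info"])

    def test_random_is_a_permutation(self, rng):
        seq = deletion_order("random", {}, 20, rng)
        assert sorted(seq) == list(range(20))

    def test_unknown_order_rejected(self, rng):
        with pytest.raises(ValueError):
            deletion_order("by_soma_size_desc", {"spatial_info": np.ones(5)}, 5, rng)

    def test_retention_is_nested(self, rng):
        seq = deletion_order("random", {}, 37, rng)
        previous = None
        for pct in LEVELS:
            kept = set(_retained(seq, pct))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestDeletionCurves:
    def test_full_population_level_uses_all_neurons(self):
        calls = []

        def ev(a, idx):
            calls.append((a, tuple(idx)))
            return float(len(idx))

        scores = [{"s": np.arange(10, dtype=float)} for _ in range(2)]
        curves = deletion_curves(ev, scores, ["s_desc"], n_random=1, seed=0)
        c = curves["s_desc"]
        assert np.allclose(c.performance[:, 0], 10.0)  # 100% level
        assert np.allclose(c.performance[:, -1], 1.0)  # 10% level

    def test_random_curve_is_average_over_draws(self):
        def ev(a, idx):
            return float(np.sum(idx))  # depends on which neurons survive

        scores = [{"s": np.ones(8)}]
        one = deletion_curves(ev, scores, ["random"], n_random=1, seed=0)
        many = deletion_curves(ev, scores, ["random"], n_random=10, seed=0)
        assert not np.allclose(
            one["random"].performance, many["random"].performance
        )


class TestEffectSize:
    def test_identical_curves_zero_d(self, rng):
        perf = rng.random((4, 10))
        d_vals, mean_abs = pairwise_effect_size(make_curve("a", perf), make_curve("b", perf))
        assert np.allclose(d_vals, 0.0) and mean_abs == 0.0

    def test_hand_computed_unit_d(self):
        base = np.array([-1.5, -0.5, 0.5, 1.5]) / np.std(
            [-1.5, -0.5, 0.5, 1.5], ddof=1
        )
        a = np.tile(base[:, None], (1, 10)) + 1.0  # mean 1, SD 1 per level
        b = np.tile(base[:, None], (1, 10)) + 2.0  # mean 2, SD 1
        d_vals, mean_abs = pairwise_effect_size(make_curve("a", a), make_curve("b", b))
        assert np.allclose(d_vals, -1.0)
        assert np.isclose(mean_abs, 1.0)

    def test_nine_points_exclude_full_population(self, rng):
        a = make_curve("a", rng.random((3, 10)))
        b = make_curve("b", rng.random((3, 10)))
        d_vals, _ = pairwise_effect_size(a, b)
        assert len(d_vals) == 9

    def test_scale_equivariance(self, rng):
        pa, pb = rng.random((5, 10)), rng.random((5, 10))
        d1, m1 = pairwise_effect_size(make_curve("a", pa), make_curve("b", pb))
        d2, m2 = pairwise_effect_size(
            make_curve("a", 7.3 * pa), make_curve("b", 7.3 * pb)
        )
        assert np.allclose(d1, d2) and np.isclose(m1, m2)

    def test_single_animal_rejected(self, rng):
        a = make_curve("a", rng.random((1, 10)))
        with pytest.raises(ValueError):
            pairwise_effect_size(a, a)


class TestMatrix:
    def test_five_orders_symmetric_zero_diagonal(self, rng):
        curves = {f"o{i}": make_curve(f"o{i}", rng.random((4, 10))) for i in range(5)}
        m = effect_size_matrix(curves)
        arr = m.mean_abs_d.to_numpy()
        assert arr.shape == (5, 5)
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)

    def test_duplicated_order_has_zero_entry(self, rng):
        perf = rng.random((4, 10))
        curves = {
            "a": make_curve("a", perf),
            "twin": make_curve("twin", perf.copy()),
            "c": make_curve("c", rng.random((4, 10))),
        }
        m = effect_size_matrix(curves)
        assert m.mean_abs_d.loc["a", "twin"] == 0.0


class TestAnova:
    def test_order_factor_df_shape(self, rng):
        curves = {
            f"o{i}": make_curve(f"o{i}", rng.random((7, 10))) for i in range(5)
        }
        res = compare_orders_anova(curves)
        assert res["order_df"] == (4, 36)
        assert res["level_df"] == (9, 36)

    def test_identical_orders_give_zero_f(self, rng):
        perf = rng.random((7, 10))
        curves = {f"o{i}": make_curve(f"o{i}", perf.copy()) for i in range(5)}
        res = compare_orders_anova(curves)
        assert res["order_F"] == 0.0
        assert res["order_p"] == 1.0

    def test_separated_orders_significant(self, rng):
        curves = {}
        for i in range(5):
            base = np.linspace(10, 20, 10)[None, :] + 2.0 * i
            curves[f"o{i}"] = make_curve(
                f"o{i}", base + 0.3 * rng.standard_normal((7, 10))
            )
        res = compare_orders_anova(curves)
        assert res["order_p"] < 0.001
        assert (res["posthoc"]["p_tukey"] < 0.01).any()

    def test_agrees_with_statsmodels_two_way_anova(self, rng):
        """Cross-check F statistics against an independent OLS/ANOVA route."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        curves = {
            f"o{i}": make_curve(f"o{i}", rng.random((7, 10))) for i in range(4)
        }
        res = compare_orders_anova(curves)
        rows = [
            {"order": name, "level": li, "perf": m}
            for name, c in curves.items()
            for li, m in enumerate(c.mean_curve())
        ]
        fit = ols("perf ~ C(order) + C(level)", pd.DataFrame(rows)).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert np.isclose(res["order_F"], table.loc["C(order)", "F"])
        assert np.isclose(res["level_F"], table.loc["C(level)", "F"])
        assert res["order_df"] == (
            int(table.loc["C(order)", "df"]),
            int(table.loc["Residual", "df"]),
        )

    def test_unbalanced_design_rejected(self, rng):
        curves = {
            "a": make_curve("a", rng.random((7, 10))),
            "b": make_curve("b", rng.random((5, 10))),
        }
        with pytest.raises(ValueError, match="nbalanced"):
            compare_orders_anova(curves)
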