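import math

import numpy as np
import pandas as pd
import pytest

from neri.differential import (
    PowerLawFit,
    WindowSpec,
    compute_delta_prime,
    compute_xdelta,
    fit_powerlaw,
    overlap_stats,
    rank_agreement,
    rank_and_select,
)
from neri.scoring import ConditionScores


def scores(cond, **sig):
    return ConditionScores(condition=cond, sigma=sig,
                           n_paths={g: 1 for g in sig})


def table_from(x, delta, x_ini=5.0):
    df = pd.DataFrame({"x": np.asarray(x, float), "delta": np.asarray(delta, float)},
                      index=[f"G{i:03d}" for i in range(len(x))])
    df["sigma_control"] = df["x"] * (1 - df["delta"]) / 2
    df["sigma_disease"] = df["x"] * (1 + df["delta"]) / 2
    df["n_paths_control"] = 1
    df["n_paths_disease"] = 1
    df["filtered"] = df["x"] <= x_ini
    return df


class TestComputeXDelta:
    def test_basic_arithmetic(self):
        t = compute_xdelta(scores("control", g=1.0), scores("disease", g=3.0))
        assert t.at["g", "x"] == pytest.approx(4.0)
        assert t.at["g", "delta"] == pytest.approx(0.5)

    def test_equal_scores_give_zero_alteration(self):
        t = compute_xdelta(scores("control", g=2.0), scores("disease", g=2.0))
        assert t.at["g", "delta"] == 0.0

    def test_control_only_gene_hits_minus_one(self):
        t = compute_xdelta(scores("control", g=2.0), scores("disease"))
        assert t.at["g", "delta"] == pytest.approx(-1.0)

    def test_zero_intensity_genes_dropped(self):
        t = compute_xdelta(scores("control", g=0.0), scores("disease", g=0.0, h=1.0))
        assert "g" not in t.index and "h" in t.index

    def test_filter_is_strictly_greater_than_x_ini(self):
        t = compute_xdelta(scores("control", g=2.5, h=2.6), scores("disease", g=2.5, h=2.6))
        assert bool(t.at["g", "filtered"]) is True  # x = 5.0 is not > 5
        assert bool(t.at["h", "filtered"]) is False

    def test_swapping_conditions_negates_delta(self):
        sc, sd = scores("control", g=1.0, h=4.0), scores("disease", g=3.0, h=1.0)
        t1 = compute_xdelta(sc, sd)
        t2 = compute_xdelta(ConditionScores("control", sd.sigma, sd.n_paths),
                            ConditionScores("disease", sc.sigma, sc.n_paths))
        assert t2["delta"].tolist() == pytest.approx((-t1["delta"]).tolist())
        assert t2["x"].tolist() == pytest.approx(t1["x"].tolist())


class TestFitPowerlaw:
    def test_noiseless_inverse_law_recovered_exactly(self):
        # one point per non-overlapping unit window, sitting at each midpoint
        x = np.arange(5.5, 30.0, 1.0)
        t = table_from(x, 2.0 / x)
        spec = WindowSpec(w_len=1.0, w_step=1.0, x_ini=5.0, min_points_per_window=1)
        fit = fit_powerlaw(t, spec)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.k == pytest.approx(1.0, abs=1e-9)

    def test_constant_envelope_gives_k_zero(self):
        x = np.arange(5.5, 20.0, 1.0)
        t = table_from(x, np.full_like(x, 0.25))
        spec = WindowSpec(w_len=1.0, w_step=1.0, x_ini=5.0, min_points_per_window=1)
        fit = fit_powerlaw(t, spec)
        assert fit.k == pytest.approx(0.0, abs=1e-12)
        assert fit.a == pytest.approx(0.25, abs=1e-12)

    def test_general_exponent_recovered(self):
        x = np.arange(5.5, 40.0, 1.0)
        t = table_from(x, 0.5 * x ** -0.7)
        spec = WindowSpec(w_len=1.0, w_step=1.0, x_ini=5.0, min_points_per_window=1)
        fit = fit_powerlaw(t, spec)
        assert fit.a == pytest.approx(0.5, abs=1e-6)
        assert fit.k == pytest.approx(0.7, abs=1e-6)

    def test_sign_of_delta_is_ignored(self):
        x = np.arange(5.5, 30.0, 1.0)
        d = 2.0 / x * np.where(np.arange(len(x)) % 2 == 0, 1, -1)
        spec = WindowSpec(w_len=1.0, w_step=1.0, x_ini=5.0, min_points_per_window=1)
        fit = fit_powerlaw(table_from(x, d), spec)
        assert fit.a == pytest.approx(2.0, abs=1e-9)

    def test_sparse_data_falls_back_to_equal_count_windows(self):
        # too few unfiltered points for any fixed-width window to qualify
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(0.1, 4.5, 40), [6.0, 11.0, 30.0]])
        d = 0.5 * x ** -0.5 * (1 + 0.1 * rng.normal(size=len(x)))
        fit = fit_powerlaw(table_from(x, d), WindowSpec())
        assert len(fit.window_points) >= 2
        assert (fit.predict(np.array([1.0, 10.0])) > 0).all()

    def test_degenerate_input_still_errors(self):
        t = table_from([6.0], [0.5])
        t["delta"] = 0.0  # q3 = 0 everywhere -> no usable window anywhere
        with pytest.raises(ValueError, match="window"):
            fit_powerlaw(t, WindowSpec(min_points_per_window=1))


class TestDeltaPrime:
    def test_ratio_arithmetic(self):
        t = table_from([8.0], [0.3])
        f = PowerLawFit(a=0.6 * 8.0, k=1.0)  # f(8) = 0.6
        out = compute_delta_prime(t, f)
        assert out.at["G000", "delta_prime"] == pytest.approx(0.5)

    def test_zero_delta_maps_to_zero(self):
        out = compute_delta_prime(table_from([8.0], [0.0]), PowerLawFit(a=1.0, k=0.5))
        assert out["delta_prime"].iloc[0] == 0.0

    def test_monotone_in_abs_delta_at_equal_intensity(self):
        t = table_from([8.0, 8.0, 8.0], [0.1, -0.2, 0.3])
        out = compute_delta_prime(t, PowerLawFit(a=1.0, k=0.3))
        dp = out["delta_prime"].abs()
        assert dp.iloc[0] < dp.iloc[1] < dp.iloc[2]

    def test_filtered_genes_carry_no_rank(self):
        t = table_from([2.0, 8.0, 9.0], [0.5, 0.3, -0.4])
        out = compute_delta_prime(t, PowerLawFit(a=1.0, k=0.5))
        assert np.isnan(out.at["G000", "delta_prime"])
        assert np.isnan(out.at["G000", "rank_abs_delta_prime"])
        assert sorted(out["rank_abs_delta_prime"].dropna()) == [1.0, 2.0]


class TestRankAndSelect:
    def make(self):
        t = table_from([8, 9, 10, 11, 12, 13, 14, 15, 16, 17],
                       [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        return compute_delta_prime(t, PowerLawFit(a=1.0, k=0.0))

    def test_fraction_count(self):
        assert len(rank_and_select(self.make(), top_fraction=0.2)) == 2

    def test_order_matches_abs_delta_prime(self):
        t = self.make()
        out = rank_and_select(t, top_fraction=1.0)
        dp = t["delta_prime"].abs()
        assert out == sorted(t.index, key=lambda g: (-dp[g], g))

    def test_ties_broken_by_symbol(self):
        t = table_from([8.0, 8.0, 8.0], [0.5, 0.5, 0.5])
        out = rank_and_select(compute_delta_prime(t, PowerLawFit(a=1.0, k=0.0)),
                              top_fraction=1.0)
        assert out == sorted(out)

    def test_rank_by_intensity(self):
        out = rank_and_select(self.make(), by="x", top_fraction=0.3)
        assert out == ["G009", "G008", "G007"]

    def test_empty_and_bad_arguments(self):
        t = self.make()
        with pytest.raises(ValueError):
            rank_and_select(t, by="degree")
        with pytest.raises(ValueError):
            rank_and_select(t, top_fraction=0.0)
        empty = t[t["x"] < 0]
        with pytest.raises(ValueError):
            rank_and_select(empty)


class TestOverlapStats:
    def test_three_ten_percent_lists_expect_tenth_of_percent(self):
        lists = [[f"A{i}" for i in range(100)],
                 [f"B{i}" for i in range(100)],
                 [f"C{i}" for i in range(100)]]
        st = overlap_stats(lists, universe_size=1000)
        assert st.expected_proportion == pytest.approx(0.001)

    def test_study_sized_lists_expect_about_three_random_genes(self):
        u = [f"G{i:04d}" for i in range(2753)]
        lists = [u[:265], u[:285], u[:276]]
        st = overlap_stats(lists, universe_size=2753)
        assert round(st.expected_count) == 3
        assert st.expected_count == pytest.approx(
            2753 * (265 / 2753) * (285 / 2753) * (276 / 2753))

    def test_identical_lists_full_overlap(self):
        l = [f"G{i}" for i in range(50)]
        st = overlap_stats([l, list(l)], universe_size=100)
        assert st.observed_proportion == pytest.approx(1.0)
        assert len(st.intersection) == 50

    def test_universe_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats([["a", "b"], ["a"]], universe_size=1)


class TestRankAgreement:
    def test_identical_rankings(self):
        r = [f"G{i}" for i in range(30)]
        out = rank_agreement(r, list(r), [5, 10, 20])
        assert out["proportion"].tolist() == [1.0, 1.0, 1.0]
        assert out["spearman"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_disjoint_top_lists(self):
        a = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        b = [f"B{i}" for i in range(10)] + [f"A{i}" for i in range(10)]
        out = rank_agreement(a, b, [10])
        assert out["proportion"].iloc[0] == 0.0
        assert math.isnan(out["spearman"].iloc[0])

    def test_two_element_swap_hand_case(self):
        out = rank_agreement(list("abcd"), list("bacd"), [2], min_overlap=2)
        assert out["proportion"].iloc[0] == 1.0
        assert out["spearman"].iloc[0] == pytest.approx(-1.0)

    def test_small_intersections_reported_missing_by_default(self):
        out = rank_agreement(list("abcd"), list("bacd"), [2])
        assert math.isnan(out["spearman"].iloc[0])

    def test_n_beyond_ranking_length_rejected(self):
        with pytest.raises(ValueError):
            rank_agreement(list("abc"), list("abc"), [5])
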