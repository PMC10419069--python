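"""Nonparametric statistics: paired and unpaired rank tests, normalization,
outlier detection, significance labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dabquant import (
    bilateral_average,
    detect_outlier,
    group_compare,
    hemisphere_test,
    mannwhitney,
    normalize_to_control,
    rank_correlation,
    stars,
)
from dabquant.stats import wilcoxon_signed_rank, holm_adjust, validate_measure_table


def mw_enumeration_oracle(x, y):
    """Independent oracle: U by direct pairwise comparison over all labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(s) for s in itertools.combinations(range(len(pooled)), n1)]
    p_le = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_enumeration_oracle(diffs):
    """Independent oracle: exact two-sided p by 2^n sign enumeration."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = sps.rankdata([abs(d) for d in diffs])
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    p_le = sum(w <= w_obs + 1e-12 for w in ws) / len(ws)
    p_ge = sum(w >= w_obs - 1e-12 for w in ws) / len(ws)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonPaired:
    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning):
            w, p, n = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and n == 0

    def test_six_doubling_pairs_exact_p(self):
        """(1,2)...(6,12): all signs negative, W⁺=0, p = 2/64 = 0.03125."""
        left = [1, 2, 3, 4, 5, 6]
        right = [2, 4, 6, 8, 10, 12]
        w, p, n = wilcoxon_signed_rank(left, right)
        assert w == 0.0
        assert p == pytest.approx(2 / 64)
        assert n == 6

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_matches_sign_enumeration(self, n):
        """Exact p equals the 2ⁿ enumeration oracle, tie-free and tied."""
        rng = np.random.default_rng(n)
        for trial in range(8):
            diffs = rng.normal(0.3, 1.0, n)
            if trial >= 4:
                diffs = np.round(diffs, 1)  # induce ties in |d|
                diffs = diffs[diffs != 0]
                if len(diffs) < 3:
                    continue
            w_got, p_got, _ = wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
            w_exp, p_exp = wilcoxon_enumeration_oracle(diffs)
            assert w_got == pytest.approx(w_exp)
            assert p_got == pytest.approx(p_exp, abs=1e-12)

    def test_scale_shift_invariance(self):
        rng = np.random.default_rng(0)
        left, right = rng.normal(5, 1, 8), rng.normal(4, 1, 8)
        _, p1, _ = wilcoxon_signed_rank(left, right)
        _, p2, _ = wilcoxon_signed_rank(3 * left + 7, 3 * right + 7)
        assert p1 == pytest.approx(p2)


class TestHemisphereTest:
    def _table(self, pairs, region="hippocampus", metric="AT8_hscore"):
        rows = []
        for i, (l, r) in enumerate(pairs):
            for hemi, v in (("left", l), ("right", r)):
                if v is None:
                    continue
                rows.append(
                    dict(mouse_id=f"m{i}", genotype="P301S", group="sonicated",
                         delay_days=7, region=region, hemisphere=hemi,
                         metric=metric, value=v)
                )
        return pd.DataFrame(rows)

    def test_doubling_pairs(self):
        table = self._table([(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12)])
        res = hemisphere_test(table, "AT8_hscore", "hippocampus")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.03125)
        assert res.n_pairs == 6 and not res.underpowered

    def test_missing_hemisphere_dropped_and_logged(self):
        table = self._table([(1, 2), (2, 4), (3, 6), (4, None)])
        with pytest.warns(UserWarning, match="missing hemisphere"):
            res = hemisphere_test(table, "AT8_hscore", "hippocampus")
        assert res.n_pairs == 3
        assert res.dropped_mice == ("m3",)

    def test_underpowered_flag(self):
        table = self._table([(1, 2), (5, 3)])
        res = hemisphere_test(table, "AT8_hscore", "hippocampus")
        assert res.underpowered
        assert 0 < res.p <= 1


class TestBilateralAverage:
    def _table(self):
        rows = []
        for hemi, v in (("left", 80.0), ("right", 120.0)):
            rows.append(dict(mouse_id="m1", genotype="P301S", group="sonicated",
                             delay_days=7, region="amygdala", hemisphere=hemi,
                             metric="AT8_hscore", value=v))
        rows.append(dict(mouse_id="m2", genotype="P301S", group="sonicated",
                         delay_days=7, region="amygdala", hemisphere="left",
                         metric="AT8_hscore", value=80.0))
        return pd.DataFrame(rows)

    def test_mean_of_hemispheres(self):
        avg = bilateral_average(self._table())
        m1 = avg[avg.mouse_id == "m1"].iloc[0]
        assert m1.value == pytest.approx(100.0)
        assert m1.n_sides == 2

    def test_single_side_passes_through(self):
        avg = bilateral_average(self._table())
        m2 = avg[avg.mouse_id == "m2"].iloc[0]
        assert m2.value == pytest.approx(80.0)
        assert m2.n_sides == 1

    def test_idempotent(self):
        once = bilateral_average(self._table())
        twice = bilateral_average(once)
        assert twice.value.tolist() == once.value.tolist()
        assert len(twice) == len(once)


class TestMannWhitney:
    def test_complete_separation_two_vs_two(self):
        """{3,4} vs {1,2}: U = 4, exact two-sided p = 2/6."""
        u, p, method = mannwhitney([3, 4], [1, 2])
        assert u == 4.0
        assert p == pytest.approx(1 / 3)
        assert method == "exact"

    def test_identical_groups(self):
        cmp = group_compare([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert cmp.percent_change == 0.0
        assert cmp.p == 1.0

    def test_matches_enumeration_oracle_small_n(self):
        """Exact p equals the independent pairwise-count enumeration for
        n1, n2 ≤ 8 over many random datasets (with and without ties)."""
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.normal(0.5, 1, n1)
            y = rng.normal(0.0, 1, n2)
            if trial % 3 == 0:
                x, y = np.round(x, 0), np.round(y, 0)  # ties
            u_got, p_got, _ = mannwhitney(x, y)
            u_exp, p_exp = mw_enumeration_oracle(x, y)
            assert u_got == pytest.approx(u_exp)
            assert p_got == pytest.approx(p_exp, abs=1e-12)

    def test_matches_scipy_exact_tie_free(self):
        """Cross-check against scipy's exact method on tie-free data."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(1, 1, int(rng.integers(3, 8)))
            y = rng.normal(0, 1, int(rng.integers(3, 8)))
            _, p_got, _ = mannwhitney(x, y)
            p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p_got == pytest.approx(float(p_scipy), abs=1e-12)

    def test_scale_invariance_and_normalization_commute(self):
        """Rank tests are invariant to positive affine maps, so normalizing
        to the control mean leaves p unchanged."""
        rng = np.random.default_rng(3)
        x, y = rng.lognormal(0.4, 0.3, 10), rng.lognormal(0.0, 0.3, 6)
        _, p_raw, _ = mannwhitney(x, y)
        norm = normalize_to_control({"t": x, "c": y}, "c")
        _, p_norm, _ = mannwhitney(norm["t"], norm["c"])
        assert p_raw == pytest.approx(p_norm)

    def test_asymptotic_path_for_large_n(self):
        rng = np.random.default_rng(11)
        u, p, method = mannwhitney(rng.normal(1, 1, 12), rng.normal(0, 1, 12))
        assert method == "asymptotic"
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1, 2])


class TestGroupCompare:
    def test_percent_change_and_normalization(self):
        cmp = group_compare([4.5, 4.5], [2.0, 4.0], group_labels=("son", "ctl"))
        assert cmp.control_mean == pytest.approx(3.0)
        assert cmp.normalized_means["ctl"] == 100.0  # exact
        assert cmp.normalized_means["son"] == pytest.approx(150.0)
        assert cmp.percent_change == pytest.approx(50.0)

    def test_effect_cohort_detected(self):
        """Multiplier 1.48, n = 10 vs 6, low noise: change ≈ +48%, p < 0.05."""
        rng = np.random.default_rng(42)
        control = 60.0 * rng.lognormal(0, 0.05, 6)
        treated = 60.0 * 1.48 * rng.lognormal(0, 0.05, 10)
        cmp = group_compare(treated, control)
        assert cmp.p < 0.05
        assert cmp.percent_change == pytest.approx(48.0, abs=10.0)

    def test_stars_consistent_with_p(self):
        cmp = group_compare([10, 11, 12, 13], [1, 2, 3, 4])
        assert cmp.stars == stars(cmp.p)


class TestNormalization:
    def test_control_mean_exactly_100(self):
        rng = np.random.default_rng(5)
        vals = {"c": rng.uniform(1, 9, 7), "t": rng.uniform(1, 9, 9)}
        norm = normalize_to_control(vals, "c")
        assert norm["c"].mean() == pytest.approx(100.0, abs=1e-10)

    def test_all_equal_values_map_to_100(self):
        norm = normalize_to_control({"c": [4, 4], "t": [4, 4, 4]}, "c")
        assert np.allclose(norm["c"], 100.0) and np.allclose(norm["t"], 100.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control({"c": [0.0, 0.0], "t": [1.0]}, "c")


class TestGrubbs:
    def test_flags_gross_outlier(self):
        """{10,11,12,100}: G = 66.75/44.51 ≈ 1.4997 > crit ≈ 1.4812 → flag."""
        rep = detect_outlier([10, 11, 12, 100], ids=["a", "b", "c", "d"])
        assert rep.flagged == ("d",)
        assert rep.statistic == pytest.approx(1.4997, abs=1e-3)
        assert rep.critical == pytest.approx(1.4812, abs=1e-3)

    def test_no_outlier_in_tight_triple(self):
        rep = detect_outlier([10, 11, 12])
        assert rep.flagged == ()

    def test_constant_values_warn_no_flag(self):
        with pytest.warns(UserWarning):
            rep = detect_outlier([5.0, 5.0, 5.0, 5.0])
        assert rep.flagged == ()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            detect_outlier([1.0, 2.0])

    def test_at_most_one_flag(self):
        rep = detect_outlier([1, 1, 1, 1, 50, 60])
        assert len(rep.flagged) <= 1


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.03, "*"),
            (0.004, "***"),
            (0.009, "**"),
            (0.0004, "****"),
            (0.05, "ns"),
            (0.5, "ns"),
            (1.0, "ns"),
            (0.0049999, "***"),
        ],
    )
    def test_mapping(self, p, label):
        assert stars(p) == label

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            stars(p)


class TestPower:
    def test_detection_ordered_by_effect_size(self):
        """CV 25%, n = 10 vs 6: detection rate at multiplier 1.48 strictly
        exceeds the rate at 1.16 over 200 simulated cohorts."""
        from dabquant.synthetic import CohortSpec, GroupSpec, generate_cohort

        def rate(mult, seed0):
            hits = 0
            for i in range(200):
                spec = CohortSpec(
                    groups=(GroupSpec("t", 10, mult), GroupSpec("c", 6, 1.0)),
                    between_mouse_cv=0.25,
                    regions=("piriform_cortex",),
                    seed=seed0 + i,
                )
                m = generate_cohort(spec).measures.groupby(
                    ["mouse_id", "group"]
                ).true_value.mean().reset_index()
                t = m[m.group == "t"].true_value.to_numpy()
                c = m[m.group == "c"].true_value.to_numpy()
                _, p, _ = mannwhitney(t, c)
                hits += p < 0.05
            return hits / 200

        assert rate(1.48, 10_000) > rate(1.16, 20_000)


class TestUtilities:
    def test_rank_correlation_monotone(self):
        rho, p = rank_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)

    def test_holm_adjustment_monotone(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.all(adj >= [0.01, 0.04, 0.03])
        assert np.all(adj <= 1.0)

    def test_measure_table_validation(self):
        df = pd.DataFrame(
            [dict(mouse_id="m1", genotype="P301S", group="g", delay_days=7,
                  region="amygdala", hemisphere="left", metric="AT8_hscore",
                  value=1.0)]
        )
        validate_measure_table(df)
        bad = pd.concat([df, df])
        with pytest.raises(ValueError, match="duplicate"):
            validate_measure_table(bad)
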