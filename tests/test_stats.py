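"""Statistical layer: rank tests, corrections, effect rules, ANOVA, Fisher."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from zfkin.stats import (
    bootstrap_median_ci,
    classify_significance,
    compare_groups,
    effect_size,
    fisher_exact_2x2,
    iqr_anova,
    mad_outliers,
    sidak_critical,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_identical_samples_give_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(x, x) >= 0.99

    def test_exact_small_sample_matches_enumeration(self):
        # all 20 assignments of ranks to groups enumerate the exact null
        x, y = [1, 2, 3], [10, 11, 12]
        p = wilcoxon_rank_sum(x, y)
        pooled = sorted(x + y)
        obs = sum(sorted(pooled).index(v) + 1 for v in x)
        stats = []
        for combo in itertools.combinations(range(1, 7), 3):
            stats.append(sum(combo))
        lo = sum(1 for s in stats if s <= obs) / len(stats)
        hi = sum(1 for s in stats if s >= obs) / len(stats)
        assert p == pytest.approx(min(1.0, 2 * min(lo, hi)))
        assert p == pytest.approx(0.1)

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            rejections += wilcoxon_rank_sum(x, y) < 0.05
        assert 0.04 <= rejections / n_sim <= 0.06

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSidak:
    def test_single_comparison_is_alpha(self):
        assert sidak_critical(0.05, 1) == pytest.approx(0.05)

    @pytest.mark.parametrize("m,printed", [(8, 0.006), (5, 0.01), (12, 0.004)])
    def test_printed_critical_values(self, m, printed):
        assert round(sidak_critical(0.05, m), len(str(printed)) - 2) == printed

    def test_decreasing_in_m_and_bonferroni_limit(self):
        vals = [sidak_critical(0.05, m) for m in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # ratio to alpha/m grows to -ln(1-a)/a = 1.0259 at alpha = 0.05
        for m in range(5, 30):
            assert sidak_critical(0.05, m) == pytest.approx(0.05 / m, rel=0.026)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            sidak_critical(0.05, 0)


class TestEffectSize:
    @pytest.mark.parametrize("ctrl,cond,ref,printed", [
        (14.7, 19.0, None, 29),    # climb posture, activation
        (10.0, 13.6, None, 36),    # climb posture, 7 dpf lesion
        (14.3, 17.1, None, 20),    # climb posture, 14 dpf lesion
        (0.041, 0.018, 0.068, -34),  # medium slope, fast-control reference
        (0.068, 0.026, 0.068, -62),
    ])
    def test_printed_effect_sizes(self, ctrl, cond, ref, printed):
        assert round(effect_size(ctrl, cond, reference=ref)) == printed

    def test_no_change_is_zero(self):
        assert effect_size(5.0, 5.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            effect_size(0.0, 1.0)


class TestSignificanceRule:
    @pytest.mark.parametrize("p,crit,eff,expected", [
        (0.0005, 0.006, 36.0, True),     # strong effect, small p
        (0.002, 0.006, -4.0, False),     # small p but tiny effect
        (0.005, 0.004, 35.0, False),     # effect large but p above critical
        (0.003, 0.004, 14.999, False),   # unrounded effect just under floor
    ])
    def test_dual_criterion(self, p, crit, eff, expected):
        assert classify_significance(p, crit, eff) is expected


class TestBootstrapMedianCI:
    def test_constant_data_degenerate_interval(self):
        m, lo, hi = bootstrap_median_ci([4.2] * 20, seed=0)
        assert m == lo == hi == 4.2

    def test_seed_reproducibility(self):
        x = np.random.default_rng(3).normal(size=200)
        assert bootstrap_median_ci(x, seed=5) == bootstrap_median_ci(x, seed=5)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(1)
        covered = 0
        n_sim = 300
        for i in range(n_sim):
            x = rng.normal(size=400)
            _, lo, hi = bootstrap_median_ci(x, n_boot=500, seed=i)
            covered += lo <= 0.0 <= hi
        # percentile bootstrap is approximate; binomial band around 95%
        assert 0.91 <= covered / n_sim <= 0.99


class TestMadOutliers:
    def test_single_gross_outlier_flagged(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask = mad_outliers(x)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = np.abs(x - med) > 3 * 1.4826 * mad
        assert np.array_equal(mask, expected)
        assert mask.sum() == 1 and mask[-1]

    def test_constant_data_has_no_outliers(self):
        assert not mad_outliers([2.0] * 10).any()

    def test_zero_mad_flags_any_deviation(self):
        mask = mad_outliers([1.0, 1.0, 1.0, 1.0, 1.5])
        assert mask.tolist() == [False] * 4 + [True]


def _brute_force_two_way(df):
    """Type I sums of squares for a balanced two-factor layout, from scratch."""
    y = df.value.to_numpy()
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    a_means = df.groupby("group").value.mean()
    b_means = df.groupby("measure").value.mean()
    cell = df.groupby(["group", "measure"]).value.mean()
    n_a = df.groupby("group").size()
    n_b = df.groupby("measure").size()
    n_cell = df.groupby(["group", "measure"]).size()
    ss_a = sum(n_a[a] * (a_means[a] - gm) ** 2 for a in a_means.index)
    ss_b = sum(n_b[b] * (b_means[b] - gm) ** 2 for b in b_means.index)
    ss_cells = sum(n_cell[c] * (cell[c] - gm) ** 2 for c in cell.index)
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    return ss_a, ss_b, ss_ab, ss_err, ss_total


class TestIqrAnova:
    @staticmethod
    def _layout(values):
        rows = []
        it = iter(values)
        for g in ("g1", "g2"):
            for m in ("m1", "m2"):
                for _ in range(3):
                    rows.append({"group": g, "measure": m, "value": next(it)})
        return pd.DataFrame(rows)

    def test_no_between_cell_variation_gives_zero_f(self):
        # replicate noise identical in every cell: factor effects vanish
        vals = [1.0, 2.0, 3.0] * 4
        tab = iqr_anova(self._layout(vals))
        for src in ("group", "measure", "group:measure"):
            assert tab.row(src).F == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(42)
        df = self._layout(rng.normal(size=12).tolist())
        tab = iqr_anova(df)
        ss = _brute_force_two_way(df)
        for src, expected in zip(("group", "measure", "group:measure",
                                  "error", "total"), ss):
            assert tab.row(src).sum_sq == pytest.approx(expected, rel=1e-9)

    def test_df_and_ss_conservation(self):
        rng = np.random.default_rng(9)
        df = self._layout(rng.normal(size=12).tolist())
        tab = iqr_anova(df)  # AnovaTable asserts conservation on construction
        comp = tab.rows[tab.rows.source != "total"]
        assert comp.df.sum() == tab.row("total").df

    def test_empty_cell_rejected(self):
        df = self._layout(list(range(12)))
        with pytest.raises(ValueError):
            iqr_anova(df[~((df.group == "g1") & (df.measure == "m2"))])


class TestFisherExact:
    @pytest.mark.parametrize("table,printed", [
        (((0, 44), (8, 32)), 0.0018),   # activated-cell contingency
        (((0, 22), (0, 22)), 1.0),      # washout comparison
        (((1, 1), (1, 1)), 1.0),
    ])
    def test_printed_values(self, table, printed):
        (a, b), (c, d) = table
        assert round(fisher_exact_2x2(a, b, c, d), 4) == printed

    def test_matches_hypergeometric_enumeration(self):
        # probability-mass two-sided rule, enumerated from scratch
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 16, size=4)
            n = a + b + c + d
            if n == 0 or n > 60:
                continue
            r1, c1 = a + b, a + c
            obs = sps.hypergeom.pmf(a, n, r1, c1)
            p_enum = sum(
                sps.hypergeom.pmf(k, n, r1, c1)
                for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                if sps.hypergeom.pmf(k, n, r1, c1) <= obs * (1 + 1e-9))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_enum, rel=1e-9)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestCompareGroups:
    def test_full_comparison_detects_programmed_shift(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal(10.0, 2.0, 800)
        cond = rng.normal(13.0, 2.0, 800)
        res = compare_groups(ctrl, cond, "demo", critical_p=0.006, seed=0)
        assert res.significant
        assert res.effect_size_pct == pytest.approx(30.0, abs=6.0)
        assert res.control_ci[0] <= res.control_median <= res.control_ci[1]
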