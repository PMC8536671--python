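import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from coamap.regions import PIAL_REGIONS
from coamap.stats import (
    PARAMETERS,
    StatResult,
    anova_oneway,
    build_grid,
    fdr_adjust,
    hd_ld_tests,
    levene,
    posthoc,
    regional_parameter_table,
    spearman,
    t_test_unpaired,
)


def bh_stepup_oracle(p):
    """Independent brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank in ascending order
        val = min(prev, m * p[idx] / i, 1.0)
        adj[idx] = val
        prev = val
    return adj


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_no_tie_rank_formula_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        expected = 1 - 6 * d2 / (5 * (25 - 1))
        assert spearman(x, y).statistic == pytest.approx(expected)

    def test_too_few_pairs_is_missing(self):
        res = spearman([1, 2, np.nan], [1, np.nan, 3])
        assert math.isnan(res.statistic) and res.n < 3

    def test_pairwise_deletion(self):
        res = spearman([1, 2, 3, 4, np.nan], [1, np.nan, 3, 4, 5])
        assert res.n == 3


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_missing_passthrough_shrinks_family(self):
        adj = fdr_adjust([0.01, np.nan, 0.04])
        assert math.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_stepup_oracle([0.01, 0.04]))

    @given(seed=st.integers(0, 10_000), m=st.integers(1, 40))
    def test_matches_bruteforce_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(1e-6, 1.0, m)
        np.testing.assert_allclose(fdr_adjust(p), bh_stepup_oracle(p), rtol=0, atol=1e-12)


class TestTTest:
    def test_identical_samples(self):
        res = t_test_unpaired([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_pooled_formula_oracle(self):
        res = t_test_unpaired([1, 2, 3], [4, 5, 6])
        # pooled s^2 = 1, se = sqrt(2/3), t = -3/se
        assert res.statistic == pytest.approx(-3 / math.sqrt(2 / 3), abs=1e-3)
        assert res.df == 4

    def test_zero_variance_guards(self):
        same = t_test_unpaired([2, 2, 2], [2, 2, 2])
        assert same.p_raw == 1.0
        diff = t_test_unpaired([2, 2, 2], [3, 3, 3])
        assert diff.p_raw == 0.0


class TestLeveneAnova:
    def test_identical_groups_degenerate(self):
        res = levene([[1, 1, 1], [1, 1, 1]])
        assert res.p_raw == 1.0
        an = anova_oneway([[2, 2, 2], [2, 2, 2]])
        assert an.statistic == 0.0 and an.p_raw == 1.0

    def test_levene_detects_scaled_variance(self, rng):
        a = rng.normal(0, 1, 20)
        b = a * 10
        res = levene([a, b])
        assert res.p_raw < 0.01

    def test_anova_sums_of_squares_oracle(self):
        res = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        # SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6, df 2; SSW = 6, df 6 -> F = 3
        assert res.statistic == pytest.approx(3.0)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.4, 1, 11)
        t = t_test_unpaired(a, b)
        f = anova_oneway([a, b])
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert f.p_raw == pytest.approx(t.p_raw, abs=1e-10)


class TestPosthoc:
    def _unequal(self):
        return StatResult("", "levene", 10.0, 1e-4)

    def _equal(self):
        return StatResult("", "levene", 0.5, 0.6)

    def test_games_howell_equals_welch_at_k2(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 4, 14)
        res = posthoc([a, b], levene_result=self._unequal())[0]
        assert res.method == "games_howell"
        welch = sps.ttest_ind(a, b, equal_var=False)
        assert res.p_raw == pytest.approx(welch.pvalue, abs=1e-6)

    def test_games_howell_matches_independent_implementation(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(0.8, 2.5, 12), rng.normal(-0.2, 0.5, 9)]
        mine = posthoc(groups, levene_result=self._unequal(), labels=["a", "b", "c"])
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "grp": ["a"] * 10 + ["b"] * 12 + ["c"] * 9,
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="grp")
        ref_p = dict(zip(zip(ref["A"], ref["B"]), ref["pval"]))
        for res in mine:
            a, b = res.comparison_id.split(" vs ")
            assert res.p_raw == pytest.approx(ref_p[(a, b)], abs=1e-6)

    def test_lsd_pooled_mse_oracle(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0.5, 1, 6), rng.normal(1.0, 1, 6)]
        res = posthoc(groups, levene_result=self._equal(), labels=["a", "b", "c"])
        k, n = 3, 18
        mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / (n - k)
        t01 = (groups[0].mean() - groups[1].mean()) / math.sqrt(mse * (2 / 6))
        p01 = 2 * sps.t.sf(abs(t01), n - k)
        assert res[0].method == "lsd"
        assert res[0].p_raw == pytest.approx(p01, abs=1e-12)

    def test_identical_groups_all_p_one(self):
        res = posthoc([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert all(r.p_raw == 1.0 for r in res)


class TestGrid:
    def _summaries(self, rng, n_sections=8):
        rows = []
        for s in range(n_sections):
            for region in PIAL_REGIONS:
                count = float(rng.poisson(5 + 3 * s)) if region.value != "CPS" else 0.0
                rows.append(
                    {
                        "section_id": f"S{s}",
                        "region": region.value,
                        "count": count,
                        "area_fraction_pct": count / 100,
                        "mean_diameter_um": rng.normal(9, 0.5) if count else np.nan,
                        "min_diameter_um": rng.normal(5, 0.5) if count else np.nan,
                        "max_diameter_um": rng.normal(15, 0.5) if count else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_missing_cell_reduces_family(self, rng):
        summ = self._summaries(rng)
        table = regional_parameter_table(summ)
        cov = pd.Series(np.arange(8.0), index=[f"S{s}" for s in range(8)])
        grid = build_grid(table, cov, "ranked_sequence")
        cps_diam = grid.cell("CPS", "mean_diameter_um")
        assert math.isnan(cps_diam["r"]) and math.isnan(cps_diam["p_adj"])
        family = grid.table["p_raw"].notna().sum()
        assert family < len(PIAL_REGIONS) * len(PARAMETERS)
        # adjusted never below raw
        ok = grid.table.dropna(subset=["p_raw"])
        assert (ok["p_adj"] >= ok["p_raw"] - 1e-12).all()

    def test_gradient_covariate_flags_density_cells(self, rng):
        summ = self._summaries(rng)
        table = regional_parameter_table(summ)
        cov = pd.Series(np.arange(8.0), index=[f"S{s}" for s in range(8)])
        grid = build_grid(table, cov, "ranked_sequence")
        fps_count = grid.cell("FPS", "count")
        assert fps_count["r"] > 0.7

    def test_hd_ld_table_shape(self, rng):
        rows = []
        for s in range(6):
            for zone, dens in (("HD", 400.0), ("LD", 40.0)):
                rows.append(
                    {
                        "section_id": f"S{s}",
                        "region": "FPS",
                        "zone": zone,
                        "packing_density_per_mm2": dens + rng.normal(0, 10),
                        "area_fraction_pct": dens / 100,
                        "mean_diameter_um": 9.0,
                        "max_diameter_um": 15.0,
                    }
                )
        out = hd_ld_tests(pd.DataFrame(rows))
        cell = out[(out.region == "FPS") & (out.parameter == "packing_density_per_mm2")].iloc[0]
        assert cell["significant"]
        assert cell["fold_change"] == pytest.approx(10.0, rel=0.2)
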