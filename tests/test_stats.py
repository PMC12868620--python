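"""Welch ANOVA, Dunnett T3 / SMM, weighted ANOVA and correlation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.optimize import brentq

from electroperm.stats import (
    GroupSample,
    dunnett_t3,
    pearson,
    significance_stars,
    smm_cdf,
    weighted_one_way_anova,
    welch_anova,
)


def _groups_from(arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return [GroupSample(lbl, np.asarray(a, dtype=float)) for lbl, a in zip(labels, arrays)]


class TestWelchAnova:
    def test_hand_computed_two_group_case(self):
        """{1,2,3} vs {2,3,4}: Welch t = -1.2247 so W = 1.5 with df_den = 4."""
        res = welch_anova(_groups_from([[1, 2, 3], [2, 3, 4]]))
        assert res.statistic == pytest.approx(1.5, rel=1e-9)
        assert res.df_num == 1
        assert res.df_den == pytest.approx(4.0, rel=1e-9)

    def test_identical_groups_give_zero(self):
        res = welch_anova(_groups_from([[1, 2, 3], [1, 2, 3]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        arrays = [rng.normal(size=8), rng.normal(1, 2, size=12), rng.normal(-1, 0.5, size=6)]
        r1 = welch_anova(_groups_from(arrays))
        r2 = welch_anova(_groups_from([a + 17.3 for a in arrays]))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_zero_variance_cases(self):
        equal = welch_anova(_groups_from([[5, 5, 5], [5, 5, 5]]))
        assert equal.statistic == 0.0 and equal.p_value == 1.0
        unequal = welch_anova(_groups_from([[5, 5, 5], [7, 7, 7]]))
        assert unequal.degenerate and unequal.p_value == 0.0

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_k2_equals_squared_welch_t(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 15))
        b = rng.normal(0.5, 2, rng.integers(3, 15))
        res = welch_anova(_groups_from([a, b]))
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_implementation(self, seed):
        """Cross-check the W statistic, df and p against pingouin."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c", "d"], [8, 10, 12, 9]),
                "v": rng.normal(size=39) * np.repeat([1, 2, 0.5, 1.5], [8, 10, 12, 9]),
            }
        )
        mine = welch_anova([GroupSample(k, grp["v"].to_numpy()) for k, grp in df.groupby("g")])
        ref = pg.welch_anova(dv="v", between="g", data=df).iloc[0]
        assert mine.statistic == pytest.approx(ref["F"], rel=1e-9)
        assert mine.df_den == pytest.approx(ref["ddof2"], rel=1e-9)
        assert mine.p_value == pytest.approx(ref["p_unc"], rel=1e-9)


class TestSmm:
    def test_cdf_monotone_and_bounded(self):
        qs = np.linspace(0.5, 5, 10)
        cdfs = [smm_cdf(q, 3, 20) for q in qs]
        assert np.all(np.diff(cdfs) > 0)
        assert all(0 <= c <= 1 for c in cdfs)

    def test_m1_reduces_to_student_t(self):
        for q in (1.0, 2.0, 3.0):
            two_sided = 2 * sps.t.sf(q, 15)
            assert 1 - smm_cdf(q, 1, 15) == pytest.approx(two_sided, abs=1e-9)

    def test_quantile_matches_monte_carlo(self):
        """SMM 95% quantile (m=3, df=30) vs simulation, 2-decimal agreement."""
        m, df, n_sim = 3, 30, 400_000
        rng = np.random.default_rng(7)
        z = np.abs(rng.standard_normal((n_sim, m))).max(axis=1)
        s = rng.chisquare(df, n_sim) ** 0.5 / math.sqrt(df)
        mc_q = float(np.quantile(z / s, 0.95))
        num_q = brentq(lambda q: smm_cdf(q, m, df) - 0.95, 1.0, 10.0)
        assert num_q == pytest.approx(mc_q, abs=0.01)


class TestDunnettT3:
    def test_single_comparison_equals_welch_t_test(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        ph = dunnett_t3(_groups_from([a, b]))
        t = sps.ttest_ind(a, b, equal_var=False)
        assert len(ph) == 1
        assert ph[0].p_adjusted == pytest.approx(t.pvalue, rel=1e-9)

    def test_adjustment_is_conservative(self):
        rng = np.random.default_rng(5)
        groups = _groups_from([rng.normal(i * 0.5, 1 + i, 10) for i in range(4)])
        for comp in dunnett_t3(groups):
            assert comp.p_adjusted >= comp.p_unadjusted - 1e-12
        assert len(dunnett_t3(groups)) == 6  # all pairs
        vs_ref = dunnett_t3(groups, reference="g0")
        assert len(vs_ref) == 3

    def test_adjusted_p_monotone_in_m(self):
        """The same pair gets a larger adjusted p inside a bigger family."""
        rng = np.random.default_rng(6)
        base = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        p_small = dunnett_t3(_groups_from(base))[0].p_adjusted
        groups4 = _groups_from(base + [rng.normal(0, 3, 8), rng.normal(2, 2, 8)])
        p_big = [c for c in dunnett_t3(groups4) if c.pair == ("g0", "g1")][0].p_adjusted
        assert p_big >= p_small


class TestWeightedAnova:
    def test_equal_weights_match_ordinary_anova(self):
        rng = np.random.default_rng(8)
        arrays = [rng.normal(i, 1, 10) for i in range(3)]
        groups = _groups_from(arrays)
        res = weighted_one_way_anova(groups, [np.ones(10)] * 3)
        f, p = sps.f_oneway(*arrays)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_duplication_equals_weight_doubling(self):
        a = np.array([1.0, 2.0, 3.5, 4.0])
        b = np.array([2.0, 4.0, 5.0])
        dup = weighted_one_way_anova(
            _groups_from([np.concatenate([a, a[:1]]), b]),
            [np.ones(5), np.ones(3)],
        )
        wtd = weighted_one_way_anova(
            _groups_from([a, b]),
            [np.array([2.0, 1.0, 1.0, 1.0]), np.ones(3)],
        )
        # both encodings share the same between/within sums of squares, so
        # F / df_den (= SSB/SSW) is identical; F itself differs only through
        # the row-count denominator df
        assert dup.statistic / dup.df_den == pytest.approx(
            wtd.statistic / wtd.df_den, rel=1e-9
        )

    def test_two_groups_equal_squared_weighted_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        wa, wb = rng.uniform(0.5, 2, 8), rng.uniform(0.5, 2, 6)
        res = weighted_one_way_anova(_groups_from([a, b]), [wa, wb])
        # pooled-weighted t statistic computed independently
        ma, mb = np.average(a, weights=wa), np.average(b, weights=wb)
        ssw = np.sum(wa * (a - ma) ** 2) + np.sum(wb * (b - mb) ** 2)
        mse = ssw / (len(a) + len(b) - 2)
        t = (ma - mb) / math.sqrt(mse * (1 / wa.sum() + 1 / wb.sum()))
        assert res.statistic == pytest.approx(t**2, rel=1e-9)

    def test_nonpositive_weight_errors(self):
        with pytest.raises(ValueError, match="> 0"):
            weighted_one_way_anova(
                _groups_from([[1, 2, 3], [2, 3, 4]]),
                [np.array([1.0, -1.0, 1.0]), np.ones(3)],
            )

    def test_posthoc_tukey_bounds(self):
        rng = np.random.default_rng(10)
        groups = _groups_from([rng.normal(i, 1, 9) for i in range(3)])
        res = weighted_one_way_anova(groups, [np.ones(9)] * 3)
        for comp in res.posthoc:
            assert 0 <= comp.p_adjusted <= 1
            assert comp.p_adjusted >= comp.p_unadjusted - 1e-12


class TestPearson:
    def test_perfect_correlation(self):
        res = pearson(np.arange(10.0), np.arange(10.0))
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-9
        assert res.slope == pytest.approx(1.0)

    def test_reported_correlation_p_value(self):
        """Sample r = 0.36 at n = 45 gives r^2 = 0.13 and p ~ 0.015."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=45)
        e = rng.normal(size=45)
        zx = (x - x.mean()) / x.std()
        resid = e - np.polyval(np.polyfit(zx, e, 1), zx)
        zy = resid / resid.std()
        r_target = 0.36
        y = r_target * zx + math.sqrt(1 - r_target**2) * zy
        res = pearson(x, y)
        assert res.r == pytest.approx(0.36, abs=1e-9)
        assert round(res.r_squared, 2) == 0.13
        assert res.p_value == pytest.approx(0.0148, abs=5e-4)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = pearson(x, y), pearson(x, -y)
        assert a.r == pytest.approx(-b.r)
        assert a.p_value == pytest.approx(b.p_value)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


def test_significance_stars():
    assert significance_stars(0.3) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
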