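"""Effect measures and hypothesis tests for the validation assays."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from tipselect.valstats import (
    CompetitionCounts,
    assay_table_comparison,
    competition_chisq,
    group_comparison,
    percent_change,
    pooled_competition_chisq,
    wound_closure,
)


def t_sf_numeric(t, df):
    """Upper-tail Student-t probability by direct numerical integration."""
    c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))
    val, _ = integrate.quad(lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2), t, np.inf)
    return val


def f_sf_numeric(f, d1, d2):
    """Upper-tail F probability by direct numerical integration."""
    c = (d1 / d2) ** (d1 / 2) / special.beta(d1 / 2, d2 / 2)
    val, _ = integrate.quad(
        lambda x: c * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2), f, np.inf
    )
    return val


class TestEffectMeasures:
    def test_percent_change(self):
        assert percent_change(100, 65) == pytest.approx(35.0)
        assert percent_change(10, 10) == 0.0
        assert percent_change(1.0, 0.674) == pytest.approx(32.6)
        assert percent_change(100, 120) == pytest.approx(-20.0)  # increase
        with pytest.raises(ValueError):
            percent_change(0, 5)

    def test_wound_closure(self):
        assert wound_closure(0.8, 0.8) == 0.0
        assert wound_closure(0.8, 0.0) == 100.0
        assert wound_closure(0.8, 0.2) == pytest.approx(75.0)
        assert wound_closure(0.8, 1.0) == pytest.approx(-25.0)  # gap widened
        with pytest.raises(ValueError):
            wound_closure(0.0, 0.1)


class TestCompetitionChisq:
    def test_perfect_fit(self):
        r = competition_chisq(CompetitionCounts(50, 100))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_closed_form_values(self):
        # chi2(1) upper tail at 4 equals 2*Phi(-2)
        r = competition_chisq(CompetitionCounts(40, 100))
        assert r.statistic == pytest.approx(4.0)
        assert r.p_value == pytest.approx(2 * stats.norm.cdf(-2), abs=1e-6)
        assert r.p_value == pytest.approx(0.04550, abs=5e-6)
        r2 = competition_chisq(CompetitionCounts(0, 10))
        assert r2.statistic == pytest.approx(10.0)
        assert r2.p_value == pytest.approx(2 * stats.norm.cdf(-math.sqrt(10)), abs=1e-9)
        assert r2.p_value == pytest.approx(0.001565, abs=5e-7)

    def test_symmetry_at_even_split(self):
        a = competition_chisq(CompetitionCounts(30, 100))
        b = competition_chisq(CompetitionCounts(70, 100))
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value

    def test_small_sample_flagged_not_rejected(self):
        r = competition_chisq(CompetitionCounts(2, 6))
        assert any("expected count" in f for f in r.flags)

    def test_pooled_replicates(self):
        reps = [CompetitionCounts(10, 30), CompetitionCounts(12, 30)]
        pooled = pooled_competition_chisq(reps)
        direct = competition_chisq(CompetitionCounts(22, 60))
        assert pooled.statistic == direct.statistic

    def test_null_type_one_error_calibrated(self):
        """Under k ~ Binomial(100, 0.5), rejection at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(123)
        ks = rng.binomial(100, 0.5, size=10_000)
        rej = np.mean(
            [competition_chisq(CompetitionCounts(int(k), 100)).p_value < 0.05 for k in ks]
        )
        assert 0.035 <= rej <= 0.065

    def test_domain_guards(self):
        with pytest.raises(ValueError):
            CompetitionCounts(5, 4)
        with pytest.raises(ValueError):
            CompetitionCounts(1, 10, p0=1.0)


class TestGroupComparison:
    def test_identical_groups_t(self):
        g = {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])}
        (r,) = group_comparison(g, design="two_group_t")
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_anova(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3 on (2, 6) df
        g = {
            "a": np.array([1.0, 2, 3]),
            "b": np.array([2.0, 3, 4]),
            "c": np.array([3.0, 4, 5]),
        }
        results = group_comparison(g, design="oneway_anova_tukey")
        f = results[0]
        assert f.statistic == pytest.approx(3.0)
        assert f.df == (2.0, 6.0)
        assert f.p_value == pytest.approx(f_sf_numeric(3.0, 2, 6), abs=1e-6)

    def test_tukey_identical_groups_all_p_one(self):
        g = {k: np.array([5.0, 5, 5, 5]) + 0 for k in "abc"}
        results = group_comparison(g, design="oneway_anova_tukey")
        for r in results[1:]:
            assert np.isnan(r.p_value) or r.p_value == pytest.approx(1.0)

    def test_t_squared_equals_f_for_two_groups(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(loc=0.5, size=7)
            (t_res,) = group_comparison({"a": a, "b": b}, design="two_group_t")
            f_stat = stats.f_oneway(a, b).statistic
            assert t_res.statistic**2 == pytest.approx(f_stat, rel=1e-10)

    def test_p_values_match_numerical_cdf_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n1, n2 = rng.integers(3, 10, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.uniform(0, 1), size=n2)
            (t_res,) = group_comparison({"a": a, "b": b}, design="two_group_t")
            assert t_res.p_value == pytest.approx(
                2 * t_sf_numeric(abs(t_res.statistic), n1 + n2 - 2), abs=1e-6
            )
            c = rng.normal(size=int(rng.integers(3, 8)))
            res = group_comparison({"a": a, "b": b, "c": c}, design="oneway_anova_tukey")
            f = res[0]
            assert f.p_value == pytest.approx(
                f_sf_numeric(f.statistic, *f.df), abs=1e-6
            )

    def test_degenerate_zero_variance_unequal_means(self):
        g = {"a": np.array([1.0, 1, 1]), "b": np.array([2.0, 2, 2])}
        (r,) = group_comparison(g, design="two_group_t")
        assert r.p_value <= np.finfo(float).tiny
        assert r.flags

    def test_design_guards(self):
        g2 = {"a": np.array([1.0, 2]), "b": np.array([1.0, 2])}
        with pytest.raises(ValueError, match="needs exactly 2"):
            group_comparison({**g2, "c": np.array([1.0, 2])}, design="two_group_t")
        with pytest.raises(ValueError, match=">= 3"):
            group_comparison(g2, design="oneway_anova_tukey")
        with pytest.raises(ValueError, match="< 2"):
            group_comparison({"a": np.array([1.0]), "b": np.array([1.0, 2])})

    def test_auto_design_from_tidy_table(self):
        table = pd.DataFrame(
            {
                "group": ["control"] * 3 + ["si2"] * 3 + ["si3"] * 3,
                "value": [10.0, 11, 9, 7, 6.5, 7.2, 6.8, 7.1, 6.4],
            }
        )
        results = assay_table_comparison(table)
        assert results[0].name == "anova_f"
        assert len(results) == 1 + 3  # F plus three pairwise Tukey contrasts
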