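import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ltrdyn.dynstats import (anova_tukey, compact_letter_display,
                             lineage_summary, regress, slope_table,
                             superfamily_summary)

COPIA_COUNTS = {"Ale": 319, "Angela": 152, "Bianca": 4, "Ikeros": 34,
                "Ivana": 22, "Sire": 14, "TAR": 41, "Tork": 37}
GYPSY_COUNTS = {"CRM": 108, "Galadriel": 15, "Reina": 8, "Tekay": 704,
                "Athila": 125, "Ogre-Tat": 203}


def _pairs():
    pairs = []
    for lin, n in COPIA_COUNTS.items():
        pairs += [("Copia", lin)] * n
    for lin, n in GYPSY_COUNTS.items():
        pairs += [("Gypsy", lin)] * n
    pairs += [("unknown", "unknown")] * 74
    return pairs


class TestLineageSummary:
    def test_predominant_copia_lineage_percentage(self):
        df = lineage_summary(_pairs()).set_index(["superfamily", "lineage"])
        assert df.loc[("Copia", "Ale"), "count"] == 319
        assert df.loc[("Copia", "Ale"), "pct_of_superfamily"] == 51.20

    def test_predominant_gypsy_lineage_percentage(self):
        df = lineage_summary(_pairs()).set_index(["superfamily", "lineage"])
        assert df.loc[("Gypsy", "Tekay"), "pct_of_superfamily"] == 60.53

    def test_single_element_is_100_percent(self):
        df = lineage_summary([("Copia", "Ale")])
        assert df["pct_of_superfamily"].tolist() == [100.0]
        assert df["pct_of_total"].tolist() == [100.0]

    def test_within_superfamily_percentages_sum_to_100(self):
        df = lineage_summary(_pairs())
        for _sf, sub in df.groupby("superfamily"):
            assert sub["pct_of_superfamily"].sum() == pytest.approx(100, abs=0.05)

    def test_superfamily_totals(self):
        df = superfamily_summary(_pairs()).set_index("superfamily")
        assert df.loc["Copia", "count"] == 623
        assert df.loc["Gypsy", "count"] == 1163
        assert df.loc["Copia", "pct_of_total"] == 33.49


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0],
                           "c": [1.0, 1.0, 1.0]})
        assert res.p_value == 1.0
        assert set(res.letters.values()) == {"a"}

    def test_f_statistic_hand_fixture(self):
        # SSB = 54, SSW = 6, df = (2, 6): F = (54/2)/(6/6) = 27
        res = anova_tukey({"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]})
        assert res.f_statistic == pytest.approx(27.0, abs=1e-9)

    def test_f_matches_definitional_sums_of_squares(self, rng):
        for _ in range(10):
            groups = {f"g{i}": rng.normal(rng.uniform(-2, 2), 1,
                                          int(rng.integers(3, 9))).tolist()
                      for i in range(int(rng.integers(2, 6)))}
            res = anova_tukey(groups)
            allv = np.concatenate([np.asarray(v) for v in groups.values()])
            grand = allv.mean()
            ssb = sum(len(v) * (np.mean(v) - grand) ** 2
                      for v in groups.values())
            ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                      for v in groups.values())
            dfb, dfw = len(groups) - 1, len(allv) - len(groups)
            assert res.f_statistic == pytest.approx(
                (ssb / dfb) / (ssw / dfw), abs=1e-9)

    def test_intermediate_group_shares_both_letters(self, rng):
        low = rng.normal(0, 1, 20).tolist()
        mid = rng.normal(2.2, 1, 20).tolist()
        high = rng.normal(4.4, 1, 20).tolist()
        res = anova_tukey({"low": low, "mid": mid, "high": high})
        # letters must be consistent with the pairwise matrix whatever the
        # sampled significance pattern is
        _assert_letters_consistent(res)

    def test_letters_consistent_on_random_fixtures(self, rng):
        for _ in range(10):
            groups = {f"g{i}": rng.normal(rng.uniform(0, 4), 1,
                                          int(rng.integers(4, 10))).tolist()
                      for i in range(int(rng.integers(3, 6)))}
            _assert_letters_consistent(anova_tukey(groups))

    def test_too_few_groups_is_error(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 2]})


def _assert_letters_consistent(res, alpha=0.05):
    """Groups share a letter iff their Tukey p >= alpha (transitively via
    the letter sets: sharing requires non-significance; non-sharing
    requires significance)."""
    for (a, b), p in res.tukey_pvalues.items():
        share = set(res.letters[a]) & set(res.letters[b])
        if p < alpha:
            assert not share, (a, b, p, res.letters)
        else:
            assert share, (a, b, p, res.letters)


class TestRegress:
    def test_perfect_line(self):
        x = [0, 1, 2, 3, 4]
        y = [2 * v + 1 for v in x]
        r = regress(x, y)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r == pytest.approx(1.0)

    def test_slope_equals_covariance_over_variance(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        r = regress(x, y)
        cov = np.cov(x, y, ddof=1)[0, 1]
        assert r.slope == pytest.approx(cov / np.var(x, ddof=1))

    def test_null_pvalues_are_uniform(self, rng):
        # permutation oracle: with y independent of x the p-values are
        # Uniform(0,1); KS at a generous threshold on 200 replicates
        x = rng.normal(0, 1, 30)
        pvals = [regress(x, rng.permutation(rng.normal(0, 1, 30))).p_value
                 for _ in range(200)]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_constant_x_is_error(self):
        with pytest.raises(ValueError):
            regress([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_n2_has_no_pvalue(self):
        r = regress([0.0, 1.0], [5.0, 9.0])
        assert r.p_value is None and r.slope == pytest.approx(4.0)


class TestSlopeTable:
    def _frame(self, rpkm_fn, n=30, rng=None):
        rng = rng or np.random.default_rng(0)
        ages = rng.uniform(1e6, 1e7, n)
        cov = rng.uniform(1, 50, n)
        df = pd.DataFrame({
            "element": [f"e{i}" for i in range(n)],
            "superfamily": ["Copia"] * n,
            "age_years": ages,
            "coverage": cov,
        })
        for t in ("C24", "S24", "C48", "S48"):
            df[f"rpkm_{t}"] = rpkm_fn(ages, cov, rng)
        return df

    def test_planted_decreasing_expression_gives_negative_slopes(self):
        df = self._frame(lambda ages, cov, rng:
                         20 - 1.5e-6 * ages + rng.normal(0, 0.5, len(ages)))
        out = slope_table(df)
        age_rows = out[out["correlation"] == "expression_vs_insertion_time"]
        assert (age_rows["slope"] < 0).all()
        assert set(age_rows["treatment"]) == {"C24", "S24", "C48", "S48"}

    def test_null_slopes_centre_on_zero(self):
        rng = np.random.default_rng(1)
        slopes = []
        for _ in range(50):
            df = self._frame(lambda ages, cov, r: r.normal(5, 1, len(ages)),
                             rng=rng)
            out = slope_table(df)
            slopes.extend(out[out["correlation"] ==
                              "expression_vs_insertion_time"]["slope"])
        # mean slope ~ 0 within 3 SE of the Monte-Carlo sample
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se

    def test_gypsy_rows_are_excluded_from_expression_correlations(self):
        df = self._frame(lambda ages, cov, rng: np.linspace(1, 5, len(ages)))
        df.loc[df.index[:15], "superfamily"] = "Gypsy"
        out = slope_table(df)
        assert (out["n"] == 15).all()

    def test_two_elements_has_slope_but_no_pvalue(self):
        df = self._frame(lambda ages, cov, rng: np.linspace(1, 5, len(ages)),
                         n=2)
        out = slope_table(df)
        assert out["p_value"].isna().all()
        assert np.isfinite(out["slope"]).all()

    def test_missing_treatment_is_error(self):
        df = self._frame(lambda ages, cov, rng: np.linspace(1, 5, len(ages)))
        with pytest.raises(ValueError):
            slope_table(df.drop(columns=["rpkm_S48"]))
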