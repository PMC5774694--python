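"""LM1 variance decomposition, permutation tests, Tukey letters, Wilcoxon, CV."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fermphen.gxe import (
    LM1_TERMS,
    Lm1Model,
    cv_table,
    fit_lm1,
    permutation_pvalues,
    significance_stars,
    tukey_letters,
    wilcoxon_compare,
)


def brute_force_percent_ss(df: pd.DataFrame, response: str = "value") -> dict:
    """Independent sequential-SS oracle from cell and marginal means.

    On a balanced design the sequential SS of each term equals the weighted
    sum of squared (interaction-)contrast means: main-effect SS from marginal
    means, interaction SS from cell means minus both marginals plus the grand
    mean, residual from within-cell deviations.
    """
    y = df[response].to_numpy(float)
    gm = y.mean()
    n = len(df)
    out = {}

    def marg(cols):
        return df.groupby(cols)[response].transform("mean").to_numpy()

    s, m, o = marg(["strain"]), marg(["must"]), marg(["shaking"])
    out["Strain"] = np.sum((s - gm) ** 2)
    out["Must"] = np.sum((m - gm) ** 2)
    out["MicroOxygenation"] = np.sum((o - gm) ** 2)
    sm = marg(["strain", "must"])
    so = marg(["strain", "shaking"])
    out["Strain:Must"] = np.sum((sm - s - m + gm) ** 2)
    out["Strain:MicroOxygenation"] = np.sum((so - s - o + gm) ** 2)
    cell = marg(["strain", "must", "shaking"])
    explained = sum(out.values())
    total = np.sum((y - gm) ** 2)
    out["Residual"] = total - explained
    return {k: 100 * v / total for k, v in out.items()}


class TestLm1:
    def test_single_contrast_goes_to_must(self):
        rows = []
        for s in "AB":
            for m in ["M1", "M2"]:
                for o in [False, True]:
                    for _ in range(2):
                        rows.append({"strain": s, "must": m, "shaking": o,
                                     "value": 1.0 if m == "M1" else 0.0})
        df = pd.DataFrame(rows)
        perc = fit_lm1(df)
        assert perc["Must"] == pytest.approx(100.0, abs=1e-9)
        assert perc.drop(["Must"]).abs().max() < 1e-9

    def test_matches_brute_force_oracle(self, balanced_table):
        perc = fit_lm1(balanced_table)
        oracle = brute_force_percent_ss(balanced_table)
        for term in perc.index:
            assert perc[term] == pytest.approx(oracle[term], abs=1e-9)
        assert perc.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_statsmodels_anova(self, balanced_table):
        """Cross-check the QR path against statsmodels' type-I ANOVA."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols(
            "value ~ C(strain) + C(must) + C(shaking) + C(strain):C(must) "
            "+ C(strain):C(shaking)", data=balanced_table,
        ).fit()
        tab = anova_lm(fit, typ=1)
        total = tab["sum_sq"].sum()
        perc = fit_lm1(balanced_table)
        mapping = {
            "C(strain)": "Strain", "C(must)": "Must", "C(shaking)": "MicroOxygenation",
            "C(strain):C(must)": "Strain:Must",
            "C(strain):C(shaking)": "Strain:MicroOxygenation",
            "Residual": "Residual",
        }
        for sm_name, term in mapping.items():
            assert perc[term] == pytest.approx(100 * tab.loc[sm_name, "sum_sq"] / total,
                                               abs=1e-8)

    def test_order_invariance_on_balanced(self, balanced_table):
        """Balanced designs: %SS identical after relabeling factor columns."""
        renamed = balanced_table.rename(columns={"must": "shaking", "shaking": "must"})
        a = fit_lm1(balanced_table)
        b = fit_lm1(renamed)
        assert a["Must"] == pytest.approx(b["MicroOxygenation"], abs=1e-9)
        assert a["MicroOxygenation"] == pytest.approx(b["Must"], abs=1e-9)
        assert a["Residual"] == pytest.approx(b["Residual"], abs=1e-9)

    def test_empty_cell_named(self, balanced_table):
        df = balanced_table[~((balanced_table.strain == "A") & (balanced_table.must == "M1"))]
        with pytest.raises(ValueError, match="strain=.?A.? x must=.?M1.?"):
            fit_lm1(df)

    def test_strong_effect_minimal_pvalue(self, balanced_table):
        df = balanced_table.copy()
        df.loc[df.must == "M1", "value"] += 50.0
        p = permutation_pvalues(df, n_perm=199, seed=0)
        assert p["Must"] == pytest.approx(1 / 200)

    def test_permutation_determinism(self, balanced_table):
        p1 = permutation_pvalues(balanced_table, n_perm=99, seed=42)
        p2 = permutation_pvalues(balanced_table, n_perm=99, seed=42)
        assert p1.equals(p2)

    def test_pvalues_in_valid_range(self, balanced_table):
        p = permutation_pvalues(balanced_table, n_perm=99, seed=1)
        assert ((p >= 1 / 100) & (p <= 1.0)).all()

    def test_null_pvalues_roughly_uniform(self):
        """Under the null, permutation p-values pass a KS uniformity check."""
        rng = np.random.default_rng(11)
        base = list(itertools.product("ABCD", ["M1", "M2"], [False, True], range(3)))
        pvals = []
        for _ in range(200):
            df = pd.DataFrame(
                [{"strain": s, "must": m, "shaking": o, "value": rng.normal()}
                 for s, m, o, _r in base]
            )
            model = Lm1Model(df)
            pvals.append(model.fit(n_perm=99, seed=int(rng.integers(2**31))).pvalues["Strain"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_unbalanced_warns(self, balanced_table, caplog):
        import logging

        df = balanced_table.iloc[:-1]
        with caplog.at_level(logging.WARNING):
            fit_lm1(df)
        assert any("unbalanced" in r.message for r in caplog.records)


class TestTukeyLetters:
    def test_separated_group(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.01, 5), rng.normal(0, 0.01, 5), rng.normal(10, 0.01, 5)]
        groups = np.r_[["g1"] * 5, ["g2"] * 5, ["g3"] * 5]
        letters = tukey_letters(vals, groups)
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] != letters["g1"]

    def test_all_identical(self):
        letters = tukey_letters([1.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert set(letters.values()) == {"a"}

    def test_graded_groups_match_pairwise_oracle(self):
        """Letter sharing agrees with brute-force pairwise Tukey decisions."""
        rng = np.random.default_rng(3)
        means = [0.0, 1.0, 4.0, 9.0]
        vals, groups = [], []
        for gi, mu in enumerate(means):
            vals.extend(rng.normal(mu, 1.0, 6))
            groups.extend([f"g{gi}"] * 6)
        vals, groups = np.asarray(vals), np.asarray(groups)
        letters = tukey_letters(vals, groups, alpha=0.05)

        # independent all-pairs oracle via statsmodels
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        hsd = pairwise_tukeyhsd(vals, groups, alpha=0.05)
        res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
        for _, row in res.iterrows():
            share = set(letters[row["group1"]]) & set(letters[row["group2"]])
            if row["reject"]:
                assert not share, f"{row['group1']} vs {row['group2']} should differ"
            else:
                assert share, f"{row['group1']} vs {row['group2']} should share a letter"

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="2 groups"):
            tukey_letters([1, 2, 3], ["a", "a", "a"])


class TestWilcoxon:
    def test_identical_samples(self):
        res = wilcoxon_compare([1, 2, 3], [1, 2, 3])
        assert res.pvalue == pytest.approx(1.0)
        assert not res.significant

    def test_fully_separated(self):
        a = np.arange(10, dtype=float)
        b = a + 100
        res = wilcoxon_compare(a, b)
        assert res.pvalue < 0.001
        # exact enumeration: most extreme arrangement has p = 2 / C(20, 10)
        assert res.pvalue == pytest.approx(2 / 184756, rel=1e-6)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        r1 = wilcoxon_compare(a, b)
        r2 = wilcoxon_compare(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_all_tied(self):
        res = wilcoxon_compare([5, 5, 5], [5, 5])
        assert res.pvalue == 1.0


class TestCvTable:
    def test_reference_values(self):
        df = pd.DataFrame({
            "strain": ["S"] * 3, "condition": ["c"] * 3, "trait": [0] * 3,
            "x": [9.0, 10.0, 11.0],
        })
        cv = cv_table(df, traits=["x"])
        assert cv.per_cell["cv_pct"].iloc[0] == pytest.approx(10.0)

    def test_identical_replicates_zero(self):
        df = pd.DataFrame({"strain": ["S"] * 3, "condition": ["c"] * 3, "x": [4.0] * 3})
        assert cv_table(df, ["x"]).per_cell["cv_pct"].iloc[0] == pytest.approx(0.0)

    def test_scale_invariance(self):
        df = pd.DataFrame({"strain": ["S"] * 4, "condition": ["c"] * 4,
                           "x": [1.0, 2.0, 3.0, 4.0]})
        df2 = df.assign(x=df.x * 7)
        assert cv_table(df, ["x"]).per_cell["cv_pct"].iloc[0] == pytest.approx(
            cv_table(df2, ["x"]).per_cell["cv_pct"].iloc[0]
        )

    def test_zero_mean_flagged(self):
        df = pd.DataFrame({"strain": ["S"] * 2, "condition": ["c"] * 2, "x": [-1.0, 1.0]})
        cv = cv_table(df, ["x"])
        assert cv.per_cell["flag"].iloc[0] == "UNDEFINED_CV"
        assert np.isnan(cv.per_cell["cv_pct"].iloc[0])

    def test_cumulated_is_sum_over_traits(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "strain": np.repeat(["S1", "S2"], 6),
            "condition": ["c"] * 12,
            "x": rng.uniform(5, 10, 12), "y": rng.uniform(5, 10, 12),
        })
        cv = cv_table(df, ["x", "y"])
        assert cv.cumulated["c"] == pytest.approx(cv.per_condition.loc["c"].sum())


def test_significance_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.07) == "."
    assert significance_stars(0.5) == ""
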