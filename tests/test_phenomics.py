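"""Multivariate phenomics: normalization, correlations, PCA, ranking, robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fermphen.phenomics import (
    correlation_matrix,
    normalize_by_must,
    pca,
    rank_clustermap,
    robustness_analysis,
    strain_dispersion,
)


def _survey_table(n_strains=6, musts=("M1", "M2", "M3"), seed=0, traits=("x", "y", "z")):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strains):
        for m in musts:
            row = {"strain": f"S{s}", "must": m}
            for t in traits:
                row[t] = rng.normal(loc=10 * hash(m) % 7, scale=2.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestNormalize:
    def test_basic_column(self):
        df = pd.DataFrame({"strain": list("abc"), "must": ["M"] * 3, "x": [1.0, 2.0, 3.0]})
        out = normalize_by_must(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1, 0, 1])

    def test_idempotent(self):
        df = _survey_table()
        once = normalize_by_must(df, ["x", "y", "z"])
        twice = normalize_by_must(once, ["x", "y", "z"])
        np.testing.assert_allclose(once[["x", "y", "z"]], twice[["x", "y", "z"]], atol=1e-12)

    def test_means_zero_sds_one(self):
        out = normalize_by_must(_survey_table(), ["x", "y", "z"])
        for _, grp in out.groupby("must"):
            np.testing.assert_allclose(grp[["x", "y", "z"]].mean(), 0, atol=1e-9)
            np.testing.assert_allclose(grp[["x", "y", "z"]].std(ddof=1), 1, atol=1e-9)

    def test_zero_variance_named(self):
        df = _survey_table()
        df.loc[df.must == "M2", "y"] = 4.2
        with pytest.raises(ValueError, match=r"'y'.*'M2'"):
            normalize_by_must(df, ["x", "y", "z"])


class TestCorrelation:
    def test_monotone_pair(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"]
        res = correlation_matrix(df, ["x", "y"])
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)
        assert res.significant.loc["x", "y"]

    def test_symmetric_unit_diagonal(self):
        df = _survey_table(seed=5)
        res = correlation_matrix(df, ["x", "y", "z"])
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(np.diag(res.rho), 1.0)

    def test_constant_trait_flagged(self):
        df = _survey_table(seed=2)
        df["c"] = 1.0
        res = correlation_matrix(df, ["x", "c"])
        assert "c" in res.constant_traits
        assert np.isnan(res.rho.loc["x", "c"])
        assert not res.significant.loc["x", "c"]

    def test_spearman_rank_invariance(self):
        """rho is unchanged by a monotone transform applied to one trait."""
        df = _survey_table(seed=8)
        a = correlation_matrix(df, ["x", "y"])
        df2 = df.assign(y=np.exp(df["y"] / 3))
        b = correlation_matrix(df2, ["x", "y"])
        assert a.rho.loc["x", "y"] == pytest.approx(b.rho.loc["x", "y"])


class TestPca:
    def test_two_identical_directions(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": 3 * x + 1})
        res = pca(df, ["x", "y"])
        assert res.percent_variance.iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_sums_to_100(self):
        df = _survey_table(n_strains=8, seed=4)
        res = pca(df, ["x", "y", "z"])
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        """Axis variances equal eigenvalues of the correlation matrix."""
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        res = pca(df, list("abcd"))
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(
            res.percent_variance.to_numpy(), 100 * eig / eig.sum(), atol=1e-8
        )

    def test_observation_order_invariant(self):
        df = _survey_table(n_strains=7, seed=3)
        a = pca(df, ["x", "y", "z"]).percent_variance
        b = pca(df.sample(frac=1, random_state=1), ["x", "y", "z"]).percent_variance
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_variance_rejected(self):
        df = _survey_table()
        df["c"] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            pca(df, ["x", "c"])

    def test_loadings_are_correlations(self):
        df = _survey_table(n_strains=10, seed=6)
        res = pca(df, ["x", "y", "z"])
        assert (res.loadings.abs().to_numpy() <= 1 + 1e-9).all()


class TestDispersion:
    def test_three_four_five(self):
        df = pd.DataFrame({
            "strain": ["A", "B"], "must": ["M", "M"],
            "u": [0.0, 3.0], "v": [0.0, 4.0],
        })
        out = strain_dispersion(df, {"k": ["u", "v"]})
        assert out.loc["M", "k"] == pytest.approx(5.0)

    def test_identical_strains_zero(self):
        df = pd.DataFrame({
            "strain": list("ABC"), "must": ["M"] * 3, "u": [1.0] * 3, "v": [2.0] * 3,
        })
        assert strain_dispersion(df, {"k": ["u", "v"]}).loc["M", "k"] == 0.0

    def test_matches_pair_enumeration(self):
        df = _survey_table(n_strains=6, musts=("M1",), seed=12)
        out = strain_dispersion(df, {"all": ["x", "y", "z"]})
        vals = df[["x", "y", "z"]].to_numpy()
        dists = [np.linalg.norm(vals[i] - vals[j])
                 for i, j in itertools.combinations(range(6), 2)]
        assert out.loc["M1", "all"] == pytest.approx(np.mean(dists))

    def test_empty_class_rejected(self):
        df = _survey_table()
        with pytest.raises(ValueError, match="no traits"):
            strain_dispersion(df, {"k": []})


class TestRankClustermap:
    def test_rank_values(self):
        df = pd.DataFrame({"t": [5.0, 2.0, 9.0]}, index=["a", "b", "c"])
        rc = rank_clustermap(df, ["t"])
        assert rc.ranks["t"].tolist() == [2.0, 1.0, 3.0]

    def test_columns_are_permutations(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(9, 3)), columns=list("abc"),
                          index=[f"S{i}" for i in range(9)])
        rc = rank_clustermap(df, list("abc"))
        for col in "abc":
            assert sorted(rc.ranks[col]) == list(range(1, 10))

    def test_two_pairs_clustered_with_oracle_heights(self):
        """Clear pairs merge first; heights match naive complete linkage."""
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 9.0, 10.0], "b": [1.0, 2.0, 9.0, 10.0]},
            index=["p1", "p2", "q1", "q2"],
        )
        rc = rank_clustermap(df, ["a", "b"], max_abs_rho=1.1)
        order = list(rc.leaf_order)
        assert {order.index("p1"), order.index("p2")} in ({0, 1}, {2, 3})
        ranks = rc.ranks.to_numpy()
        # naive complete linkage on 4 points: first two merges at pair
        # distances, final at the max inter-pair distance
        d = lambda i, j: np.linalg.norm(ranks[i] - ranks[j])
        expected = sorted([d(0, 1), d(2, 3)]) + [max(d(i, j) for i in (0, 1) for j in (2, 3))]
        np.testing.assert_allclose(sorted(rc.linkage[:, 2]), sorted(expected))

    def test_redundant_traits_warn(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]},
                          index=list("wxyz"))
        with pytest.warns(UserWarning, match="rank-correlated"):
            rank_clustermap(df, ["a", "b"], max_abs_rho=0.8)


class TestRobustness:
    def _means_table(self, n_strains=8, musts=("M1", "M2", "M3"), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_strains):
            base = rng.normal(10, 1)
            for m in musts:
                rows.append({"strain": f"S{s:02d}", "must": m,
                             "x": base + rng.normal(0, 0.5),
                             "y": rng.normal(5, 1)})
        return pd.DataFrame(rows)

    def test_constant_strain_never_fluctuating(self):
        df = self._means_table()
        df.loc[df.strain == "S00", "x"] = 7.0
        df.loc[df.strain == "S00", "y"] = 3.0
        rep = robustness_analysis(df, ["x", "y"])
        assert not rep.fluctuating.loc["S00"].any()
        assert rep.variance.loc["S00", "x"] == 0.0

    def test_quartile_sizes(self):
        df = self._means_table(n_strains=35, seed=3)
        rep = robustness_analysis(df, ["x", "y"])
        assert rep.quartile_size == 8
        assert rep.fluctuating["x"].sum() == 8
        assert (~rep.fluctuating["x"]).sum() == 27

    def test_too_few_strains_rejected(self):
        df = self._means_table(n_strains=3)
        with pytest.raises(ValueError):
            robustness_analysis(df, ["x", "y"])

    def test_interaction_strain_lands_in_fluctuating_quartile(self):
        df = self._means_table(n_strains=12, seed=5)
        # one strain with a strong must-dependent response on x
        df.loc[(df.strain == "S03") & (df.must == "M1"), "x"] += 8.0
        rep = robustness_analysis(df, ["x", "y"])
        assert "S03" in rep.fluctuating_strains("x")

    def test_report_contrasts_complete(self):
        df = self._means_table(n_strains=10, seed=9)
        rep = robustness_analysis(df, ["x", "y"])
        assert set(rep.group_means["trait"]) == {"x", "y"}
        assert len(rep.group_means) == 2 * 3  # traits x musts
        assert set(rep.letters) == {"x", "y"}
        assert len(rep.letters["x"]) == 6  # musts x {fluctuating, robust}
        # scaled variance is column-standardized for display
        np.testing.assert_allclose(rep.scaled_variance.mean(), 0, atol=1e-9)
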