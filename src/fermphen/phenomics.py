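"""Multivariate strain characterization across grape musts.

Operates on phenotype tables whose observations are strain x must replicate
means and whose variables are kinetic and metabolite traits.  Provides:

* per-must centering/scaling, so strain behaviour can be compared across
  musts whose raw scales differ wildly;
* Spearman trait-trait correlation structure with significance masking;
* PCA on standardized variables with loadings as variable-axis correlations
  (correlation-circle convention);
* within-must strain dispersion (average pairwise Euclidean distance) per
  trait class, quantifying how well a must discriminates strains;
* strain ranking with hierarchical clustering (rank heatmap);
* the robustness analysis: cross-must variance per strain and trait, a
  fluctuating-quartile split, and robust-vs-fluctuating group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .gxe import WilcoxonResult, tukey_letters, wilcoxon_compare

__all__ = [
    "normalize_by_must",
    "correlation_matrix",
    "CorrelationResult",
    "pca",
    "PcaResult",
    "strain_dispersion",
    "rank_clustermap",
    "RankClustermap",
    "robustness_analysis",
    "RobustnessReport",
]


def normalize_by_must(
    table: pd.DataFrame,
    traits: Sequence[str],
    must: str = "must",
) -> pd.DataFrame:
    """Center and scale each trait to mean 0 / sd 1 within each must.

    Uses the sample standard deviation (n-1).  Raises when a trait is
    constant within a must, naming both.
    """
    out = table.copy()
    for m, grp in table.groupby(must, sort=True):
        if len(grp) < 2:
            raise ValueError(f"must {m!r} has < 2 strains; cannot normalize")
        for trait in traits:
            vals = grp[trait].to_numpy(dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"trait {trait!r} has zero variance within must {m!r}")
            out.loc[grp.index, trait] = (vals - vals.mean()) / sd
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman trait-trait correlations with a significance mask."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    constant_traits: tuple[str, ...]

    def summary(self) -> str:
        n_sig = int(self.significant.to_numpy()[np.triu_indices(len(self.rho), 1)].sum())
        lines = [
            f"Spearman correlation matrix: {len(self.rho)} traits, "
            f"{n_sig} significant pairs",
        ]
        if self.constant_traits:
            lines.append(f"constant traits (rho undefined): {', '.join(self.constant_traits)}")
        return "\n".join(lines)


def correlation_matrix(
    table: pd.DataFrame,
    traits: Sequence[str],
    alpha: float = 0.05,
) -> CorrelationResult:
    """All-pairs Spearman rho with per-pair significance at ``alpha``.

    Ties receive average ranks; the mask is true where the null rho = 0 is
    rejected.  Constant traits yield undefined correlations and are flagged
    rather than raising.
    """
    x = table[list(traits)].to_numpy(dtype=float)
    if x.shape[0] < 4:
        raise ValueError(f"need >= 4 observations, got {x.shape[0]}")
    constant = tuple(t for j, t in enumerate(traits) if np.all(x[:, j] == x[0, j]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(x)
    if np.ndim(rho) == 0:  # scipy collapses the two-variable case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    for j, t in enumerate(traits):
        if t in constant:
            rho[j, :] = rho[:, j] = np.nan
            pval[j, :] = pval[:, j] = np.nan
    idx = pd.Index(traits, name="trait")
    rho_df = pd.DataFrame(rho, index=idx, columns=idx)
    p_df = pd.DataFrame(pval, index=idx, columns=idx)
    sig = (p_df < alpha).fillna(False)
    np.fill_diagonal(sig.values, False)
    return CorrelationResult(rho=rho_df, pvalues=p_df, significant=sig, constant_traits=constant)


@dataclass(frozen=True)
class PcaResult:
    """PCA scores, correlation-circle loadings and percent variance per axis."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: pd.Series

    def summary(self) -> str:
        head = self.percent_variance.iloc[: min(4, len(self.percent_variance))]
        axes = ", ".join(f"{a}: {v:.1f} %" for a, v in head.items())
        return (
            f"PCA on {self.scores.shape[0]} observations x {self.loadings.shape[0]} "
            f"standardized variables\n  variance explained - {axes}"
        )

    def plot(self, axes=(1, 2)):
        """Score scatter and correlation circle for two principal axes."""
        import matplotlib.pyplot as plt

        a1, a2 = (f"PC{axes[0]}", f"PC{axes[1]}")
        fig, (ax_sc, ax_cc) = plt.subplots(1, 2, figsize=(10, 5))
        ax_sc.scatter(self.scores[a1], self.scores[a2], s=12)
        ax_sc.set_xlabel(f"{a1} ({self.percent_variance[a1]:.1f} %)")
        ax_sc.set_ylabel(f"{a2} ({self.percent_variance[a2]:.1f} %)")
        ax_sc.axhline(0, lw=0.5, color="grey")
        ax_sc.axvline(0, lw=0.5, color="grey")
        theta = np.linspace(0, 2 * np.pi, 200)
        ax_cc.plot(np.cos(theta), np.sin(theta), lw=0.5, color="grey")
        for trait, row in self.loadings.iterrows():
            ax_cc.annotate("", xy=(row[a1], row[a2]), xytext=(0, 0),
                           arrowprops=dict(arrowstyle="->", lw=0.8))
            ax_cc.text(row[a1] * 1.05, row[a2] * 1.05, str(trait), fontsize=8)
        ax_cc.set_xlim(-1.1, 1.1)
        ax_cc.set_ylim(-1.1, 1.1)
        ax_cc.set_aspect("equal")
        ax_cc.set_xlabel(a1)
        ax_cc.set_ylabel(a2)
        fig.tight_layout()
        return fig


def pca(table: pd.DataFrame, traits: Sequence[str]) -> PcaResult:
    """PCA on centered, unit-variance variables.

    Percent variance per axis sums to 100; loadings are reported as the
    Pearson correlation between each variable and each axis's scores, the
    quantity drawn on a correlation circle.
    """
    from sklearn.decomposition import PCA

    x = table[list(traits)].to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 observations and >= 2 variables")
    sd = x.std(axis=0, ddof=1)
    zero = [t for t, s in zip(traits, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variables: {zero}")
    z = (x - x.mean(axis=0)) / sd

    model = PCA()
    scores = model.fit_transform(z)
    k = scores.shape[1]
    axis_names = [f"PC{i + 1}" for i in range(k)]
    pct = pd.Series(100.0 * model.explained_variance_ratio_, index=axis_names)

    load = np.zeros((len(traits), k))
    for j in range(k):
        s = scores[:, j]
        s_sd = s.std(ddof=1)
        if s_sd > 0:
            load[:, j] = [np.corrcoef(z[:, v], s)[0, 1] for v in range(len(traits))]
    scores_df = pd.DataFrame(scores, index=table.index, columns=axis_names)
    load_df = pd.DataFrame(load, index=pd.Index(traits, name="trait"), columns=axis_names)
    return PcaResult(scores=scores_df, loadings=load_df, percent_variance=pct)


def strain_dispersion(
    table: pd.DataFrame,
    trait_classes: Mapping[str, Sequence[str]],
    must: str = "must",
    strain: str = "strain",
) -> pd.DataFrame:
    """Average pairwise strain distance per must and trait class.

    For each must and class (e.g. kinetic vs metabolic traits), the mean over
    all unordered strain pairs of the Euclidean distance between their trait
    subvectors.  Expects standardized (per-must normalized) input so traits
    contribute comparably.
    """
    for cls, cols in trait_classes.items():
        if len(cols) == 0:
            raise ValueError(f"trait class {cls!r} contains no traits")
    rows = []
    for m, grp in table.groupby(must, sort=True):
        if grp[strain].duplicated().any():
            raise ValueError(f"must {m!r}: multiple rows per strain; aggregate replicates first")
        if len(grp) < 2:
            raise ValueError(f"must {m!r} has < 2 strains")
        for cls, cols in trait_classes.items():
            d = pdist(grp[list(cols)].to_numpy(dtype=float), metric="euclidean")
            rows.append({must: m, "trait_class": cls, "mean_distance": float(d.mean())})
    return pd.DataFrame(rows).pivot(index=must, columns="trait_class", values="mean_distance")


@dataclass(frozen=True)
class RankClustermap:
    """Strain rank matrix with a hierarchical-clustering leaf order."""

    ranks: pd.DataFrame
    linkage: np.ndarray
    leaf_order: tuple[str, ...]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.25 * len(self.ranks) + 1))
        ordered = self.ranks.loc[list(self.leaf_order)]
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(ordered)), ordered.index)
        ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90)
        plt.colorbar(im, ax=ax, label="rank")
        return ax


def rank_clustermap(
    table: pd.DataFrame,
    traits: Sequence[str],
    max_abs_rho: float = 0.8,
) -> RankClustermap:
    """Rank strains per trait and cluster them on the rank matrix.

    ``table`` must be indexed by strain (one row per strain, e.g. cross-must
    means of normalized values).  Ranks are ascending 1..n with average ranks
    on ties, so every trait weighs equally; strains are clustered by complete
    linkage on Euclidean distances between rank vectors.  Trait pairs more
    rank-correlated than ``max_abs_rho`` trigger a redundancy warning, since
    strongly correlated traits double-weight the clustering.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 strains to rank and cluster")
    x = table[list(traits)].to_numpy(dtype=float)
    ranks = np.column_stack([stats.rankdata(x[:, j], method="average") for j in range(x.shape[1])])
    if len(traits) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(x).statistic
        if np.ndim(rho) == 0:
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        hi = np.argwhere(np.triu(np.abs(rho), 1) > max_abs_rho)
        for i, j in hi:
            warnings.warn(
                f"traits {traits[i]!r} and {traits[j]!r} are strongly rank-correlated "
                f"(|rho| > {max_abs_rho}); consider dropping one",
                stacklevel=2,
            )
    rank_df = pd.DataFrame(ranks, index=table.index, columns=list(traits))
    z = hierarchy.linkage(ranks, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(z)
    return RankClustermap(
        ranks=rank_df, linkage=z, leaf_order=tuple(table.index[i] for i in order)
    )


@dataclass(frozen=True)
class RobustnessReport:
    """Cross-must variance analysis of strain robustness.

    ``variance``: per strain x trait, sample variance of the per-must means;
    ``scaled_variance``: the same matrix z-scored by column for display;
    ``fluctuating``: boolean strain x trait membership of the most
    fluctuating quartile; ``group_means``: per must x trait, the mean of the
    fluctuating and robust groups; ``letters``: per trait, Tukey compact
    letters over the must x group cells; ``wilcoxon``: per must x trait,
    the two-sample fluctuating-vs-robust comparison.
    """

    variance: pd.DataFrame
    scaled_variance: pd.DataFrame
    fluctuating: pd.DataFrame
    group_means: pd.DataFrame
    letters: dict
    wilcoxon: pd.DataFrame
    quartile_size: int

    def fluctuating_strains(self, trait: str) -> tuple[str, ...]:
        col = self.fluctuating[trait]
        return tuple(col.index[col])

    def summary(self) -> str:
        n = len(self.variance)
        lines = [
            f"Robustness analysis: {n} strains x {self.variance.shape[1]} traits; "
            f"fluctuating quartile = {self.quartile_size} strains per trait "
            f"(robust group = {n - self.quartile_size})",
        ]
        for trait in self.variance.columns:
            lines.append(f"  {trait}: fluctuating = {', '.join(self.fluctuating_strains(trait))}")
        return "\n".join(lines)


def robustness_analysis(
    per_must_means: pd.DataFrame,
    traits: Sequence[str],
    strain: str = "strain",
    must: str = "must",
    quartile_fraction: float = 0.25,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Classify strains as robust or fluctuating from cross-must variance.

    Works on the raw (non-normalized) per-must mean table so genuine
    strain x must interactions drive the variance.  Per trait, the
    ``floor(quartile_fraction * n_strains)`` highest-variance strains form
    the fluctuating group (for 35 strains: 8 fluctuating vs 27 robust); per
    must, the two groups' trait means are contrasted with Tukey letters over
    the must x group cells and a Wilcoxon two-sample fallback.
    """
    wide = per_must_means.pivot_table(index=strain, columns=must, values=list(traits))
    if wide.isna().any().any():
        raise ValueError("every strain needs a value in every must")
    strains = list(wide.index)
    musts = sorted(per_must_means[must].unique())
    if len(musts) < 2:
        raise ValueError("need >= 2 musts to measure cross-must variance")
    n = len(strains)
    q = int(quartile_fraction * n)
    if q < 1 or q >= n:
        raise ValueError(
            f"fluctuating quartile of {n} strains would have {q} members; "
            "need at least 4 strains"
        )

    var = pd.DataFrame(
        {t: wide[t].var(axis=1, ddof=1) for t in traits}, index=wide.index
    )
    scaled = (var - var.mean()) / var.std(ddof=1)

    fluct = pd.DataFrame(False, index=var.index, columns=list(traits))
    for t in traits:
        top = var[t].sort_values(ascending=False, kind="stable").index[:q]
        fluct.loc[top, t] = True

    gm_rows, wx_rows = [], []
    letters: dict = {}
    for t in traits:
        f_strains = fluct.index[fluct[t]]
        cell_vals, cell_labels = [], []
        for m in musts:
            sub = per_must_means[per_must_means[must] == m].set_index(strain)[t]
            fv = sub.loc[sub.index.intersection(f_strains)].to_numpy(dtype=float)
            rv = sub.loc[sub.index.difference(f_strains)].to_numpy(dtype=float)
            gm_rows.append({
                "trait": t, must: m,
                "fluctuating_mean": float(fv.mean()), "robust_mean": float(rv.mean()),
                "fluctuating_sem": float(fv.std(ddof=1) / np.sqrt(fv.size)),
                "robust_sem": float(rv.std(ddof=1) / np.sqrt(rv.size)),
            })
            wres: WilcoxonResult = wilcoxon_compare(fv, rv, alpha=alpha)
            wx_rows.append({
                "trait": t, must: m, "statistic": wres.statistic,
                "pvalue": wres.pvalue, "significant": wres.significant,
            })
            cell_vals.extend(fv)
            cell_labels.extend([f"{m}|fluctuating"] * fv.size)
            cell_vals.extend(rv)
            cell_labels.extend([f"{m}|robust"] * rv.size)
        letters[t] = tukey_letters(cell_vals, cell_labels, alpha=alpha)

    return RobustnessReport(
        variance=var,
        scaled_variance=scaled,
        fluctuating=fluct,
        group_means=pd.DataFrame(gm_rows),
        letters=letters,
        wilcoxon=pd.DataFrame(wx_rows),
        quartile_size=q,
    )
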