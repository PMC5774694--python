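"""Genotype x environment univariate statistics.

The workhorse is the two-way-plus-interactions ANOVA ("LM1")

    y = m + Strain + Must + MicroOxygenation
          + Strain x Must + Strain x MicroOxygenation + error

fitted per trait on a (near-)balanced factorial of vials.  The variance
decomposition reports each term's share of the total sum of squares;
significance comes from permutation of the response rather than normal
theory.  Post-hoc group comparisons use Tukey's HSD rendered as a compact
letter display, two-sample comparisons use the Wilcoxon-Mann-Whitney test,
and replicate quality control uses coefficient-of-variation tables.

``Lm1Model(df, response).fit(n_perm, seed)`` returns an :class:`Lm1Results`
whose ``summary()`` prints the per-term percentages with significance stars.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Lm1Model",
    "Lm1Results",
    "fit_lm1",
    "permutation_pvalues",
    "tukey_letters",
    "wilcoxon_compare",
    "WilcoxonResult",
    "cv_table",
    "CvTable",
    "significance_stars",
]

#: Model terms in fitting order (sequential SS; order-invariant when balanced).
LM1_TERMS = ("Strain", "Must", "MicroOxygenation", "Strain:Must", "Strain:MicroOxygenation")


def significance_stars(p: float) -> str:
    """Conventional star codes: *** <0.001, ** <0.01, * <0.05, '.' <0.1."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded indicator columns (drop first level)."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise products of two dummy blocks."""
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.zeros((a.shape[0], 0))
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


class Lm1Model:
    """Sequential-SS ANOVA of one trait on a strain x must x oxygenation design.

    Parameters
    ----------
    data : DataFrame
        One row per vial with columns for the three factors and the response.
    response : str
        Name of the trait column, default ``"value"``.
    strain, must, mox : str
        Factor column names (``mox`` = micro-oxygenation / shaking level).

    Notes
    -----
    Sums of squares are sequential (type I), computed through a QR
    factorization of the blocked design matrix so that permutation replicates
    reduce to one matrix product.  On balanced designs the decomposition is
    order-invariant; unbalanced input triggers a logged warning.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "value",
        strain: str = "strain",
        must: str = "must",
        mox: str = "shaking",
    ):
        for col in (response, strain, must, mox):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data.reset_index(drop=True)
        self.response = response
        y = self.data[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"response {response!r} contains non-finite values")
        self.y = y

        s_codes, self.strain_levels = pd.factorize(self.data[strain], sort=True)
        m_codes, self.must_levels = pd.factorize(self.data[must], sort=True)
        o_codes, self.mox_levels = pd.factorize(self.data[mox], sort=True)
        for name, levels in (
            (strain, self.strain_levels), (must, self.must_levels), (mox, self.mox_levels)
        ):
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels, got {len(levels)}")

        self._check_cells(s_codes, m_codes, strain, must, self.strain_levels, self.must_levels)
        self._check_cells(s_codes, o_codes, strain, mox, self.strain_levels, self.mox_levels)

        counts = pd.crosstab(index=[s_codes, m_codes], columns=o_codes).to_numpy()
        self.balanced = counts.size > 0 and np.all(counts == counts.flat[0])
        if not self.balanced:
            logger.warning(
                "design is unbalanced; sequential (type I) sums of squares depend on term order"
            )

        ds = _dummies(s_codes, len(self.strain_levels))
        dm = _dummies(m_codes, len(self.must_levels))
        do = _dummies(o_codes, len(self.mox_levels))
        blocks = [
            np.ones((y.size, 1)),
            ds, dm, do,
            _interaction(ds, dm),
            _interaction(ds, do),
        ]
        widths = [b.shape[1] for b in blocks]
        x = np.hstack(blocks)
        if x.shape[1] >= y.size:
            raise ValueError("no residual degrees of freedom: need replicated cells")
        q, r = np.linalg.qr(x)
        if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
            raise ValueError("design matrix is rank-deficient; a model term is inestimable")
        self._q = q
        # column slice of each term (skip intercept block)
        edges = np.cumsum([0] + widths)
        self._slices = {
            term: slice(edges[i + 1], edges[i + 2]) for i, term in enumerate(LM1_TERMS)
        }
        self.df_terms = {term: widths[i + 1] for i, term in enumerate(LM1_TERMS)}
        self.df_resid = y.size - sum(widths)
        if self.df_resid <= 0:
            raise ValueError("no residual degrees of freedom: need >= 2 replicates per cell")

    @staticmethod
    def _check_cells(a_codes, b_codes, a_name, b_name, a_levels, b_levels) -> None:
        table = np.zeros((len(a_levels), len(b_levels)), dtype=int)
        np.add.at(table, (a_codes, b_codes), 1)
        empty = np.argwhere(table == 0)
        if empty.size:
            i, j = empty[0]
            raise ValueError(
                f"empty design cell: {a_name}={a_levels[i]!r} x {b_name}={b_levels[j]!r} "
                f"has no observations, so the {a_name}:{b_name} interaction is inestimable"
            )

    def _term_ss(self, y: np.ndarray) -> tuple[dict, np.ndarray]:
        """Sequential SS per term and residual SS for response column(s) y."""
        proj = self._q.T @ y  # (p, ...) coordinates in the orthonormal basis
        ss = {term: np.sum(proj[sl] ** 2, axis=0) for term, sl in self._slices.items()}
        resid = np.sum(y**2, axis=0) - np.sum(proj**2, axis=0)
        return ss, resid

    def fit(self, n_perm: int = 5000, seed: int | None = None) -> "Lm1Results":
        """Decompose the variance; add permutation p-values when ``n_perm > 0``.

        The response is permuted across all rows; for each term
        ``p = (1 + #(F_perm >= F_obs)) / (n_perm + 1)``.
        """
        y = self.y
        ss, ss_resid = self._term_ss(y)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        if ss_total <= 0:
            # constant response: no variance to attribute to any model term
            perc = {t: 0.0 for t in LM1_TERMS}
            perc["Residual"] = 100.0
            f_obs = {t: float("nan") for t in LM1_TERMS}
        else:
            perc = {t: 100.0 * float(ss[t]) / ss_total for t in LM1_TERMS}
            perc["Residual"] = 100.0 * float(ss_resid) / ss_total
            ms_resid = float(ss_resid) / self.df_resid
            f_obs = {
                t: (float(ss[t]) / self.df_terms[t]) / ms_resid if ms_resid > 0 else np.inf
                for t in LM1_TERMS
            }

        pvalues = {t: float("nan") for t in LM1_TERMS}
        if n_perm > 0:
            if ss_total <= 0:
                raise ValueError("response has zero total variance; no permutation test possible")
            if seed is None:
                raise ValueError("a seed is required for permutation p-values")
            rng = np.random.default_rng(seed)
            yp = np.empty((y.size, n_perm))
            for j in range(n_perm):
                yp[:, j] = rng.permutation(y)
            ss_p, resid_p = self._term_ss(yp)
            ms_resid_p = resid_p / self.df_resid
            for t in LM1_TERMS:
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_p = (ss_p[t] / self.df_terms[t]) / ms_resid_p
                exceed = int(np.sum(f_p >= f_obs[t]))
                pvalues[t] = (1 + exceed) / (n_perm + 1)

        return Lm1Results(
            model=self,
            percent_ss=pd.Series(perc, name=self.response),
            pvalues=pd.Series(pvalues, name=self.response),
            f_obs=pd.Series(f_obs),
            n_perm=n_perm,
        )


@dataclass(frozen=True)
class Lm1Results:
    """Variance decomposition of one trait with permutation p-values."""

    model: Lm1Model
    percent_ss: pd.Series
    pvalues: pd.Series
    f_obs: pd.Series
    n_perm: int

    @property
    def trait(self) -> str:
        return self.model.response

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term table: %SS, F, permutation p, stars."""
        terms = list(LM1_TERMS) + ["Residual"]
        return pd.DataFrame(
            {
                "trait": self.trait,
                "term": terms,
                "percent_ss": [self.percent_ss[t] for t in terms],
                "F": [self.f_obs.get(t, np.nan) for t in terms],
                "p_perm": [self.pvalues.get(t, np.nan) for t in terms],
                "stars": [significance_stars(self.pvalues.get(t, np.nan)) for t in terms],
            }
        )

    def summary(self) -> str:
        lines = [
            f"LM1 variance decomposition - trait {self.trait!r} "
            f"(n = {self.model.y.size}, permutations = {self.n_perm})",
            f"{'term':<28}{'%SS':>8}  {'p':>10}",
        ]
        for t in LM1_TERMS:
            p = self.pvalues[t]
            ptxt = f"{p:.4g} {significance_stars(p)}" if np.isfinite(p) else "-"
            lines.append(f"{t:<28}{self.percent_ss[t]:>8.1f}  {ptxt:>10}")
        lines.append(f"{'Residual':<28}{self.percent_ss['Residual']:>8.1f}")
        return "\n".join(lines)


def fit_lm1(
    data: pd.DataFrame,
    response: str = "value",
    strain: str = "strain",
    must: str = "must",
    mox: str = "shaking",
) -> pd.Series:
    """Percent of total SS per LM1 term (no permutation test)."""
    return Lm1Model(data, response, strain, must, mox).fit(n_perm=0).percent_ss


def permutation_pvalues(
    data: pd.DataFrame,
    n_perm: int = 5000,
    seed: int | None = None,
    response: str = "value",
    strain: str = "strain",
    must: str = "must",
    mox: str = "shaking",
) -> pd.Series:
    """Permutation p-value per LM1 term (response permuted across rows)."""
    return Lm1Model(data, response, strain, must, mox).fit(n_perm=n_perm, seed=seed).pvalues


# ---------------------------------------------------------------------------
# post-hoc comparisons


def _insert_absorb(n_groups: int, significant_pairs: set[tuple[int, int]]) -> list[str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Starts with one letter spanning all groups; each significantly different
    pair splits every letter containing both; letters whose group set is a
    subset of another's are absorbed.
    """
    letters: list[set[int]] = [set(range(n_groups))]
    for i, j in sorted(significant_pairs):
        for col in [c for c in letters if i in c and j in c]:
            letters.remove(col)
            a, b = col - {j}, col - {i}
            for new in (a, b):
                if not any(new <= other for other in letters):
                    letters.append(new)
    letters = [c for c in letters if c and not any(c < other for other in letters)]
    deduped: list[set[int]] = []
    for c in letters:
        if c not in deduped:
            deduped.append(c)
    letters = deduped
    # order letters by their smallest member for a stable display
    letters.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    codes = ["" for _ in range(n_groups)]
    for li, col in enumerate(letters):
        ch = alphabet[li % len(alphabet)] * (1 + li // len(alphabet))
        for g in sorted(col):
            codes[g] += ch
    return codes


def tukey_letters(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> dict:
    """All-pairs Tukey HSD as a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    The pairwise tests use the pooled-variance studentized range on the
    one-way fit; the letter assignment uses insert-and-absorb.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must be equal length")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 1:
        raise ValueError("every group needs at least one observation")

    means = np.array([values[groups == g].mean() for g in labels])
    ns = counts.astype(float)
    df_resid = values.size - labels.size
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for Tukey HSD")
    sse = sum(float(np.sum((values[groups == g] - m) ** 2)) for g, m in zip(labels, means))
    mse = sse / df_resid

    sig: set[tuple[int, int]] = set()
    if mse == 0:
        for i in range(labels.size):
            for j in range(i + 1, labels.size):
                if means[i] != means[j]:
                    sig.add((i, j))
    else:
        qcrit = stats.studentized_range.ppf(1 - alpha, labels.size, df_resid)
        for i in range(labels.size):
            for j in range(i + 1, labels.size):
                se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
                if abs(means[i] - means[j]) / se > qcrit:
                    sig.add((i, j))

    # assign letters walking groups in descending mean order (field convention)
    order = np.argsort(-means, kind="stable")
    sig_ord = {(int(np.where(order == i)[0][0]), int(np.where(order == j)[0][0])) for i, j in sig}
    codes_ord = _insert_absorb(labels.size, sig_ord)
    return {labels[order[k]]: codes_ord[k] for k in range(labels.size)}


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    pvalue: float
    significant: bool


def wilcoxon_compare(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
) -> WilcoxonResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum comparison.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.  Two samples that are completely tied give
    p = 1 (no signal), not an error.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(statistic=a.size * b.size / 2.0, pvalue=1.0, significant=False)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return WilcoxonResult(statistic=float(res.statistic), pvalue=p, significant=p < alpha)


# ---------------------------------------------------------------------------
# replicate quality control


@dataclass(frozen=True)
class CvTable:
    """Replicate coefficient-of-variation tables.

    ``per_cell``: one row per (strain, condition, trait) with mean, sd and
    CV %; ``per_condition``: trait-averaged CV per condition; ``cumulated``:
    per condition, the sum over traits of the strain-averaged CVs (the height
    of a stacked CV bar chart).
    """

    per_cell: pd.DataFrame
    per_condition: pd.DataFrame
    cumulated: pd.Series


def cv_table(
    data: pd.DataFrame,
    traits: Sequence[str],
    strain: str = "strain",
    condition: str = "condition",
) -> CvTable:
    """Coefficient of variation (CV %) of replicates per strain x condition.

    CV % = 100 * sd / mean within each (strain, condition, trait) cell
    (sample sd, n-1).  Cells with zero mean get an undefined CV and a flag.
    """
    rows = []
    for (s, c), grp in data.groupby([strain, condition], sort=True):
        if len(grp) < 2:
            raise ValueError(f"strain {s!r} in condition {c!r} has < 2 replicates")
        for trait in traits:
            vals = grp[trait].to_numpy(dtype=float)
            m = float(vals.mean())
            sd = float(vals.std(ddof=1))
            undefined = m == 0
            rows.append({
                strain: s, condition: c, "trait": trait,
                "mean": m, "sd": sd,
                "cv_pct": np.nan if undefined else 100.0 * sd / abs(m),
                "flag": "UNDEFINED_CV" if undefined else "",
            })
    per_cell = pd.DataFrame(rows)
    per_condition = (
        per_cell.groupby([condition, "trait"], sort=True)["cv_pct"].mean().unstack("trait")
    )
    cumulated = per_condition.sum(axis=1)
    cumulated.name = "cumulated_cv_pct"
    return CvTable(per_cell=per_cell, per_condition=per_condition, cumulated=cumulated)
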