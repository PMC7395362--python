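"""Group-comparison tests and correlation matrices over sample covariates.

Covers the study's statistical repertoire: Wilcoxon rank-sum (Mann-Whitney
U) for grouped continuous measures, Welch t-test for mean differences,
chi-square for proportions, and all-pairs Pearson/Spearman correlation
matrices with significance flags at p < 0.05 (*) and p < 0.01 (**).
Missing data are handled by pairwise-complete deletion throughout; no
multiple-testing correction is applied to the correlation matrix by
default (raw p-values are flagged, with a Benjamini-Hochberg option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

__all__ = [
    "GroupComparison",
    "CorrelationMatrixResult",
    "compare_groups",
    "correlation_matrix",
    "composition_report",
]


@dataclass(frozen=True)
class GroupComparison:
    """One two-group comparison of a covariate, with descriptives and a p-value."""

    variable: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    median: tuple[float, float]
    sd: tuple[float, float]
    test: str  # "wilcoxon" | "t" | "chi-square"
    statistic: float
    p: float

    @property
    def fold_change(self) -> float:
        """Ratio of group means (first / second); nan when undefined."""
        return self.mean[0] / self.mean[1] if self.mean[1] != 0 else float("nan")


def compare_groups(
    cov: pd.DataFrame,
    grouping: str,
    variable: str,
    test: str = "wilcoxon",
) -> GroupComparison:
    """Two-sided two-group test of ``variable`` split by ``grouping``.

    ``test`` is one of ``wilcoxon`` (rank-sum), ``t`` (Welch), or
    ``chi-square`` (on a 2x2 contingency table of a binary variable).
    Records missing either column are dropped. Wilcoxon uses the exact
    null distribution when both groups are small and tie-free, otherwise
    the tie-corrected normal approximation.
    """
    sub = cov[[grouping, variable]].dropna()
    levels = list(pd.unique(sub[grouping]))
    if len(levels) != 2:
        raise ValidationError(f"{grouping!r} must have exactly 2 groups (got {levels})")
    a = sub.loc[sub[grouping] == levels[0], variable]
    b = sub.loc[sub[grouping] == levels[1], variable]
    min_n = 1 if test == "chi-square" else 2
    if len(a) < min_n or len(b) < min_n:
        raise ValidationError(f"group too small for {test}: n = ({len(a)}, {len(b)})")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "chi-square":
        table = pd.crosstab(sub[grouping], sub[variable])
        if table.shape[1] < 2:
            statistic, p = 0.0, 1.0  # no variation in the variable
        else:
            res = stats.chi2_contingency(table.to_numpy(), correction=False)
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    af, bf = a.astype(float), b.astype(float)
    return GroupComparison(
        variable=variable,
        groups=(str(levels[0]), str(levels[1])),
        n=(len(a), len(b)),
        mean=(float(af.mean()), float(bf.mean())),
        median=(float(af.median()), float(bf.median())),
        sd=(float(af.std(ddof=1)) if len(a) > 1 else float("nan"),
            float(bf.std(ddof=1)) if len(b) > 1 else float("nan")),
        test=test,
        statistic=statistic,
        p=p,
    )


@dataclass
class CorrelationMatrixResult:
    """All-pairs correlation with p-values and significance flags.

    ``r`` and ``p`` are symmetric DataFrames over the analysed variables;
    ``flags`` holds "" / "*" / "**" at p < 0.05 / p < 0.01. Constant
    variables yield NaN entries (flagged, never dropped silently).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame
    method: str


def correlation_matrix(
    data: pd.DataFrame,
    method: str = "pearson",
    min_pairs: int = 3,
    bh_correct: bool = False,
) -> CorrelationMatrixResult:
    """Pairwise-complete correlation matrix over the numeric columns of ``data``.

    ``method`` is ``pearson`` or ``spearman``; p-values come from the exact
    t distribution of the sample correlation under bivariate normality (the
    standard scipy reference distribution). With ``bh_correct=True`` the
    off-diagonal p-values are Benjamini-Hochberg adjusted before flagging.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    num = data.select_dtypes(include=[np.number])
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i, k):
            pair = num[[cols[i], cols[j]]].dropna() if i != j else num[[cols[i]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                r[i, i] = 1.0 if len(pair) else np.nan
                p[i, i] = 0.0 if len(pair) else np.nan
                continue
            if len(pair) < min_pairs:
                continue
            x, y = pair[cols[i]], pair[cols[j]]
            if x.nunique() == 1 or y.nunique() == 1:
                continue  # constant variable: undefined correlation, stays NaN
            res = corr_fn(x, y)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    p_frame = pd.DataFrame(p, index=cols, columns=cols)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(k, 1)
        raw = p[iu]
        ok = ~np.isnan(raw)
        adj = raw.copy()
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        p_adj = p.copy()
        p_adj[iu] = adj
        p_adj[(iu[1], iu[0])] = adj
        p_frame = pd.DataFrame(p_adj, index=cols, columns=cols)
    flags = p_frame.map(lambda v: "" if pd.isna(v) else ("**" if v < 0.01 else "*" if v < 0.05 else ""))
    np.fill_diagonal(flags.values, "")
    return CorrelationMatrixResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=p_frame,
        n=pd.DataFrame(n, index=cols, columns=cols),
        flags=flags,
        method=method,
    )


COMPARTMENTS = ("pct_adipocyte", "pct_stromal", "pct_epithelial")


def composition_report(
    cov: pd.DataFrame,
    labels: pd.Series | dict,
    plot_path: str | None = None,
) -> list[GroupComparison]:
    """Wilcoxon comparison of tissue composition between phenotype labels.

    ``labels`` maps sample_id -> phenotype. One comparison per compartment
    (% adipocyte, stromal, epithelial nuclei), Active listed first so the
    fold-change reads Active/Inactive. Optionally writes a box-plot figure.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    cov = cov.copy()
    cov["_label"] = cov["sample_id"].map(labels)
    cov = cov.dropna(subset=["_label"])
    found = set(cov["_label"])
    if len(found) < 2:
        raise ValidationError(f"composition_report needs both phenotype labels (got {sorted(found)})")
    # canonical ordering: Active first
    cov["_label"] = pd.Categorical(cov["_label"], categories=["Active", "Inactive"], ordered=True)
    cov = cov.sort_values("_label")
    out = [compare_groups(cov, "_label", c, test="wilcoxon") for c in COMPARTMENTS if c in cov.columns]
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(out), figsize=(4 * len(out), 4), squeeze=False)
        for ax, comp in zip(axes[0], out):
            groups = [
                cov.loc[cov["_label"] == g, comp.variable].dropna() for g in comp.groups
            ]
            ax.boxplot(groups, tick_labels=list(comp.groups))
            ax.set_title(f"{comp.variable}\nWilcoxon p = {comp.p:.2g}")
            ax.set_ylabel("% nuclei")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out
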