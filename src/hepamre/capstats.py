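"""Statistical layer linking metabolic capacities to imaging markers.

Covers the study's analysis path: row-wise z-normalisation of the capacity
matrix, agglomerative clustering into two metabolic groups, a qq-plot-based
normality gate steering unpaired two-sample comparisons (Student's t when
both groups look normal, Mann-Whitney rank-sum otherwise), Pearson/OLS
regression with 95% confidence bands, the stiff/soft split at SWS 1.6 m/s
and cohort descriptive summaries.  No multiple-testing correction is
applied; all reported p-values are raw two-sided values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "zscore_rows",
    "hier_cluster",
    "normality_check",
    "group_compare",
    "pearson_regression",
    "cluster_heatmap",
    "regression_plot",
    "split_by_cutoff",
    "summarize_cohort",
    "STIFFNESS_CUTOFF_M_S",
]

STIFFNESS_CUTOFF_M_S = 1.6


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    ci_lower: np.ndarray  # 95% CI band of the mean response, at sorted x
    ci_upper: np.ndarray
    x_grid: np.ndarray


def zscore_rows(matrix) -> pd.DataFrame:
    """Normalise each row (metabolic function) to mean 0, SD 1.

    Constant rows cannot be scaled; they map to all-zeros with a warning.
    Accepts an array or DataFrame of shape (functions, samples).
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise ValueError("row-wise normalisation needs at least 2 samples")
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    out = df.sub(means, axis=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) mapped to zeros during "
            "row-wise normalisation",
            stacklevel=2,
        )
    out.loc[~constant] = out.loc[~constant].div(sds[~constant], axis=0)
    out.loc[constant] = 0.0
    return out


def hier_cluster(matrix, k: int = 2):
    """Agglomerative clustering of samples (columns) into ``k`` groups.

    Euclidean distance, average linkage; the tree is cut at ``k`` clusters.
    Returns (labels, linkage_matrix); labels are 1-based in column order.
    """
    df = pd.DataFrame(matrix).astype(float)
    n = df.shape[1]
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    X = df.to_numpy().T  # samples x features
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def normality_check(values, band_z: float = 1.96) -> bool:
    """Quantile-quantile normality gate with pointwise 95% bands.

    Ordered values are compared with the normal quantiles at plotting
    positions (i - 0.375)/(n + 0.25); the reference line is the
    least-squares probability-plot line and the pointwise band uses the
    asymptotic standard error of order statistics,
    se_i = slope/phi(z_i) * sqrt(p_i (1-p_i)/n).  The sample is called
    normal iff at least 95% of points fall inside the band.  Deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("normality check needs at least 4 values")
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    z = stats.norm.ppf(p)
    slope, intercept = np.polyfit(z, x, 1)
    if slope <= 0:
        return False  # degenerate spread; cannot look normal
    fitted = intercept + slope * z
    se = slope / stats.norm.pdf(z) * np.sqrt(p * (1.0 - p) / n)
    inside = np.abs(x - fitted) <= band_z * se
    return bool(np.mean(inside) >= 0.95)


def group_compare(a, b) -> GroupComparison:
    """Unpaired two-sided comparison gated on the qq-normality check.

    Student's t-test when both groups pass the normality gate, otherwise the
    Mann-Whitney rank-sum test (the unpaired analogue of the signed-rank
    test, which is undefined for unequal independent groups).  Two identical
    constant groups are degenerate: p = 1 by convention, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    summary = dict(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return GroupComparison(
            **summary, test="t", statistic=0.0, p_value=1.0, degenerate=True
        )
    use_t = (
        a.size >= 4
        and b.size >= 4
        and normality_check(a)
        and normality_check(b)
    )
    if use_t:
        res = stats.ttest_ind(a, b)
        return GroupComparison(
            **summary,
            test="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        **summary,
        test="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def pearson_regression(x, y) -> CorrelationResult:
    """Pearson correlation plus an OLS line with 95% mean-response bands."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    grid = np.sort(x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=int(x.size),
        ci_lower=ci[:, 0],
        ci_upper=ci[:, 1],
        x_grid=grid,
    )


def split_by_cutoff(sws_values, cutoff: float = STIFFNESS_CUTOFF_M_S) -> np.ndarray:
    """Stiff/soft labels from SWS: >= cutoff is 'stiff', below is 'soft'.

    Boundary values go to the stiff group (the inclusive rule that
    reproduces the published 10/9 split of the cohort).
    """
    sws = np.asarray(sws_values, dtype=float)
    if np.any(sws[np.isfinite(sws)] <= 0):
        raise ValueError("SWS values must be positive")
    return np.where(sws >= cutoff, "stiff", "soft")


def cluster_heatmap(normalized, labels=None, path=None):
    """Heat map of a row-normalised capacity matrix, samples ordered by the
    clustering tree.  Returns the matplotlib figure; saves to ``path`` if
    given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(normalized).astype(float)
    _, Z = hier_cluster(df, k=min(2, df.shape[1]))
    order = hierarchy.leaves_list(Z)
    fig, ax = plt.subplots(figsize=(0.4 * df.shape[1] + 2, 0.3 * df.shape[0] + 2))
    im = ax.imshow(df.iloc[:, order], aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(np.asarray(df.columns)[order], rotation=90, fontsize=7)
    ax.set_yticks(range(df.shape[0]))
    ax.set_yticklabels(df.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def regression_plot(result: CorrelationResult, x, y, xlabel="x", ylabel="y", path=None):
    """Scatter with the fitted line and 95% mean-response bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, color="k", s=20)
    ax.plot(result.x_grid, result.intercept + result.slope * result.x_grid, "b-")
    ax.plot(result.x_grid, result.ci_lower, "r:", result.x_grid, result.ci_upper, "r:")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"r = {result.r:.2f}, p = {result.p_value:.3f} (n = {result.n})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def summarize_cohort(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Column-wise mean, sample SD, CoV and n, excluding missing entries.

    All-missing columns are omitted with a warning; columns with a single
    observation are likewise skipped (an SD needs n >= 2).
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = {}
    for col in columns:
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if len(vals) < 2:
            warnings.warn(
                f"column {col!r} has fewer than 2 observations; omitted",
                stacklevel=2,
            )
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows[col] = {
            "mean": mean,
            "sd": sd,
            "cov": sd / mean if mean != 0 else np.nan,
            "n": int(len(vals)),
        }
    return pd.DataFrame(rows).T
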