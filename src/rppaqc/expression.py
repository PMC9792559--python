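"""Downstream expression-profiling conventions for RPPA matrices.

Matrices are pandas DataFrames with antibodies as rows and samples as
columns (RNFI or log2 thereof).  The conventions implemented here: per-row
median centering across samples, unsupervised hierarchical clustering
(default 1 - Pearson distance, average linkage), PCA on samples, Pearson
correlation with r^2, paired/unpaired t, one-way ANOVA and Mann-Whitney group
comparisons, and the three-category (zero / low / high) binning used to
compare array signal with western-blot densitometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage as _linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import UndefinedCorrelationError, ValidationError

VALID_TESTS = ("paired_t", "unpaired_t", "anova", "mann_whitney")


@dataclass
class CorrelationResult:
    r: float
    r2: float
    n: int
    p_value: float


@dataclass
class ClusteringResult:
    """Row and column dendrograms with deterministic leaf orders."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    distance: str
    linkage_method: str

    def col_top_split(self, labels: list[str]) -> tuple[set[str], set[str]]:
        """The two column clusters produced by cutting the tree at the root."""
        assignment = fcluster(self.col_linkage, t=2, criterion="maxclust")
        a = {lab for lab, k in zip(labels, assignment) if k == 1}
        b = {lab for lab, k in zip(labels, assignment) if k == 2}
        return a, b


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each antibody row's median across samples (idempotent).

    Missing entries are left untouched; an all-missing row raises.
    """
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)][0]
        raise ValidationError(f"row {bad!r} has no observed values")
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def _check_zero_variance(values: np.ndarray, names, axis_name: str) -> None:
    ptp = values.max(axis=1) - values.min(axis=1)
    flat = np.flatnonzero(ptp == 0)
    if flat.size:
        raise ValidationError(
            f"zero-variance {axis_name} {names[flat[0]]!r} under correlation distance"
        )


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage_method: str = "average",
    impute_missing: bool = False,
) -> ClusteringResult:
    """Cluster rows and columns; deterministic given inputs and config.

    ``distance="correlation"`` is 1 - Pearson; any scipy pdist metric name is
    accepted.  Missing values abort unless ``impute_missing`` fills each
    missing cell with its row mean.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("need at least 2 rows and 2 columns to cluster")
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        if not impute_missing:
            raise ValidationError("matrix contains missing values; set impute_missing=True")
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_means, values)
    if distance == "correlation":
        _check_zero_variance(values, list(matrix.index), "row")
        _check_zero_variance(values.T, list(matrix.columns), "column")
    row_link = _linkage(pdist(values, metric=distance), method=linkage_method)
    col_link = _linkage(pdist(values.T, metric=distance), method=linkage_method)
    row_order = [matrix.index[i] for i in dendrogram(row_link, no_plot=True)["leaves"]]
    col_order = [matrix.columns[i] for i in dendrogram(col_link, no_plot=True)["leaves"]]
    return ClusteringResult(row_link, col_link, row_order, col_order, distance, linkage_method)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples (columns) on row-centered data, no variance scaling.

    Returns (scores, explained_variance_fractions).  Component signs follow a
    fixed convention — the loading with the largest magnitude is positive — so
    repeated runs are byte-identical.  ``n_components`` beyond the matrix rank
    is clipped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if matrix.isna().to_numpy().any():
        raise ValidationError("PCA input contains missing values")
    max_rank = min(matrix.shape[1], matrix.shape[0])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; clipped",
            stacklevel=2,
        )
        n_components = max_rank
    # samples are observations, antibodies features; PCA centers each feature,
    # i.e. row-centering of the matrix
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(float).T)
    # sign convention: largest-|loading| entry of each component is positive
    for k in range(scores.shape[1]):
        comp = pca.components_[k]
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[k] = -comp
            scores[:, k] = -scores[:, k]
    score_df = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    return score_df, pca.explained_variance_ratio_.copy()


def pearson_r2(x, y) -> CorrelationResult:
    """Pearson r, r^2 and the two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3 for correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, n=int(x.size), p_value=float(res.pvalue))


def group_compare(values, groups, test: str) -> tuple[float, float]:
    """Two-group or k-group comparison of one antibody's values.

    ``paired_t`` matches observations by position within each group (equal
    sizes required) and rejects zero-variance differences explicitly.
    Returns (statistic, two-sided p).
    """
    if test not in VALID_TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {VALID_TESTS}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs at least 2 observations")

    if test == "anova":
        stat, p = stats.f_oneway(*samples)
        return float(stat), float(p)
    if len(levels) != 2:
        raise ValidationError(f"{test} requires exactly 2 groups, got {len(levels)}")
    a, b = samples
    if test == "paired_t":
        if len(a) != len(b):
            raise ValidationError("paired_t requires equal group sizes in matched order")
        diff = a - b
        if np.ptp(diff) == 0:
            raise ValidationError("zero variance of paired differences; t undefined")
        stat, p = stats.ttest_rel(a, b)
    elif test == "unpaired_t":
        stat, p = stats.ttest_ind(a, b)
    else:  # mann_whitney
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def group_compare_frame(matrix: pd.DataFrame, groups, test: str) -> pd.DataFrame:
    """Apply :func:`group_compare` to every row of a matrix."""
    groups = np.asarray(groups)
    rows = []
    for antibody_id, row in matrix.iterrows():
        stat, p = group_compare(row.to_numpy(float), groups, test)
        rows.append({"antibody_id": antibody_id, "test": test, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def three_category_binning(intensities) -> list[str]:
    """Bin western-blot intensities into {zero, low, high}.

    Exact zeros form their own category; the remaining values are split at
    their median (values <= median are low) so the nonzero mass is divided
    evenly.  Scale-invariant by construction.  All-zero input warns and
    returns a single category.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 3:
        raise ValidationError("need n >= 3 intensities")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("intensities must be finite and non-negative")
    nonzero = x[x > 0]
    if nonzero.size == 0:
        warnings.warn("all intensities are zero; single category", stacklevel=2)
        return ["zero"] * x.size
    med = float(np.median(nonzero))
    out = []
    for v in x:
        if v == 0:
            out.append("zero")
        elif v <= med:
            out.append("low")
        else:
            out.append("high")
    return out
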