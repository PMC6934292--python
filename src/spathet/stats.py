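"""Group comparisons, replicate correlation, and the multimodal
low/medium/high discretization with hierarchical integration.

Comparisons operate on per-subject summaries (one value per patient), never
per-cell values.  Cell-level and heterogeneity p-values are reported without
multiple-testing adjustment; a Benjamini–Hochberg FDR helper is available for
feature panels where adjustment is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

#: largest per-group n at which the Mann-Whitney p-value is computed by exact
#: enumeration (ties force the normal approximation regardless)
EXACT_MANN_WHITNEY_MAX_N = 20

LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group test on per-subject values."""

    feature: str
    groups: tuple[str, str]
    n: tuple[int, int]
    test: str
    statistic: float
    pvalue: float
    adjusted: bool = False


def _split_two_groups(values, labels) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = tuple(pd.unique(labels))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {names}")
    return values[labels == names[0]], values[labels == names[1]], (str(names[0]), str(names[1]))


def compare_means(
    values: Sequence[float],
    labels: Sequence[str],
    feature: str = "",
    welch: bool = False,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Unpaired Student's t-test (pooled variance by default; Welch by flag).

    Inputs are per-subject scalars, e.g. mean marker expression per patient.
    """
    a, b, names = _split_two_groups(values, labels)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects for a t-test")
    if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return GroupComparison(
        feature=feature,
        groups=names,
        n=(len(a), len(b)),
        test="welch_t" if welch else "student_t",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def compare_ranks(
    values: Sequence[float],
    labels: Sequence[str],
    feature: str = "",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Mann-Whitney U test on per-subject values.

    Policy: the exact null distribution is enumerated when both groups have
    at most ``EXACT_MANN_WHITNEY_MAX_N`` subjects and the data are tie-free;
    otherwise the normal approximation with continuity correction is used.
    """
    a, b, names = _split_two_groups(values, labels)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least 1 subject")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = (
        "exact"
        if no_ties and max(len(a), len(b)) <= EXACT_MANN_WHITNEY_MAX_N
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        feature=feature,
        groups=names,
        n=(len(a), len(b)),
        test=f"mann_whitney_{method}",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def replicate_correlation(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Pearson correlation between paired replicate measurements (e.g. the
    same field quantified on two slides)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the replicate vectors")
    return float(sps.pearsonr(a, b).statistic)


def apply_fdr(comparisons: Sequence[GroupComparison]) -> list[GroupComparison]:
    """Benjamini–Hochberg adjustment across a set of comparisons."""
    adj = sps.false_discovery_control([c.pvalue for c in comparisons], method="bh")
    return [replace(c, pvalue=float(p), adjusted=True) for c, p in zip(comparisons, adj)]


# ---------------------------------------------------------------------------
# multimodal discretization + hierarchical integration

@dataclass
class DiscretizedFeatureMatrix:
    """Subject × feature matrix of ordinal bins with per-feature rule descriptors.

    ``labels`` holds "low"/"medium"/"high" strings; ``codes`` the ordinal
    coding 0/1/2.  Constant features are assigned "medium" and flagged.
    """

    labels: pd.DataFrame
    codes: pd.DataFrame
    rules: dict[str, str]
    constant_features: tuple[str, ...] = ()


def discretize_features(
    table: pd.DataFrame, rule: str = "range-thirds"
) -> DiscretizedFeatureMatrix:
    """Discretize numeric per-subject features into low/medium/high bins.

    ``rule="range-thirds"`` (default) uses three equal-width bins spanning
    [min, max] with half-open upper boundaries and the maximum assigned to
    "high"; ``rule="tertiles"`` bins at the 33rd/67th quantiles with the same
    upper-half-open convention used for marker levels.
    """
    if rule not in ("range-thirds", "tertiles"):
        raise ValueError(f"unknown rule {rule!r}")
    codes = pd.DataFrame(index=table.index)
    rules: dict[str, str] = {}
    constant: list[str] = []
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in feature {col!r}")
        lo, hi = v.min(), v.max()
        if lo == hi:
            codes[col] = 1
            constant.append(col)
            rules[col] = f"{rule} (constant feature; assigned medium)"
            continue
        if rule == "range-thirds":
            e1 = lo + (hi - lo) / 3
            e2 = lo + 2 * (hi - lo) / 3
            codes[col] = (v >= e1).astype(int) + (v >= e2).astype(int)
            rules[col] = f"range-thirds over [{lo:g}, {hi:g}]"
        else:
            q33, q67 = np.quantile(v, [0.33, 0.67])
            codes[col] = (v > q33).astype(int) + (v > q67).astype(int)
            rules[col] = f"tertiles (q33={q33:g}, q67={q67:g})"
    labels = codes.apply(lambda c: pd.Categorical.from_codes(c, LEVELS))
    labels.index = table.index
    return DiscretizedFeatureMatrix(labels, codes, rules, tuple(constant))


@dataclass
class IntegrationResult:
    """Hierarchical clustering of subjects over discretized features."""

    subject_order: tuple[str, ...]
    linkage: np.ndarray
    linkage_method: str
    newick: str


def _to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def integrate_and_cluster(
    matrix: DiscretizedFeatureMatrix, linkage_method: str = "average"
) -> IntegrationResult:
    """Agglomerative clustering of subjects on Euclidean distances of their
    ordinal (0/1/2) feature vectors; exports the leaf order and merge tree."""
    X = matrix.codes.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 subjects to cluster")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage_method)
    order = hierarchy.leaves_list(Z)
    names = [str(s) for s in matrix.codes.index]
    return IntegrationResult(
        subject_order=tuple(names[i] for i in order),
        linkage=Z,
        linkage_method=linkage_method,
        newick=_to_newick(Z, names),
    )


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparison results into a delimited-table-friendly frame."""
    return pd.DataFrame(
        {
            "feature": [c.feature for c in comparisons],
            "group_a": [c.groups[0] for c in comparisons],
            "group_b": [c.groups[1] for c in comparisons],
            "n_a": [c.n[0] for c in comparisons],
            "n_b": [c.n[1] for c in comparisons],
            "test": [c.test for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "pvalue": [c.pvalue for c in comparisons],
            "adjusted": [c.adjusted for c in comparisons],
        }
    )
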