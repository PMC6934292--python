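"""Cell-phenotype clustering: preprocessing, K-means scan, consensus clustering,
cluster-number selection, lollipop profiles and per-sample compositions.

The workflow mirrors standard multiplexed-imaging practice: log2 intensities
are winsorized at the 2.5%/97.5% tails per marker, z-standardized by the
overall marker mean and standard deviation, and clustered with K-means over a
range of K with multiple random starts.  The cluster number is judged from
silhouette width, the Calinski–Harabasz criterion, the within-cluster sum of
squares, and resampling-based consensus clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

logger = logging.getLogger("spathet")


# ---------------------------------------------------------------------------
# preprocessing

@dataclass
class PreprocessModel:
    """Per-marker winsorization bounds and standardization statistics.

    ``mode`` is "winsorize" (values outside the 2.5th/97.5th percentile are
    clipped to the bound; the cell set is preserved) or "trim_cells" (cells
    with any out-of-bounds marker are removed).  Standardization statistics
    are computed after trimming.  Zero-variance markers are flagged in
    ``dropped`` and excluded from the output space.
    """

    markers: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    mode: str = "winsorize"
    dropped: tuple[str, ...] = ()


def fit_preprocess(
    values: np.ndarray | pd.DataFrame,
    markers: Sequence[str] | None = None,
    mode: str = "winsorize",
    tail: float = 0.025,
) -> PreprocessModel:
    """Fit trim bounds (``tail``/1-``tail`` percentiles) and z-statistics.

    ``values`` are log2-transformed intensities, cells × markers.
    """
    if mode not in ("winsorize", "trim_cells"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(values, pd.DataFrame):
        markers = tuple(values.columns) if markers is None else tuple(markers)
        values = values.to_numpy(dtype=float)
    elif markers is None:
        markers = tuple(f"m{j}" for j in range(values.shape[1]))
    else:
        markers = tuple(markers)

    lower = np.quantile(values, tail, axis=0)
    upper = np.quantile(values, 1 - tail, axis=0)
    if mode == "winsorize":
        trimmed = np.clip(values, lower, upper)
    else:
        keep = ((values >= lower) & (values <= upper)).all(axis=1)
        trimmed = values[keep]
    mean = trimmed.mean(axis=0)
    sd = trimmed.std(axis=0, ddof=0)
    dropped = tuple(np.asarray(markers)[sd == 0])
    if dropped:
        logger.warning("zero-variance markers excluded from clustering: %s", dropped)
    return PreprocessModel(markers, lower, upper, mean, sd, mode, dropped)


def apply_preprocess(
    model: PreprocessModel, values: np.ndarray | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Winsorize/trim then standardize; returns (matrix, retained-row mask)."""
    if isinstance(values, pd.DataFrame):
        values = values[list(model.markers)].to_numpy(dtype=float)
    keep_rows = np.ones(len(values), dtype=bool)
    if model.mode == "winsorize":
        trimmed = np.clip(values, model.lower, model.upper)
    else:
        keep_rows = ((values >= model.lower) & (values <= model.upper)).all(axis=1)
        trimmed = values[keep_rows]
    keep_cols = model.sd > 0
    z = (trimmed[:, keep_cols] - model.mean[keep_cols]) / model.sd[keep_cols]
    return z, keep_rows


def retained_markers(model: PreprocessModel) -> tuple[str, ...]:
    return tuple(m for m in model.markers if m not in model.dropped)


# ---------------------------------------------------------------------------
# K-means scan

@dataclass
class ClusterModel:
    """Best-of-``n_starts`` K-means solution at one K, with selection metrics.

    Cluster labels are 1-based (1..K) and every cluster is nonempty.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    sse: float
    silhouette: float
    calinski: float
    n_starts: int
    seed: int | None


def kmeans_scan(
    data: np.ndarray,
    k_range: Sequence[int] = range(2, 16),
    n_starts: int = 10,
    seed: int | None = None,
    silhouette_max_cells: int = 10_000,
) -> list[ClusterModel]:
    """K-means at every K in ``k_range`` with ``n_starts`` random starts each.

    The solution with the lowest within-cluster sum of squares over the
    starts is kept per K.  Silhouette width is computed on a random subsample
    when the data exceed ``silhouette_max_cells`` (its pairwise-distance cost
    is quadratic).  Deterministic given seed.
    """
    data = np.asarray(data, dtype=float)
    n = len(data)
    ks = list(k_range)
    models = []
    root = np.random.SeedSequence(seed)
    for k, ss in zip(ks, root.spawn(len(ks))):
        if k > n:
            raise ValueError(f"K={k} exceeds the number of cells ({n})")
        state = int(ss.generate_state(1)[0] % (2**31))
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=state).fit(data)
        labels = km.labels_
        sil_kwargs = {}
        if n > silhouette_max_cells:
            sil_kwargs = {"sample_size": silhouette_max_cells, "random_state": state}
        models.append(
            ClusterModel(
                k=k,
                centroids=km.cluster_centers_,
                labels=labels + 1,
                sse=float(km.inertia_),
                silhouette=float(silhouette_score(data, labels, **sil_kwargs)),
                calinski=float(calinski_harabasz_score(data, labels)),
                n_starts=n_starts,
                seed=seed,
            )
        )
    return models


# ---------------------------------------------------------------------------
# consensus clustering

@dataclass
class ConsensusResult:
    """Pairwise co-clustering frequencies over resampled K-means runs.

    ``consensus[i, j]`` = (# iterations where i, j co-clustered) /
    (# iterations where both were sampled); NaN for pairs never co-sampled.
    The matrix is symmetric with unit diagonal wherever defined.
    """

    k: int
    consensus: np.ndarray
    subsample_index: np.ndarray
    n_iterations: int
    resample_fraction: float

    def values(self) -> np.ndarray:
        """Finite off-diagonal consensus entries (upper triangle)."""
        iu = np.triu_indices(len(self.consensus), k=1)
        v = self.consensus[iu]
        return v[np.isfinite(v)]

    def cdf(self, bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of consensus values on a fixed grid over [0, 1]."""
        v = np.sort(self.values())
        x = np.linspace(0, 1, bins + 1)
        return x, np.searchsorted(v, x, side="right") / len(v)

    def cdf_area(self) -> float:
        """Area under the consensus CDF (larger = more mass at low consensus)."""
        x, f = self.cdf()
        return float(np.trapezoid(f, x))

    def sharpness(self) -> float:
        """Fraction of consensus entries near 0 or 1 (<= 0.1 or >= 0.9)."""
        v = self.values()
        return float(((v <= 0.1) | (v >= 0.9)).mean())


def consensus_cluster(
    data: np.ndarray,
    k_range: Sequence[int],
    subsample_cells: int = 5000,
    n_iterations: int = 1000,
    resample_fraction: float = 0.8,
    seed: int | None = None,
    n_starts: int = 1,
) -> list[ConsensusResult]:
    """Resampling-based consensus clustering over ``k_range``.

    At most ``subsample_cells`` cells are drawn once (without replacement);
    each iteration then samples ``resample_fraction`` of them without
    replacement, runs K-means (``n_starts`` restarts, single by default),
    and co-clustering/co-sampling counts are accumulated.  Pairs never
    co-sampled stay missing (NaN), not zero.
    """
    if not 0 < resample_fraction <= 1:
        raise ValueError("resample_fraction must be in (0, 1]")
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(data)
    if n > subsample_cells:
        sub_idx = np.sort(rng.choice(n, size=subsample_cells, replace=False))
    else:
        sub_idx = np.arange(n)
    X = data[sub_idx]
    m = len(X)
    per_iter = max(2, round(resample_fraction * m))

    results = []
    for k in k_range:
        co_cluster = np.zeros((m, m), dtype=np.float32)
        co_sample = np.zeros((m, m), dtype=np.float32)
        for _ in range(n_iterations):
            idx = rng.choice(m, size=per_iter, replace=False)
            state = int(rng.integers(2**31))
            labels = KMeans(n_clusters=k, n_init=n_starts, random_state=state).fit_predict(X[idx])
            same = labels[:, None] == labels[None, :]
            block = np.ix_(idx, idx)
            co_cluster[block] += same
            co_sample[block] += 1.0
        with np.errstate(invalid="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / co_sample, np.nan)
        results.append(
            ConsensusResult(
                k=k,
                consensus=consensus,
                subsample_index=sub_idx,
                n_iterations=n_iterations,
                resample_fraction=resample_fraction,
            )
        )
    return results


# ---------------------------------------------------------------------------
# cluster-number selection

@dataclass
class KSelectionReport:
    """Per-K metric table, recommended K, and any reliability flags."""

    table: pd.DataFrame
    recommended_k: int
    flags: tuple[str, ...]
    rule: str


def choose_k(
    models: Sequence[ClusterModel],
    consensus: Sequence[ConsensusResult] | None = None,
    sharpness_tolerance: float = 0.01,
    silhouette_floor: float = 0.25,
) -> KSelectionReport:
    """Rank the scanned Ks and recommend one by an explicit rule.

    Rule: among the Ks whose consensus sharpness (fraction of pair consensus
    values <= 0.1 or >= 0.9) is within ``sharpness_tolerance`` of the best,
    the one with the highest silhouette.  At a stable cluster number pairs
    co-cluster near-deterministically, so sharpness peaks at the supported K;
    the silhouette tie-break resolves plateaus (merging two clean clusters
    can be as deterministic as not merging them).  Without consensus results
    the silhouette maximum is used.  Flags: "criteria_disagree" when the
    silhouette optimum differs from the recommendation, "unreliable" when no
    K reaches ``silhouette_floor``.  The per-K table also reports the
    consensus CDF area and its relative gain for plotting.
    """
    table = pd.DataFrame(
        {
            "k": [m.k for m in models],
            "sse": [m.sse for m in models],
            "silhouette": [m.silhouette for m in models],
            "calinski": [m.calinski for m in models],
        }
    ).set_index("k")
    flags: list[str] = []

    if consensus:
        areas = pd.Series({c.k: c.cdf_area() for c in consensus}).sort_index()
        gains = areas.diff() / areas.shift()
        sharp = pd.Series({c.k: c.sharpness() for c in consensus}).sort_index()
        table = table.join(areas.rename("consensus_cdf_area"))
        table = table.join(gains.rename("consensus_area_gain"))
        table = table.join(sharp.rename("consensus_sharpness"))
        near = sharp.index[sharp >= sharp.max() - sharpness_tolerance]
        rec = table.loc[near, "silhouette"].idxmax()
        rule = (
            f"max consensus sharpness (tolerance {sharpness_tolerance}), "
            "tie-broken by silhouette"
        )
    else:
        rec = table["silhouette"].idxmax()
        rule = "silhouette maximum (no consensus results supplied)"

    sil_best = table["silhouette"].idxmax()
    if sil_best != rec:
        flags.append("criteria_disagree")
    if table["silhouette"].max() < silhouette_floor:
        flags.append("unreliable")
    return KSelectionReport(table.reset_index(), int(rec), tuple(flags), rule)


# ---------------------------------------------------------------------------
# profiles and compositions

@dataclass
class ClusterProfile:
    """Per-cluster lollipop values (mean deviation from the population mean)
    and the percentage of cells in each cluster."""

    deviations: pd.DataFrame  # index: cluster; columns: markers
    percentages: pd.Series  # index: cluster; sums to 100


def cluster_profiles(
    model: ClusterModel, data: np.ndarray, markers: Sequence[str] | None = None
) -> ClusterProfile:
    """Per-cluster per-marker mean minus the population mean, in the analysis space.

    The size-weighted deviations sum to zero per marker by construction.
    """
    data = np.asarray(data, dtype=float)
    if markers is None:
        markers = [f"m{j}" for j in range(data.shape[1])]
    pop_mean = data.mean(axis=0)
    clusters = np.arange(1, model.k + 1)
    dev = pd.DataFrame(
        [data[model.labels == c].mean(axis=0) - pop_mean for c in clusters],
        index=pd.Index(clusters, name="cluster"),
        columns=list(markers),
    )
    pct = pd.Series(
        [100.0 * (model.labels == c).mean() for c in clusters],
        index=pd.Index(clusters, name="cluster"),
        name="percent_cells",
    )
    return ClusterProfile(dev, pct)


def sample_composition(model: ClusterModel, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Per-sample fraction of cells in each cluster; rows sum to one."""
    sample_ids = np.asarray(sample_ids)
    if len(sample_ids) != len(model.labels):
        raise ValueError("sample_ids and cluster assignments differ in length")
    df = pd.DataFrame({"sample_id": sample_ids, "cluster": model.labels})
    comp = (
        df.groupby("sample_id", sort=False)["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    return comp.reindex(columns=np.arange(1, model.k + 1), fill_value=0.0)


# ---------------------------------------------------------------------------
# figures

def plot_lollipop(profile: ClusterProfile, path: str | None = None):
    """Lollipop plot: one panel per cluster, markers on the y axis, deviation
    from the population mean on the x axis."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    clusters = profile.deviations.index
    fig, axes = plt.subplots(
        1, len(clusters), figsize=(2.2 * len(clusters), 0.35 * profile.deviations.shape[1] + 1.2),
        sharey=True, squeeze=False,
    )
    ypos = np.arange(profile.deviations.shape[1])
    for ax, c in zip(axes[0], clusters):
        vals = profile.deviations.loc[c].to_numpy()
        ax.hlines(ypos, 0, vals, color="tab:gray", lw=1)
        ax.plot(vals, ypos, "o", ms=4, color="tab:blue")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_title(f"cluster {c}\n{profile.percentages[c]:.1f}%", fontsize=9)
    axes[0][0].set_yticks(ypos, profile.deviations.columns)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_consensus_cdf(results: Sequence[ConsensusResult], path: str | None = None):
    """Consensus-value CDFs, one curve per K."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for r in results:
        x, f = r.cdf()
        ax.plot(x, f, label=f"K={r.k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
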