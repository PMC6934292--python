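"""Cell neighbor graphs and the two normalized Shannon-entropy heterogeneity metrics.

Molecular heterogeneity of a sample is the Shannon entropy of its molecular
state frequencies normalized by ln(Nm), where Nm is the size of the hallmark's
state space.  Spatial heterogeneity is the entropy of the "spatial state"
distribution — per cell, the number of adjacent neighbors sharing its exact
molecular state — normalized by ln(Z_max + 1), where Z_max is the maximum
neighbor count observed in the sample.  Both metrics lie in [0, 1]: zero for
a sample concentrated in one state, one for a uniform state distribution.

Cells are approximated as circles of radius sqrt(area / pi); two cells are
neighbors when the distance between their centroids is strictly less than
1.3 times the sum of their radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CellTable, HallmarkSet
from .states import MolecularStateAssignment, QuantizationModel, encode_states

DEFAULT_CONTACT_FACTOR = 1.3


@dataclass
class NeighborGraph:
    """Symmetric cell-contact graph for one tissue sample.

    ``edges`` is an (E, 2) array of cell indices with i < j per row; the
    graph has no self-loops.  ``z_max`` — the maximum degree — is the size
    parameter of the spatial-state distribution.
    """

    cell_ids: np.ndarray
    radii: np.ndarray
    contact_factor: float
    edges: np.ndarray
    _degrees: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            d = np.zeros(self.n_cells, dtype=np.int64)
            if len(self.edges):
                d += np.bincount(self.edges[:, 0], minlength=self.n_cells)
                d += np.bincount(self.edges[:, 1], minlength=self.n_cells)
            self._degrees = d
        return self._degrees

    @property
    def z_max(self) -> int:
        return int(self.degrees.max()) if self.n_cells else 0

    def neighbors(self, i: int) -> np.ndarray:
        if not len(self.edges):
            return np.empty(0, dtype=np.int64)
        out = np.concatenate(
            [self.edges[self.edges[:, 0] == i, 1], self.edges[self.edges[:, 1] == i, 0]]
        )
        return np.sort(out)


def build_neighbor_graph(
    table: CellTable, contact_factor: float = DEFAULT_CONTACT_FACTOR
) -> NeighborGraph:
    """Build the contact graph of one sample.

    Edge rule: dist(center_i, center_j) < contact_factor * (r_i + r_j),
    strict inequality, with r = sqrt(area / pi).  Candidate pairs come from a
    k-d tree queried at the largest possible contact distance and are then
    filtered by the exact pairwise rule, so the result is identical to an
    all-pairs computation at any n.
    """
    if len(table.sample_ids) > 1:
        raise ValueError("neighbor graphs are built per sample; split the table first")
    xy = table.df[["x", "y"]].to_numpy(dtype=float)
    area = table.df["area"].to_numpy(dtype=float)
    if (area <= 0).any():
        raise ValueError("all areas must be positive")
    radii = np.sqrt(area / np.pi)

    n = len(xy)
    if n < 2:
        edges = np.empty((0, 2), dtype=np.int64)
    else:
        tree = cKDTree(xy)
        cand = tree.query_pairs(r=contact_factor * 2.0 * radii.max(), output_type="ndarray")
        if len(cand):
            d = np.linalg.norm(xy[cand[:, 0]] - xy[cand[:, 1]], axis=1)
            keep = d < contact_factor * (radii[cand[:, 0]] + radii[cand[:, 1]])
            edges = cand[keep].astype(np.int64)
        else:
            edges = np.empty((0, 2), dtype=np.int64)
    return NeighborGraph(
        cell_ids=table.df["cell_id"].to_numpy(),
        radii=radii,
        contact_factor=contact_factor,
        edges=edges,
    )


def _normalized_entropy(counts: np.ndarray, n_possible: int) -> float:
    """Shannon entropy of a count vector in nats, normalized by ln(n_possible)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum() / np.log(n_possible))
    return h if h != 0 else 0.0


def molecular_heterogeneity(states: MolecularStateAssignment) -> float:
    """Normalized Shannon entropy of the molecular-state frequency distribution.

    Returns -sum_i Pm_i ln(Pm_i) / ln(Nm), with the sum over observed states
    only (0·ln 0 := 0).  Zero when every cell shares one state; one when the
    cells are spread uniformly over all Nm states.
    """
    if len(states) == 0:
        raise ValueError("no cells in state assignment")
    _, counts = np.unique(states.codes, return_counts=True)
    return _normalized_entropy(counts, states.n_states)


def spatial_states(graph: NeighborGraph, states: MolecularStateAssignment) -> np.ndarray:
    """Per-cell count of neighbors sharing the cell's exact molecular state.

    Zero (no same-state neighbor, including isolated cells) is a valid
    spatial state and is retained.
    """
    if graph.n_cells != len(states) or not np.array_equal(graph.cell_ids, states.cell_ids):
        raise ValueError("graph and state assignment cover different cells")
    counts = np.zeros(graph.n_cells, dtype=np.int64)
    if len(graph.edges):
        same = states.codes[graph.edges[:, 0]] == states.codes[graph.edges[:, 1]]
        e = graph.edges[same]
        np.add.at(counts, e[:, 0], 1)
        np.add.at(counts, e[:, 1], 1)
    return counts


def spatial_heterogeneity(spatial_state_counts: np.ndarray, z_max: int) -> float:
    """Normalized Shannon entropy of the spatial-state distribution.

    Ps_k is the fraction of cells with spatial state k for k = 0..Z_max and
    the entropy is normalized by ln(Z_max + 1).  When Z_max = 0 every cell is
    isolated, only one spatial state exists, and the metric is defined as 0.
    """
    counts = np.asarray(spatial_state_counts)
    if len(counts) == 0:
        raise ValueError("no cells")
    if counts.max(initial=0) > z_max:
        raise ValueError("spatial state exceeds z_max")
    if z_max == 0:
        return 0.0
    freq = np.bincount(counts, minlength=z_max + 1)
    return _normalized_entropy(freq, z_max + 1)


def heterogeneity_report(
    tables: Iterable[CellTable] | CellTable,
    hallmarks: Sequence[HallmarkSet],
    model: QuantizationModel,
    contact_factor: float = DEFAULT_CONTACT_FACTOR,
) -> pd.DataFrame:
    """Both heterogeneity metrics for every sample × hallmark.

    ``tables`` may be a single multi-sample table or an iterable of tables;
    each is split by sample, the neighbor graph is built once per sample, and
    the metrics are computed per hallmark.  Quality filtering is assumed to
    have been applied already.
    """
    if isinstance(tables, CellTable):
        tables = [tables]
    rows = []
    for table in tables:
        for sid, sub in table.split_by_sample().items():
            graph = build_neighbor_graph(sub, contact_factor)
            z_max = graph.z_max
            for hm in hallmarks:
                assignment = encode_states(sub, model, hm)
                ss = spatial_states(graph, assignment)
                rows.append(
                    {
                        "sample_id": sid,
                        "hallmark": hm.name,
                        "n_cells": len(sub),
                        "n_states": assignment.n_states,
                        "z_max": z_max,
                        "molecular_heterogeneity": molecular_heterogeneity(assignment),
                        "spatial_heterogeneity": spatial_heterogeneity(ss, z_max),
                    }
                )
    return pd.DataFrame(rows)


def pool_by_patient(report: pd.DataFrame, patient_of_sample: Mapping[str, str]) -> pd.DataFrame:
    """Mean-pool per-sample metrics to one row per patient × hallmark.

    Useful when several tissue cores per patient were measured; per-core
    values remain available in the unpooled report.
    """
    df = report.copy()
    df["patient_id"] = df["sample_id"].map(dict(patient_of_sample))
    if df["patient_id"].isna().any():
        missing = df.loc[df["patient_id"].isna(), "sample_id"].unique()
        raise KeyError(f"samples without a patient mapping: {list(missing)}")
    return (
        df.groupby(["patient_id", "hallmark"], sort=False)[
            ["molecular_heterogeneity", "spatial_heterogeneity"]
        ]
        .mean()
        .reset_index()
    )


def plot_heterogeneity(
    report: pd.DataFrame,
    hallmark: str,
    group_of_sample: Mapping[str, str] | None = None,
    path: str | None = None,
):
    """Scatter of molecular vs spatial heterogeneity, optionally colored by group."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = report[report["hallmark"] == hallmark]
    fig, ax = plt.subplots(figsize=(5, 4))
    if group_of_sample is None:
        ax.scatter(sub["molecular_heterogeneity"], sub["spatial_heterogeneity"], s=25)
    else:
        groups = sub["sample_id"].map(dict(group_of_sample))
        for g in pd.unique(groups):
            m = groups == g
            ax.scatter(
                sub.loc[m, "molecular_heterogeneity"],
                sub.loc[m, "spatial_heterogeneity"],
                s=25, label=str(g),
            )
        ax.legend(frameon=False)
    ax.set_xlabel("molecular heterogeneity")
    ax.set_ylabel("spatial heterogeneity")
    ax.set_title(hallmark)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
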