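"""Synthetic spatial cell cohorts with known latent phenotype structure.

The generator emulates the per-cell tables produced by a multiplexed
immunofluorescence segmentation workflow: each sample is a planar point
pattern of cells with areas, a registration quality score, and log-normal
marker intensities driven by a latent cell phenotype.  Spatial aggregation of
like-phenotype cells is controlled by seeded nearest-phenotype assignment:
``n_spatial_seeds`` seed points each carry a phenotype, and a cell adopts its
nearest seed's phenotype with probability 1 - scatter_prob, otherwise a
uniformly random phenotype.  scatter_prob = 0 gives contiguous single-
phenotype territories; scatter_prob = 1 gives a well-mixed tissue.

Two subject groups with different phenotype counts and aggregation levels
mirror the IDH-mutant-like vs wildtype-like contrast: fewer phenotypes and
strong aggregation in one group, more phenotypes and weak aggregation in the
other.  The latent phenotype is recorded in an auxiliary ``true_phenotype``
column that every analysis operation ignores; it exists only as ground truth
for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .io import CellTable, HallmarkSet, MarkerPanel

#: default marker panel: two cancer-hallmark sets commonly assayed together —
#: proliferation (3 markers, 27 states) and angiogenesis (4 markers, 81 states)
DEFAULT_HALLMARKS: dict[str, tuple[str, ...]] = {
    "proliferation": ("EGFR", "Ki67", "Nestin"),
    "angiogenesis": ("SMA", "VEGFR2", "CD31", "S100A4"),
}


def default_marker_panel() -> MarkerPanel:
    rows = []
    for hallmark, markers in DEFAULT_HALLMARKS.items():
        for m in markers:
            rows.append({"marker": m, "hallmarks": (hallmark,), "compartment": "cell"})
    return MarkerPanel(pd.DataFrame(rows))


def default_hallmark_sets() -> tuple[HallmarkSet, ...]:
    return tuple(HallmarkSet(n, ms) for n, ms in DEFAULT_HALLMARKS.items())


@dataclass(frozen=True)
class GroupSpec:
    """Phenotype list and spatial mixing level for one subject group."""

    phenotypes: tuple[str, ...]
    scatter_prob: float

    def __post_init__(self) -> None:
        if not 0 <= self.scatter_prob <= 1:
            raise ValueError("scatter_prob must be in [0, 1]")
        if len(self.phenotypes) < 1:
            raise ValueError("a group needs at least one phenotype")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Intensities for a cell of phenotype p are 2**N(mu_pm, marker_log_sd) for
    marker m, i.e. log-normal around a phenotype-specific log2-scale mean —
    matching the log2 scale on which downstream clustering operates.  Cell
    radii are truncated-normal (r > 0) and areas are pi * r^2.
    """

    groups: dict[str, GroupSpec]
    phenotype_marker_means: dict[str, dict[str, float]]
    n_subjects_per_group: int = 10
    cells_per_sample: int = 2000
    field_width: float = 1000.0
    field_height: float = 1000.0
    marker_log_sd: float = 1.0
    cell_radius_mean: float = 5.0
    cell_radius_sd: float = 1.5
    n_spatial_seeds: int = 10
    quality_score_range: tuple[float, float] = (0.7, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects_per_group, self.cells_per_sample, self.n_spatial_seeds,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.marker_log_sd <= 0:
            raise ValueError("marker_log_sd must be positive")
        lo, hi = self.quality_score_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("quality_score_range must be an interval within [0, 1]")
        markers = self.markers
        for g in self.groups.values():
            for p in g.phenotypes:
                if p not in self.phenotype_marker_means:
                    raise ValueError(f"phenotype {p!r} has no marker means")
                missing = [m for m in markers if m not in self.phenotype_marker_means[p]]
                if missing:
                    raise ValueError(f"phenotype {p!r} lacks means for markers {missing}")

    @property
    def markers(self) -> tuple[str, ...]:
        first = next(iter(self.phenotype_marker_means.values()))
        return tuple(first)


def make_phenotype_means(
    phenotypes: Sequence[str],
    markers: Sequence[str],
    separation: float,
    marker_log_sd: float,
    seed: int,
    base_level: float = 8.0,
) -> dict[str, dict[str, float]]:
    """Draw per-phenotype log2-scale marker means with a guaranteed separation.

    Means are N(base_level, (separation * marker_log_sd)^2) per marker;
    phenotype mean vectors are redrawn until every pairwise Euclidean
    distance is at least separation * marker_log_sd * sqrt(n_markers), so
    phenotypes are separated by about ``separation`` within-phenotype
    standard deviations per marker.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    m = len(markers)
    min_dist = separation * marker_log_sd * np.sqrt(m)
    scale = separation * marker_log_sd
    vecs = np.empty((len(phenotypes), m))
    for i in range(len(phenotypes)):
        for _ in range(10_000):
            v = rng.normal(base_level, scale, size=m)
            if i == 0 or np.linalg.norm(vecs[:i] - v, axis=1).min() >= min_dist:
                vecs[i] = v
                break
        else:
            raise RuntimeError("could not place separated phenotype means")
    return {
        p: {mk: float(vecs[i, j]) for j, mk in enumerate(markers)}
        for i, p in enumerate(phenotypes)
    }


def make_level_profile_means(
    group_phenotypes: Mapping[str, Sequence[str]],
    markers: Sequence[str],
    seed: int,
    base_level: float = 4.0,
    level_step: float = 4.0,
    hallmark_subsets: Sequence[Sequence[str]] | None = None,
) -> dict[str, dict[str, float]]:
    """Draw phenotype marker means on the ordinal level grid.

    Each phenotype gets a random low/medium/high level per marker and its
    log2-scale mean is ``base_level + level_step * level``.  Because the
    downstream analysis quantizes intensities into exactly these three
    levels, a group's phenotypes then map to a controlled number of distinct
    molecular states: profiles within one group are redrawn until they are
    pairwise distinct on every hallmark's marker subset, so a group with k
    phenotypes occupies k states per hallmark.  ``level_step`` should be
    several within-phenotype standard deviations so the tri-modal marker
    distributions have clear gaps.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    markers = list(markers)
    if hallmark_subsets is None:
        hallmark_subsets = [markers]
    subset_idx = [[markers.index(m) for m in subset] for subset in hallmark_subsets]

    # pooled-cohort share of each phenotype, assuming equal subjects and cells
    # per group and uniform mixing within a group
    phenotypes: list[str] = []
    shares: list[float] = []
    groups: list[int] = []
    for gi, phenos in enumerate(group_phenotypes.values()):
        for p in phenos:
            phenotypes.append(p)
            shares.append(1.0 / (len(group_phenotypes) * len(phenos)))
            groups.append(gi)
    shares_arr = np.array(shares)

    def balanced_levels() -> np.ndarray:
        """One marker's level per phenotype, with pooled mass per level ~ 1/3."""
        order = rng.permutation(len(phenotypes))
        order = order[np.argsort(-shares_arr[order], kind="stable")]
        load = np.zeros(3)
        lev = np.empty(len(phenotypes), dtype=np.int64)
        for i in order:
            lightest = np.flatnonzero(load == load.min())
            lev[i] = rng.choice(lightest)
            load[lev[i]] += shares_arr[i]
        return lev

    for _ in range(10_000):
        profile = np.column_stack([balanced_levels() for _ in markers])
        ok = True
        for gi in range(len(group_phenotypes)):
            rows = [i for i, g in enumerate(groups) if g == gi]
            for ix in subset_idx:
                sub = profile[np.ix_(rows, ix)]
                if len(np.unique(sub, axis=0)) < len(rows):
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError(
            "cannot draw distinct balanced level profiles; too many phenotypes "
            "for the hallmark state spaces"
        )
    return {
        p: {m: float(base_level + level_step * profile[i, j]) for j, m in enumerate(markers)}
        for i, p in enumerate(phenotypes)
    }


def default_config(
    n_subjects_per_group: int = 10,
    cells_per_sample: int = 2000,
    seed: int = 0,
    mt_phenotypes: int = 2,
    wt_phenotypes: int = 6,
    mt_scatter: float = 0.1,
    wt_scatter: float = 0.9,
) -> SyntheticConfig:
    """Two-group study design: "mt-like" (few phenotypes, spatially aggregated)
    vs "wt-like" (many phenotypes, well mixed), over the default marker panel.

    Phenotype marker means sit on the ordinal level grid (see
    :func:`make_level_profile_means`), so each group occupies as many
    molecular states per hallmark as it has phenotypes.
    """
    markers = default_marker_panel().markers
    mt = tuple(f"mt_p{i + 1}" for i in range(mt_phenotypes))
    wt = tuple(f"wt_p{i + 1}" for i in range(wt_phenotypes))
    means = make_level_profile_means(
        {"mt-like": mt, "wt-like": wt},
        markers,
        seed,
        hallmark_subsets=list(DEFAULT_HALLMARKS.values()),
    )
    return SyntheticConfig(
        groups={
            "mt-like": GroupSpec(mt, mt_scatter),
            "wt-like": GroupSpec(wt, wt_scatter),
        },
        phenotype_marker_means=means,
        n_subjects_per_group=n_subjects_per_group,
        cells_per_sample=cells_per_sample,
        rng_seed=seed,
    )


def generate_sample(
    config: SyntheticConfig, group: str, sample_id: str, seed: int
) -> CellTable:
    """Generate one sample's cell table; deterministic given (config, seed)."""
    if group not in config.groups:
        raise KeyError(f"unknown group label {group!r}")
    spec = config.groups[group]
    rng = np.random.default_rng(seed)
    n = config.cells_per_sample
    markers = config.markers

    xy = rng.uniform([0, 0], [config.field_width, config.field_height], size=(n, 2))
    a = (0.0 - config.cell_radius_mean) / config.cell_radius_sd
    radii = truncnorm.rvs(
        a, np.inf, loc=config.cell_radius_mean, scale=config.cell_radius_sd,
        size=n, random_state=rng,
    )
    area = np.pi * radii**2

    # seeded nearest-phenotype assignment: each spatial seed carries a phenotype;
    # cycling through a permuted phenotype list covers every phenotype when
    # n_spatial_seeds >= n_phenotypes
    n_phen = len(spec.phenotypes)
    seed_xy = rng.uniform([0, 0], [config.field_width, config.field_height],
                          size=(config.n_spatial_seeds, 2))
    perm = rng.permutation(n_phen)
    seed_phen = np.resize(perm, config.n_spatial_seeds)
    nearest = cKDTree(seed_xy).query(xy)[1]
    phen_idx = seed_phen[nearest]
    scatter = rng.random(n) < spec.scatter_prob
    phen_idx = np.where(scatter, rng.integers(0, n_phen, size=n), phen_idx)

    mean_matrix = np.array(
        [[config.phenotype_marker_means[p][m] for m in markers] for p in spec.phenotypes]
    )
    log2_intensity = rng.normal(mean_matrix[phen_idx], config.marker_log_sd)
    intensity = 2.0**log2_intensity

    lo, hi = config.quality_score_range
    quality = rng.uniform(lo, hi, size=n)

    df = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i}" for i in range(n)],
            "sample_id": sample_id,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "area": area,
            "quality_score": quality,
        }
    )
    for j, m in enumerate(markers):
        df[m] = intensity[:, j]
    df["true_phenotype"] = np.asarray(spec.phenotypes)[phen_idx]
    return CellTable(df=df, markers=markers)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, CellTable], pd.DataFrame]:
    """Generate one sample per subject for every group.

    Returns the tables keyed by sample id plus a subject metadata table
    recording group membership and the generator parameters per subject.
    Per-subject seeds are derived deterministically from ``config.rng_seed``.
    """
    n_total = config.n_subjects_per_group * len(config.groups)
    seeds = np.random.SeedSequence(config.rng_seed).generate_state(n_total)
    tables: dict[str, CellTable] = {}
    meta = []
    i = 0
    for group, spec in config.groups.items():
        for k in range(config.n_subjects_per_group):
            sid = f"{group}_s{k + 1}"
            tables[sid] = generate_sample(config, group, sid, int(seeds[i]))
            meta.append(
                {
                    "subject_id": sid,
                    "sample_id": sid,
                    "group": group,
                    "n_phenotypes": len(spec.phenotypes),
                    "scatter_prob": spec.scatter_prob,
                    "cells": config.cells_per_sample,
                    "seed": int(seeds[i]),
                }
            )
            i += 1
    return tables, pd.DataFrame(meta)
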