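"""Reading, validation, quality filtering and transforms for per-cell marker tables.

Cell tables are delimited text (comma by default, tab accepted) with a header
row and one row per segmented cell: a cell identifier, a sample identifier,
centroid coordinates, segmented cell area, a slide-registration quality score
in [0, 1], and one nonnegative intensity column per marker.  Coordinate units
are whatever the upstream segmentation produced; they are treated as opaque
but consistent and never rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spathet")

#: canonical non-marker columns of a cell table, in on-disk order
CANONICAL_COLUMNS = ("cell_id", "sample_id", "x", "y", "area", "quality_score")

#: auxiliary columns that are never treated as markers (generator ground truth)
RESERVED_COLUMNS = ("true_phenotype",)


class SchemaError(ValueError):
    """A cell table or panel file violates the documented schema."""


@dataclass(frozen=True)
class HallmarkSet:
    """An ordered marker list defining one hallmark's molecular state space.

    The marker order is the state concatenation sequence: it is arbitrary but
    must be held fixed, because the base-3 state code depends on it.
    """

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError(f"hallmark {self.name!r} has no markers")
        object.__setattr__(self, "markers", tuple(self.markers))


@dataclass
class MarkerPanel:
    """Marker → hallmark assignment table (marker, hallmarks, compartment)."""

    table: pd.DataFrame  # columns: marker, hallmarks (tuple of str), compartment

    def __post_init__(self) -> None:
        required = {"marker", "hallmarks", "compartment"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"marker panel missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            raise SchemaError("duplicate marker in panel")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.table["marker"])

    def hallmark_sets(self) -> tuple[HallmarkSet, ...]:
        """Hallmark sets with markers ordered by first appearance in the panel."""
        order: dict[str, list[str]] = {}
        for _, row in self.table.iterrows():
            for h in row["hallmarks"]:
                order.setdefault(h, []).append(row["marker"])
        return tuple(HallmarkSet(name, tuple(ms)) for name, ms in order.items())


@dataclass
class CellTable:
    """An ordered collection of per-cell records for one or more samples.

    ``df`` holds the canonical columns plus one numeric column per marker and
    any auxiliary columns (e.g. generator ground truth).  ``rejected`` is the
    per-row validation report produced by :func:`read_cell_table`, if any.
    """

    df: pd.DataFrame
    markers: tuple[str, ...]
    coord_units: str = "arbitrary"
    rejected: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table missing mandatory columns: {missing}")
        missing = [m for m in self.markers if m not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table missing marker columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df["sample_id"]))

    def intensity_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        cols = list(markers) if markers is not None else list(self.markers)
        return self.df[cols].to_numpy(dtype=float)

    def split_by_sample(self) -> dict[str, "CellTable"]:
        return {
            sid: replace(self, df=g.reset_index(drop=True), rejected=None)
            for sid, g in self.df.groupby("sample_id", sort=False)
        }

    def with_df(self, df: pd.DataFrame) -> "CellTable":
        return replace(self, df=df.reset_index(drop=True), rejected=None)


def _validate_rows(df: pd.DataFrame, markers: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise invariant checks; returns (valid rows, per-row rejection report)."""
    reasons: dict[int, list[str]] = {}

    def flag(mask: np.ndarray, reason: str) -> None:
        for i in df.index[np.asarray(mask, dtype=bool)]:
            reasons.setdefault(i, []).append(reason)

    for col in ("x", "y", "area", "quality_score"):
        flag(~np.isfinite(df[col].to_numpy(dtype=float)), f"non-finite {col}")
    area = df["area"].to_numpy(dtype=float)
    flag(np.isfinite(area) & (area <= 0), "non-positive area")
    q = df["quality_score"].to_numpy(dtype=float)
    flag(np.isfinite(q) & ((q < 0) | (q > 1)), "quality score outside [0, 1]")
    for m in markers:
        vals = df[m].to_numpy(dtype=float)
        flag(~np.isfinite(vals), f"non-numeric intensity in {m}")
        flag(np.isfinite(vals) & (vals < 0), f"negative intensity in {m}")

    bad_rows = sorted(reasons)
    report = pd.DataFrame(
        {
            "row": bad_rows,
            "cell_id": df.loc[bad_rows, "cell_id"].to_numpy(),
            "sample_id": df.loc[bad_rows, "sample_id"].to_numpy(),
            "reason": ["; ".join(reasons[i]) for i in bad_rows],
        }
    )
    return df.drop(index=bad_rows).reset_index(drop=True), report


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    markers: Sequence[str] | None = None,
    delimiter: str | None = None,
    coord_units: str = "arbitrary",
) -> CellTable:
    """Read and validate a delimited cell table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from canonical column names (``cell_id``,
        ``sample_id``, ``x``, ``y``, ``area``, ``quality_score``) to the
        column names used in the file.
    markers
        Marker columns to load.  By default every numeric, non-canonical,
        non-reserved column is taken to be a marker.
    delimiter
        Field delimiter; autodetected (comma or tab) when omitted.

    Rows violating per-row invariants (negative or non-numeric intensity,
    non-positive area, quality score outside [0, 1]) are excluded and listed
    in the returned table's ``rejected`` report rather than silently dropped.
    Structural problems — a missing mandatory column, a duplicate
    (sample_id, cell_id) pair — raise :class:`SchemaError`.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")

    if schema:
        rename = {v: k for k, v in schema.items() if v in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    if markers is None:
        candidates = [
            c for c in df.columns if c not in CANONICAL_COLUMNS and c not in RESERVED_COLUMNS
        ]
        markers = [c for c in candidates if pd.api.types.is_numeric_dtype(df[c])]
    else:
        markers = list(markers)
        absent = [m for m in markers if m not in df.columns]
        if absent:
            raise SchemaError(f"missing marker column(s): {absent}")
    if not markers:
        raise SchemaError("no marker columns found")
    for m in markers:
        if not pd.api.types.is_numeric_dtype(df[m]):
            coerced = pd.to_numeric(df[m], errors="coerce")
            if coerced.isna().all():
                raise SchemaError(f"marker column {m!r} is not numeric")
            df[m] = coerced

    dup = df.duplicated(subset=["cell_id", "sample_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate (sample_id, cell_id) pairs: "
            f"{df.loc[dup, ['sample_id', 'cell_id']].head().to_dict('records')}"
        )

    valid, report = _validate_rows(df, markers)
    if len(report):
        logger.warning("read_cell_table: rejected %d of %d rows", len(report), len(df))
    return CellTable(
        df=valid, markers=tuple(markers), coord_units=coord_units,
        rejected=report if len(report) else None,
    )


def write_cell_table(table: CellTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a cell table in the same dialect :func:`read_cell_table` accepts.

    Floats are written at full round-trip precision, so read → write → read
    is lossless.
    """
    cols = [c for c in CANONICAL_COLUMNS] + list(table.markers)
    extras = [c for c in table.df.columns if c not in cols]
    table.df[cols + extras].to_csv(path, sep=delimiter, index=False)


def read_marker_panel(path: str | Path, delimiter: str = ",") -> MarkerPanel:
    """Read a marker panel: columns marker, hallmarks (semicolon-separated), compartment."""
    df = pd.read_csv(path, sep=delimiter)
    missing = {"marker", "hallmarks", "compartment"} - set(df.columns)
    if missing:
        raise SchemaError(f"marker panel missing column(s): {sorted(missing)}")
    df = df.copy()
    df["hallmarks"] = [
        tuple(h.strip() for h in str(v).split(";") if h.strip()) for v in df["hallmarks"]
    ]
    return MarkerPanel(df)


def write_marker_panel(panel: MarkerPanel, path: str | Path, delimiter: str = ",") -> None:
    df = panel.table.copy()
    df["hallmarks"] = [";".join(h) for h in df["hallmarks"]]
    df.to_csv(path, sep=delimiter, index=False)


def filter_quality(table: CellTable, threshold: float = 0.85) -> CellTable:
    """Keep cells whose registration quality score is strictly above ``threshold``.

    The default 0.85 is the study's inclusion cut-off; "above" is read as a
    strict inequality, so a score exactly at the threshold is removed.
    Idempotent; preserves cell order; an empty result is legal.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep = table.df["quality_score"] > threshold
    removed = int((~keep).sum())
    logger.info(
        "filter_quality(threshold=%g): retained %d, removed %d",
        threshold, int(keep.sum()), removed,
    )
    return table.with_df(table.df[keep])


def log2_transform(table: CellTable, pseudocount: float | None = None) -> CellTable:
    """Apply v → log2(v + pseudocount) to every marker intensity.

    With ``pseudocount=None`` the pseudocount defaults to 0 for strictly
    positive data and to 1.0 when zeros are present.  A zero intensity with a
    zero pseudocount is an error rather than a silent -inf.
    """
    vals = table.intensity_matrix()
    has_zero = bool((vals == 0).any())
    if pseudocount is None:
        pseudocount = 1.0 if has_zero else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and has_zero:
        raise ValueError("zero intensities present; a positive pseudocount is required")
    df = table.df.copy()
    df[list(table.markers)] = np.log2(vals + pseudocount)
    return table.with_df(df)
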