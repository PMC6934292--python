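"""Ordinal quantization of marker intensities and molecular-state encoding.

Each marker intensity is discretized into three ordinal levels — low (0),
medium (1), high (2) — at the marker's 33rd and 67th empirical quantiles.
A cell's molecular state over a hallmark set is the base-3 code of its level
vector under the set's fixed marker order, giving Nm = 3^(number of markers)
possible states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellTable, HallmarkSet

logger = logging.getLogger("spathet")

_QUANTILES = (0.33, 0.67)


@dataclass
class QuantizationModel:
    """Per-marker 33rd/67th-quantile thresholds mapping intensity → level.

    ``scope`` records which cells the quantiles were fit over: ``"cohort"``
    (all cells pooled — the default, so every sample shares one state
    definition) or ``"per-sample"``, in which case ``sample_thresholds``
    holds one threshold table per sample.
    """

    thresholds: pd.DataFrame  # index: marker; columns: q33, q67
    scope: str = "cohort"
    degenerate: tuple[str, ...] = ()
    sample_thresholds: dict[str, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if (self.thresholds["q33"] > self.thresholds["q67"]).any():
            raise ValueError("q33 > q67 for some marker")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.thresholds.index)

    def save(self, path: str | Path) -> None:
        """Serialize to a plain-text key-value file for exact reuse."""
        lines = [f"scope\t{self.scope}", f"degenerate\t{';'.join(self.degenerate)}"]
        lines.append("[cohort]")
        for m, row in self.thresholds.iterrows():
            lines.append(f"{m}\t{float(row['q33'])!r}\t{float(row['q67'])!r}")
        for sid, tab in (self.sample_thresholds or {}).items():
            lines.append(f"[sample:{sid}]")
            for m, row in tab.iterrows():
                lines.append(f"{m}\t{float(row['q33'])!r}\t{float(row['q67'])!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "QuantizationModel":
        scope, degenerate = "cohort", ()
        sections: dict[str, list[tuple[str, float, float]]] = {}
        current = None
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            elif current is None:
                key, _, val = line.partition("\t")
                if key == "scope":
                    scope = val
                elif key == "degenerate":
                    degenerate = tuple(v for v in val.split(";") if v)
            else:
                m, lo, hi = line.split("\t")
                sections[current].append((m, float(lo), float(hi)))

        def frame(rows):
            return pd.DataFrame(rows, columns=["marker", "q33", "q67"]).set_index("marker")

        cohort = frame(sections.pop("cohort"))
        samples = {
            name.removeprefix("sample:"): frame(rows) for name, rows in sections.items()
        }
        return cls(cohort, scope=scope, degenerate=degenerate,
                   sample_thresholds=samples or None)


@dataclass
class MolecularStateAssignment:
    """Per-cell ordinal level vectors and base-3 state codes for one hallmark."""

    hallmark: str
    markers: tuple[str, ...]
    cell_ids: np.ndarray
    sample_ids: np.ndarray
    levels: np.ndarray  # (n_cells, n_markers) ints in {0,1,2}
    codes: np.ndarray  # (n_cells,) ints in [0, n_states)

    @property
    def n_states(self) -> int:
        return 3 ** len(self.markers)

    def __len__(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "sample_id": self.sample_ids})
        for j, m in enumerate(self.markers):
            df[f"level_{m}"] = self.levels[:, j]
        df["state_code"] = self.codes
        return df


def _fit_thresholds(df: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    q = df[list(markers)].quantile(list(_QUANTILES), interpolation="linear")
    return pd.DataFrame({"q33": q.iloc[0], "q67": q.iloc[1]}).rename_axis("marker")


def fit_quantization(
    table: CellTable, markers: Sequence[str] | None = None, scope: str = "cohort"
) -> QuantizationModel:
    """Fit per-marker tertile thresholds over the scoped cells.

    Quantiles use linear interpolation between order statistics.  A constant
    marker yields q33 == q67; it is allowed but flagged as degenerate (every
    cell then gets level 0 for that marker).
    """
    markers = tuple(markers) if markers is not None else table.markers
    absent = [m for m in markers if m not in table.df.columns]
    if absent:
        raise KeyError(f"markers not in table: {absent}")
    if scope not in ("cohort", "per-sample"):
        raise ValueError(f"unknown scope {scope!r}")
    if len(table) < 3:
        raise ValueError(f"need >= 3 cells to fit quantiles, got {len(table)}")

    cohort = _fit_thresholds(table.df, markers)
    degenerate = tuple(cohort.index[cohort["q33"] == cohort["q67"]])
    if degenerate:
        logger.warning("degenerate (constant) markers: %s", ", ".join(degenerate))

    sample_thresholds = None
    if scope == "per-sample":
        sample_thresholds = {}
        for sid, g in table.df.groupby("sample_id", sort=False):
            if len(g) < 3:
                raise ValueError(f"sample {sid!r} has fewer than 3 cells")
            sample_thresholds[str(sid)] = _fit_thresholds(g, markers)
    return QuantizationModel(cohort, scope=scope, degenerate=degenerate,
                             sample_thresholds=sample_thresholds)


def assign_levels(values, q33, q67):
    """Map intensity to ordinal level: v <= q33 → 0; q33 < v <= q67 → 1; v > q67 → 2.

    The boundary convention is half-open on the upper side, so a value exactly
    at a threshold falls in the lower level.  Vectorized over ``values``.
    """
    values = np.asarray(values)
    return (values > q33).astype(np.int64) + (values > q67).astype(np.int64)


def state_space_size(hallmark: HallmarkSet) -> int:
    """Number of possible molecular states, 3 raised to the number of markers."""
    return 3 ** len(hallmark.markers)


def encode_states(
    table: CellTable, model: QuantizationModel, hallmark: HallmarkSet
) -> MolecularStateAssignment:
    """Encode each cell's molecular state over the hallmark's ordered markers.

    The state code is sum_j level_j * 3^j with j indexing the hallmark's fixed
    marker order (j = 0 least significant), a bijection between level vectors
    and integers in [0, 3^m).
    """
    missing = [m for m in hallmark.markers if m not in model.markers]
    if missing:
        raise KeyError(f"markers missing from quantization model: {missing}")
    missing = [m for m in hallmark.markers if m not in table.df.columns]
    if missing:
        raise KeyError(f"markers missing from table: {missing}")

    n, m = len(table), len(hallmark.markers)
    levels = np.empty((n, m), dtype=np.int64)
    if model.scope == "per-sample":
        sample_ids = table.df["sample_id"].astype(str).to_numpy()
        for sid in np.unique(sample_ids):
            if model.sample_thresholds is None or sid not in model.sample_thresholds:
                raise KeyError(f"no per-sample thresholds for sample {sid!r}")
            thr = model.sample_thresholds[sid]
            rows = sample_ids == sid
            for j, mk in enumerate(hallmark.markers):
                levels[rows, j] = assign_levels(
                    table.df.loc[rows, mk].to_numpy(), thr.at[mk, "q33"], thr.at[mk, "q67"]
                )
    else:
        for j, mk in enumerate(hallmark.markers):
            levels[:, j] = assign_levels(
                table.df[mk].to_numpy(),
                model.thresholds.at[mk, "q33"],
                model.thresholds.at[mk, "q67"],
            )
    codes = levels @ (3 ** np.arange(m, dtype=np.int64))
    return MolecularStateAssignment(
        hallmark=hallmark.name,
        markers=hallmark.markers,
        cell_ids=table.df["cell_id"].to_numpy(),
        sample_ids=table.df["sample_id"].to_numpy(),
        levels=levels,
        codes=codes,
    )


def decode_state(code: int, n_markers: int) -> np.ndarray:
    """Inverse of the base-3 encoding: code → level vector (index 0 least significant)."""
    if not 0 <= code < 3**n_markers:
        raise ValueError(f"code {code} outside [0, {3 ** n_markers})")
    levels = np.empty(n_markers, dtype=np.int64)
    for j in range(n_markers):
        code, levels[j] = divmod(code, 3)
    return levels
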