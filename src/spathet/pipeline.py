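"""End-to-end pipeline orchestration: simulate/ingest → QC → encode →
heterogeneity → cluster → compare → integrate.

Each stage reads only its declared inputs from the output directory and
writes delimited tables, so any stage can be rerun independently.  A single
master seed fans out deterministically to the stochastic stages, and every
run writes a manifest (JSON) recording the config hash, seed, and stage
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, heterogeneity, io, states, stats, synthetic

logger = logging.getLogger("spathet")

STAGES = ("simulate", "qc", "encode", "heterogeneity", "cluster", "compare", "integrate")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


@dataclass
class RunConfig:
    """Validated run configuration, loadable from a plain-text YAML file."""

    outdir: Path
    seed: int = 0
    synthetic: dict[str, Any] | None = None
    input_tables: tuple[str, ...] = ()
    subject_table: str | None = None
    panel_path: str | None = None
    quality_threshold: float = 0.85
    quantization_scope: str = "cohort"
    cluster_params: dict[str, Any] = field(default_factory=dict)
    group_by: str = "group"
    discretize_rule: str = "range-thirds"
    raw: dict[str, Any] = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        cfg = cls(
            outdir=Path(raw.get("outdir", "spathet_run")),
            seed=int(raw.get("seed", 0)),
            synthetic=raw.get("synthetic"),
            input_tables=tuple(raw.get("input_tables", ())),
            subject_table=raw.get("subject_table"),
            panel_path=raw.get("panel"),
            quality_threshold=float(raw.get("quality_threshold", 0.85)),
            quantization_scope=raw.get("quantization_scope", "cohort"),
            cluster_params=dict(raw.get("cluster", {})),
            group_by=raw.get("group_by", "group"),
            discretize_rule=raw.get("discretize_rule", "range-thirds"),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None and not self.input_tables:
            raise ValueError("config needs either a 'synthetic' section or 'input_tables'")
        for p in list(self.input_tables) + (
            [self.panel_path] if self.panel_path else []
        ) + ([self.subject_table] if self.subject_table else []):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not 0 <= self.quality_threshold <= 1:
            raise ValueError("quality_threshold must be in [0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))


def _synthetic_config(cfg: RunConfig) -> synthetic.SyntheticConfig:
    params = dict(cfg.synthetic or {})
    params.setdefault("seed", cfg.stage_seed("simulate"))
    return synthetic.default_config(**params)


def _write(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return str(path)


# ---------------------------------------------------------------------------
# stages: each consumes only files under cfg.outdir (plus configured inputs)

def stage_simulate(cfg: RunConfig) -> dict[str, Any]:
    d = cfg.outdir / "cells"
    d.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic is not None:
        scfg = _synthetic_config(cfg)
        tables, meta = synthetic.generate_cohort(scfg)
        outputs = []
        for sid, t in tables.items():
            p = d / f"cells_{sid}.csv"
            io.write_cell_table(t, p)
            outputs.append(str(p))
        _write(meta, cfg.outdir / "subjects.csv")
        io.write_marker_panel(synthetic.default_marker_panel(), cfg.outdir / "panel.csv")
    else:
        outputs = []
        for p in cfg.input_tables:
            t = io.read_cell_table(p)
            out = d / f"cells_{Path(p).stem}.csv"
            io.write_cell_table(t, out)
            outputs.append(str(out))
        meta = pd.read_csv(cfg.subject_table) if cfg.subject_table else pd.DataFrame()
        if len(meta):
            _write(meta, cfg.outdir / "subjects.csv")
        if cfg.panel_path:
            io.write_marker_panel(io.read_marker_panel(cfg.panel_path), cfg.outdir / "panel.csv")
        else:
            io.write_marker_panel(synthetic.default_marker_panel(), cfg.outdir / "panel.csv")
    return {"cell_tables": outputs, "subjects": str(cfg.outdir / "subjects.csv"),
            "panel": str(cfg.outdir / "panel.csv")}


def _read_stage_tables(d: Path) -> list[io.CellTable]:
    paths = sorted(d.glob("cells_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no cell tables under {d}")
    return [io.read_cell_table(p) for p in paths]


def stage_qc(cfg: RunConfig) -> dict[str, Any]:
    tables = _read_stage_tables(cfg.outdir / "cells")
    d = cfg.outdir / "qc"
    d.mkdir(parents=True, exist_ok=True)
    outputs, rows = [], []
    for t in tables:
        f = io.filter_quality(t, cfg.quality_threshold)
        sid = f.sample_ids[0] if f.sample_ids else t.sample_ids[0]
        p = d / f"cells_{sid}.csv"
        io.write_cell_table(f, p)
        outputs.append(str(p))
        rows.append({"sample_id": sid, "cells_in": len(t), "cells_retained": len(f),
                     "threshold": cfg.quality_threshold})
    _write(pd.DataFrame(rows), d / "qc_summary.csv")
    return {"cell_tables": outputs, "summary": str(d / "qc_summary.csv")}


def _pool(tables: Sequence[io.CellTable]) -> io.CellTable:
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return io.CellTable(df=df, markers=tables[0].markers)


def stage_encode(cfg: RunConfig) -> dict[str, Any]:
    tables = _read_stage_tables(cfg.outdir / "qc")
    panel = io.read_marker_panel(cfg.outdir / "panel.csv")
    pooled = _pool(tables)
    model = states.fit_quantization(pooled, panel.markers, scope=cfg.quantization_scope)
    d = cfg.outdir / "encode"
    d.mkdir(parents=True, exist_ok=True)
    model.save(d / "quantization.txt")
    outputs = {"quantization": str(d / "quantization.txt")}
    for hm in panel.hallmark_sets():
        assignment = states.encode_states(pooled, model, hm)
        outputs[hm.name] = _write(assignment.to_frame(), d / f"states_{hm.name}.csv")
    return outputs


def stage_heterogeneity(cfg: RunConfig) -> dict[str, Any]:
    tables = _read_stage_tables(cfg.outdir / "qc")
    panel = io.read_marker_panel(cfg.outdir / "panel.csv")
    model = states.QuantizationModel.load(cfg.outdir / "encode" / "quantization.txt")
    report = heterogeneity.heterogeneity_report(tables, panel.hallmark_sets(), model)
    d = cfg.outdir / "heterogeneity"
    out = {"report": _write(report, d / "heterogeneity.csv")}
    subjects_path = cfg.outdir / "subjects.csv"
    if subjects_path.exists():
        meta = pd.read_csv(subjects_path)
        if cfg.group_by in meta.columns:
            groups = dict(zip(meta["sample_id"].astype(str), meta[cfg.group_by]))
            for hm in panel.hallmark_sets():
                p = d / f"scatter_{hm.name}.png"
                heterogeneity.plot_heterogeneity(report, hm.name, groups, str(p))
                out[f"scatter_{hm.name}"] = str(p)
    return out


def stage_cluster(cfg: RunConfig) -> dict[str, Any]:
    tables = _read_stage_tables(cfg.outdir / "qc")
    panel = io.read_marker_panel(cfg.outdir / "panel.csv")
    pooled = io.log2_transform(_pool(tables))
    params = cfg.cluster_params
    k_range = range(int(params.get("k_min", 2)), int(params.get("k_max", 15)) + 1)
    seed = cfg.stage_seed("cluster")

    pre = clustering.fit_preprocess(pooled.df[list(panel.markers)],
                                    mode=params.get("trim_mode", "winsorize"))
    X, keep = clustering.apply_preprocess(pre, pooled.df[list(panel.markers)])
    sample_ids = pooled.df.loc[keep, "sample_id"].to_numpy()

    models = clustering.kmeans_scan(X, k_range, n_starts=int(params.get("n_starts", 10)),
                                    seed=seed)
    consensus = clustering.consensus_cluster(
        X, k_range,
        subsample_cells=int(params.get("consensus_cells", 5000)),
        n_iterations=int(params.get("consensus_iterations", 1000)),
        resample_fraction=float(params.get("resample_fraction", 0.8)),
        seed=seed + 1,
    )
    sel = clustering.choose_k(models, consensus)
    best = next(m for m in models if m.k == sel.recommended_k)
    profile = clustering.cluster_profiles(best, X, clustering.retained_markers(pre))
    comp = clustering.sample_composition(best, sample_ids)

    d = cfg.outdir / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    out = {
        "selection": _write(sel.table, d / "k_selection.csv"),
        "assignments": _write(
            pd.DataFrame({"cell_id": pooled.df.loc[keep, "cell_id"],
                          "sample_id": sample_ids, "cluster": best.labels}),
            d / "assignments.csv"),
        "profiles": _write(profile.deviations.assign(percent=profile.percentages)
                           .reset_index(), d / "profiles.csv"),
        "composition": _write(comp.reset_index(), d / "composition.csv"),
        "recommended_k": sel.recommended_k,
        "flags": list(sel.flags),
    }
    clustering.plot_lollipop(profile, str(d / "lollipop.png"))
    clustering.plot_consensus_cdf(consensus, str(d / "consensus_cdf.png"))
    return out


def _subject_features(cfg: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    het = pd.read_csv(cfg.outdir / "heterogeneity" / "heterogeneity.csv")
    meta = pd.read_csv(cfg.outdir / "subjects.csv")
    feats = het.pivot_table(
        index="sample_id",
        columns="hallmark",
        values=["molecular_heterogeneity", "spatial_heterogeneity"],
    )
    feats.columns = [f"{metric}_{hm}" for metric, hm in feats.columns]
    comp_path = cfg.outdir / "cluster" / "composition.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path).set_index("sample_id")
        comp.columns = [f"cluster{c}_fraction" for c in comp.columns]
        feats = feats.join(comp)
    groups = meta.set_index("sample_id")[cfg.group_by]
    return feats, groups.loc[feats.index]


def stage_compare(cfg: RunConfig) -> dict[str, Any]:
    feats, groups = _subject_features(cfg)
    comparisons = []
    for col in feats.columns:
        v = feats[col].to_numpy(dtype=float)
        try:
            comparisons.append(stats.compare_ranks(v, groups.to_numpy(), feature=col))
        except ValueError as e:
            logger.warning("skipping comparison for %s: %s", col, e)
    d = cfg.outdir / "compare"
    return {"comparisons": _write(stats.comparison_table(comparisons),
                                  d / "comparisons.csv")}


def stage_integrate(cfg: RunConfig) -> dict[str, Any]:
    feats, _ = _subject_features(cfg)
    disc = stats.discretize_features(feats, rule=cfg.discretize_rule)
    result = stats.integrate_and_cluster(disc)
    d = cfg.outdir / "integrate"
    d.mkdir(parents=True, exist_ok=True)
    out = {
        "discretized": _write(disc.labels.reset_index(), d / "discretized.csv"),
        "dendrogram": str(d / "dendrogram.nwk"),
        "subject_order": list(result.subject_order),
    }
    (d / "dendrogram.nwk").write_text(result.newick + "\n")
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "encode": stage_encode,
    "heterogeneity": stage_heterogeneity,
    "cluster": stage_cluster,
    "compare": stage_compare,
    "integrate": stage_integrate,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Run the requested stages (all by default) and write the run manifest.

    Stage failures abort with a stage-named :class:`StageError`; outputs of
    completed stages and the partial manifest are preserved.
    """
    cfg.validate()
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    manifest_path = cfg.outdir / "manifest.json"
    for name in stages:
        logger.info("running stage %s", name)
        try:
            manifest["stages"][name] = _STAGE_FUNCS[name](cfg)
        except Exception as e:
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            raise StageError(f"stage {name!r} failed: {e}") from e
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
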