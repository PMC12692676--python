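"""End-to-end orchestration: simulate → qc → summarize → stats → screen → network.

Each stage writes its artifacts under the run's output directory and is
recorded in a manifest (inputs, parameters, seed, sha256 checksums), so a
rerun with the same configuration reproduces identical manifests. A stage
failure aborts the run naming the stage; artifacts already written stay on
disk for inspection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import duncan, network, profiles, qc, rf, simulate
from .table import FeatureTable, read_feature_table, write_feature_table

__all__ = ["RunConfig", "StageError", "run_all", "assign_subclasses"]

#: Subclass weights used to annotate synthetic features, shaped like the
#: species counts a targeted lipidomics panel typically reports.
_SUBCLASS_WEIGHTS = {
    "TG": 210, "PS": 94, "PE": 88, "PC": 87, "CAR": 80, "PC-O": 65,
    "PE-P": 60, "SM": 55, "PI": 45, "Cer": 40, "DG": 35, "PG": 30,
    "LPC": 25, "LPE": 20, "HexCer": 10, "CE": 5, "ST": 2, "CoQ": 2,
    "MG": 5, "FFA": 4,
}


def assign_subclasses(feature_ids, rng: np.random.Generator) -> dict[str, str]:
    """Random subclass annotation for synthetic features (realistic weights)."""
    codes = list(_SUBCLASS_WEIGHTS)
    w = np.array([_SUBCLASS_WEIGHTS[c] for c in codes], dtype=float)
    draws = rng.choice(len(codes), size=len(feature_ids), p=w / w.sum())
    return {fid: codes[i] for fid, i in zip(feature_ids, draws)}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    When ``table_path`` is unset the run starts from the synthetic
    generator; otherwise the feature table (and optional quality table /
    annotation) are read from disk.
    """

    out_dir: str = "lipimark_run"
    seed: int = 0
    table_path: str | None = None
    groups_path: str | None = None
    annotation_path: str | None = None
    quality_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    qc_filter: dict = field(default_factory=dict)       # rate_min, cv_max, floor
    alpha: float = 0.05
    rf_config: dict = field(default_factory=dict)       # RFConfig fields
    network_config: dict = field(default_factory=dict)  # r_min, p_max

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (JSON is a subset and also accepted)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("table_path", "groups_path", "annotation_path",
                     "quality_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_all(config: RunConfig) -> dict:
    """Run every stage in dependency order and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }

    rng = np.random.default_rng(config.seed)

    # -- simulate (or load) ------------------------------------------------
    stage = "simulate"
    try:
        if config.table_path is None:
            cfg = simulate.SyntheticConfig(seed=config.seed, **config.synthetic)
            table, truth = simulate.generate_lipidome(cfg, rng)
            quality = simulate.generate_quality_table(cfg, truth, table, rng=rng)
            annotation = assign_subclasses(table.feature_ids, rng)
            table_file = out / "table.csv"
            write_feature_table(table, table_file)
            quality.to_csv(out / "quality.csv")
            _write_json(annotation, out / "annotation.json")
            _write_json({"marker_ids": truth.marker_ids,
                         "up_group": truth.up_group,
                         "trait_loadings": {t: [m, r] for t, (m, r)
                                            in truth.trait_loadings.items()}},
                        out / "truth.json")
            files = [table_file, out / "table.groups.csv", out / "quality.csv",
                     out / "annotation.json", out / "truth.json"]
            record(stage, {"synthetic": asdict(cfg)}, files)
        else:
            table = read_feature_table(config.table_path, config.groups_path)
            quality = (pd.read_csv(config.quality_path, index_col=0)
                       if config.quality_path else None)
            annotation = (json.loads(Path(config.annotation_path).read_text())
                          if config.annotation_path else None)
            record(stage, {"table_path": str(config.table_path)}, [])
    except Exception as exc:  # noqa: BLE001 - named-stage abort
        raise StageError(stage, exc) from exc

    # -- qc ----------------------------------------------------------------
    stage = "qc"
    try:
        filtered, report = qc.filter_features(table, **config.qc_filter)
        r, scores, dispersion, flagged = qc.qc_reliability(table)
        report.qc_pairwise_r = r
        report.pca_scores = scores
        report.qc_dispersion = dispersion
        report.flagged_pairs = flagged
        write_feature_table(filtered, out / "filtered.csv")
        _write_json(report.to_dict(), out / "qc_report.json")
        record(stage, {**config.qc_filter},
               [out / "filtered.csv", out / "filtered.groups.csv",
                out / "qc_report.json"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- summarize (class/subclass composition) ----------------------------
    stage = "summarize"
    try:
        summary: dict = {}
        if annotation is not None:
            from .catalog import subclass_to_class

            sub_counts: dict[str, int] = {}
            for fid in filtered.feature_ids:
                sc = annotation[fid]
                sub_counts[sc] = sub_counts.get(sc, 0) + 1
            cls_counts: dict[str, int] = {}
            for sc, n in sub_counts.items():
                c = subclass_to_class(sc)
                cls_counts[c] = cls_counts.get(c, 0) + n
            summary["subclass_counts"] = sub_counts
            summary["class_counts"] = cls_counts
            summary["proportions"] = {
                g: profiles.composition_proportions(filtered, annotation, g)
                for g in filtered.biological_groups}
        _write_json(summary, out / "composition.json")
        record(stage, {}, [out / "composition.json"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stats (Duncan letters on quality traits) --------------------------
    stage = "stats"
    try:
        stats_files = []
        if quality is not None:
            groups = table.groups.loc[quality.index]
            stats_df = duncan.summarize_groups(quality, groups,
                                               alpha=config.alpha)
            stats_df.to_csv(out / "stats.csv", index_label="variable")
            stats_files.append(out / "stats.csv")
        record(stage, {"alpha": config.alpha}, stats_files)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- screen (RF-RFE) ---------------------------------------------------
    stage = "screen"
    try:
        rf_cfg = rf.RFConfig(seed=config.seed, **config.rf_config)
        trajectory, panel = rf.rfe(filtered, rf_cfg)
        _write_json({"rounds": [
            {"n_features": r_.n_features, "mean_error": r_.mean_error,
             "feature_ids": r_.feature_ids} for r_ in trajectory.rounds],
            "panel": panel.feature_ids, "panel_error": panel.error,
            "informative": panel.informative},
            out / "trajectory.json")
        pd.DataFrame({"feature_id": panel.feature_ids}).to_csv(
            out / "panel.csv", index=False)
        record(stage, asdict(rf_cfg), [out / "trajectory.json",
                                       out / "panel.csv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- network (panel × traits correlations) -----------------------------
    stage = "network"
    try:
        net_files = []
        if quality is not None and panel.feature_ids:
            samples = filtered.biological_samples
            lipids = np.log(
                filtered.values.loc[panel.feature_ids, samples].T)
            both = pd.concat([lipids, quality.loc[samples]], axis=1)
            r, p = network.pairwise_pearson(both)
            kinds = {c: ("lipid" if c in panel.feature_ids else "trait")
                     for c in both.columns}
            g = network.build_network(r, p, kinds=kinds,
                                      **config.network_config)
            network.export_graph(g, out / "network.graphml", "graphml")
            network.export_graph(g, out / "edges.csv", "csv")
            order = network.heatmap_order(r)
            r.loc[order, order].to_csv(out / "heatmap.csv")
            net_files = [out / "network.graphml", out / "edges.csv",
                         out / "heatmap.csv"]
        record(stage, {**config.network_config}, net_files)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_json(manifest, out / "manifest.json")
    return manifest
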