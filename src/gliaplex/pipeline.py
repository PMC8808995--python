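"""End-to-end orchestration: synth → measure → normalize → spatial → states →
gbm → (cnn) → stats, from one YAML config, with a provenance manifest.

Each stage reads only the previous stages' outputs, writes CSV/JSON under
its own subdirectory, and is seeded independently so stages are
reproducible in isolation. The run manifest lists every output file with
its stage, seed and content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gbm as gbm_mod
from . import imaging, profiles, states, stats, synth
from .panel import default_panel

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("gliaplex")

STAGES = ("synth", "measure", "normalize", "spatial", "states", "gbm", "cnn", "stats")


@dataclass
class RunConfig:
    out_dir: str = "gliaplex_run"
    cohort: dict = field(default_factory=dict)  # CohortParams overrides
    stages: dict = field(default_factory=lambda: {s: (s != "cnn") for s in STAGES})
    seeds: dict = field(default_factory=dict)  # per-stage seeds
    ball_radius: int = 200
    cluster_k: int | str = "auto"
    gbm_grid: dict = field(default_factory=lambda: {"n_trees": [100, 200], "depth": [1, 2, 3]})
    gbm_folds: int = 5
    cnn: dict = field(default_factory=dict)  # CnnConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = {**{s: (s != "cnn") for s in STAGES}, **cfg.stages}
        return cfg

    def seed_for(self, stage: str) -> int:
        return int(self.seeds.get(stage, STAGES.index(stage) + 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out: Path):
        self.out = out
        self.entries = []

    def add(self, stage: str, seed: int, *paths):
        for p in paths:
            p = Path(p)
            self.entries.append(
                {
                    "stage": stage,
                    "seed": seed,
                    "path": str(p.relative_to(self.out)),
                    "sha256": _sha256(p),
                }
            )

    def write(self) -> Path:
        path = self.out / "manifest.json"
        path.write_text(json.dumps({"outputs": self.entries}, indent=1))
        return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the manifest path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    panel = default_panel()
    enabled = config.stages

    params = synth.CohortParams(**{**config.cohort, "seed": config.seed_for("synth")})

    # --- synth -------------------------------------------------------------
    synth_dir = out / "synth"
    if enabled.get("synth", True):
        log.info("stage synth: rendering cohort to %s", synth_dir)
        synth.generate_cohort(params, synth_dir, panel)
        manifest.add("synth", params.seed, *sorted(synth_dir.rglob("*.*")))

    # --- measure -----------------------------------------------------------
    measured_csv = out / "measured.csv"
    if enabled.get("measure", True):
        field_manifests = sorted(synth_dir.glob("*/manifest.json"))
        if not field_manifests:
            raise RuntimeError("measure: no field manifests found; rerun the synth stage")
        rows, lesion_rows = [], []
        for mpath in field_manifests:
            stack = imaging.read_stack(mpath)
            rois = imaging.parse_annotations(mpath.parent / "annotations.json", stack.shape)
            table, lesions = imaging.measure_stack(stack, rois, panel, config.ball_radius)
            table = profiles.attach_lesion_distances(table, lesions)
            rows.append(table)
            for lesion in lesions:
                lesion_rows.append(
                    {
                        "field_id": stack.metadata.get("field_id"),
                        "type": lesion.type,
                        "x_um": lesion.centroid[0],
                        "y_um": lesion.centroid[1],
                        "area_um2": lesion.area,
                        "radius_um": lesion.radius,
                    }
                )
        measured = pd.concat(rows, ignore_index=True)
        measured.to_csv(measured_csv, index=False)
        pd.DataFrame(lesion_rows).to_csv(out / "lesions.csv", index=False)
        manifest.add("measure", config.seed_for("measure"), measured_csv, out / "lesions.csv")

    # --- normalize ----------------------------------------------------------
    matrix_csv = out / "matrix.csv"
    cell_type = params.cell_type
    markers = panel.phenotypic(cell_type)
    if enabled.get("normalize", True):
        if not measured_csv.exists():
            raise RuntimeError("normalize: measured.csv missing; rerun the measure stage")
        measured = pd.read_csv(measured_csv)
        glia = measured[measured["object_class"] == cell_type].reset_index(drop=True)
        matrix = profiles.log_z_normalize(glia, markers)
        matrix.to_csv(matrix_csv)
        manifest.add("normalize", config.seed_for("normalize"), matrix_csv)

    # --- spatial -------------------------------------------------------------
    if enabled.get("spatial", True):
        if not measured_csv.exists():
            raise RuntimeError("spatial: measured.csv missing; rerun the measure stage")
        measured = pd.read_csv(measured_csv)
        ann_map = pd.read_csv(synth_dir / "truth.csv")[["field_id", "annotation_id", "profile_id"]]
        state_map = pd.read_csv(synth_dir / "profiles.csv")[["profile_id", "state"]]
        merged = measured.merge(ann_map, on=["field_id", "annotation_id"], how="left").merge(
            state_map, on="profile_id", how="left"
        )
        hist = profiles.bin_phenotype_proportions(
            merged.dropna(subset=["state"]), lesion_type="plaque"
        )
        hist_csv = out / "proximity_histogram.csv"
        hist.to_csv(hist_csv, index=False)
        manifest.add("spatial", config.seed_for("spatial"), hist_csv)

    # --- states --------------------------------------------------------------
    labels_csv = out / "state_labels.csv"
    if enabled.get("states", True):
        if not matrix_csv.exists():
            raise RuntimeError("states: matrix.csv missing; rerun the normalize stage")
        matrix = profiles.IntensityMatrix.from_csv(matrix_csv, markers)
        result = states.cluster_states(
            matrix, cell_type, k=config.cluster_k, seed=config.seed_for("states")
        )
        lab = matrix.meta.copy()
        lab["state"] = result.labels
        lab.to_csv(labels_csv, index=False)
        pd.DataFrame({"eigenvalue": result.eigenvalues}).to_csv(out / "spectrum.csv", index=False)
        result.display_matrix.to_csv(out / "display_matrix.csv")
        wd, ws, counts = states.crosstab_states(result.labels, matrix.meta["diagnosis"])
        counts.to_csv(out / "state_by_diagnosis_counts.csv")
        wd.to_csv(out / "states_within_diagnosis.csv")
        ws.to_csv(out / "diagnoses_within_state.csv")
        manifest.add(
            "states",
            config.seed_for("states"),
            labels_csv,
            out / "spectrum.csv",
            out / "display_matrix.csv",
            out / "state_by_diagnosis_counts.csv",
            out / "states_within_diagnosis.csv",
            out / "diagnoses_within_state.csv",
        )

    # --- gbm ------------------------------------------------------------------
    if enabled.get("gbm", True):
        matrix = profiles.IntensityMatrix.from_csv(matrix_csv, markers)
        if labels_csv.exists():
            matrix.meta["state"] = pd.read_csv(labels_csv)["state"].to_numpy()
        suite = gbm_mod.run_paper_gbm_suite(
            matrix,
            grid=config.gbm_grid,
            folds=config.gbm_folds,
            seed=config.seed_for("gbm"),
        )
        report = {name: rep.to_dict() for name, rep in suite["reports"].items()}
        report["multi_beats_singles"] = suite["multi_beats_singles"]
        gbm_json = out / "gbm_report.json"
        gbm_json.write_text(json.dumps(report, indent=1))
        manifest.add("gbm", config.seed_for("gbm"), gbm_json)

    # --- cnn (optional) --------------------------------------------------------
    if enabled.get("cnn", False):
        from . import cnn as cnn_mod

        X, y = _profile_crops(out, synth_dir, params, panel)
        seed = config.seed_for("cnn")
        cfg = cnn_mod.CnnConfig(**{**config.cnn, "seed": seed})
        split = gbm_mod.stratified_split(pd.DataFrame({"diagnosis": y}), seed=seed)
        model, history = cnn_mod.train_cnn(X[split.train_idx], y[split.train_idx], cfg)
        proba = model.predict_proba(X[split.test_idx])
        rep = gbm_mod.evaluate_scores(
            proba[:, 1], y[split.test_idx], seed=seed, positive_label=model.classes_[1]
        )
        cnn_json = out / "cnn_report.json"
        cnn_json.write_text(json.dumps(rep.to_dict(), indent=1))
        history.to_csv(out / "cnn_history.csv", index=False)
        manifest.add("cnn", seed, cnn_json, out / "cnn_history.csv")

    # --- stats -------------------------------------------------------------------
    if enabled.get("stats", True):
        matrix = profiles.IntensityMatrix.from_csv(matrix_csv, markers)
        contrasts, summary = stats.compare_groups(matrix, grouping="diagnosis")
        contrasts.to_csv(out / "mixedmodel_diagnosis.csv", index=False)
        summary.to_csv(out / "marker_summary.csv", index=False)
        outputs = [out / "mixedmodel_diagnosis.csv", out / "marker_summary.csv"]
        counts_csv = out / "state_by_diagnosis_counts.csv"
        if counts_csv.exists():
            counts = pd.read_csv(counts_csv, index_col=0)
            if counts.shape == (2, 3):
                trend = stats.chi2_trend(counts.to_numpy())
                trend_json = out / "trend_test.json"
                trend_json.write_text(
                    json.dumps({"chi2": trend.chi2, "df": trend.df, "p": trend.p}, indent=1)
                )
                outputs.append(trend_json)
        manifest.add("stats", config.seed_for("stats"), *outputs)

    path = manifest.write()
    log.info("pipeline complete: %s", path)
    return path


def _profile_crops(out: Path, synth_dir: Path, params, panel):
    """Extract standardized (C, 64, 64) crops for every measured glial ROI."""
    from .cnn import prepare_image

    measured = pd.read_csv(out / "measured.csv")
    cell_type = params.cell_type
    chans = [panel.constitutive(cell_type)] + panel.phenotypic(cell_type) + ["DAPI"]
    images, labels = [], []
    for mpath in sorted(synth_dir.glob("*/manifest.json")):
        stack = imaging.read_stack(mpath)
        fid = stack.metadata.get("field_id")
        rois = imaging.parse_annotations(mpath.parent / "annotations.json", stack.shape)
        roi_by_id = {r.annotation_id: r for r in rois}
        for _, row in measured[measured["field_id"] == fid].iterrows():
            roi = roi_by_id.get(int(row["annotation_id"]))
            if roi is None or roi.object_class != cell_type:
                continue
            crop = np.stack([roi.crop(stack[c]) for c in chans])
            images.append(prepare_image(crop))
            labels.append(row["diagnosis"])
    return np.asarray(images), np.asarray(labels)
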