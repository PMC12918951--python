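"""End-to-end orchestration with a run manifest for reproducibility.

``run_pipeline`` executes the stages requested by a structured (YAML) config:
synthetic-data generation or dataset loading, standardization, clustering and
cluster-aware splitting, nested cross-validation, final-model fitting,
label-shuffle control, interpretation and screening.  Every stochastic stage
draws from a seed recorded in the manifest written next to the artifacts, so
a rerun with the same config reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .chemio import AROMATICITY_MODEL, read_dataset, write_dataset, write_rejects
from .dmpnn import MPNNConfig
from .featurize import fingerprint_matrix
from .interpret import rank_features, shapley_attributions
from .model import (PipelineOptions, fit_final, nested_cv,
                    paper_booster_config, shuffle_control)
from .screen import ScreenConfig, filter_cascade, predict_library
from .split import (add_outer_folds, assert_no_cluster_leakage, butina_cluster,
                    cluster_train_test_split)
from .synthdata import GeneratorConfig, generate_dataset


@dataclass
class RunManifest:
    """Snapshot of everything a rerun needs: version, config, seeds, digests."""

    version: str
    created: str
    seed: int
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, Any] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def options_from_config(cfg: dict) -> PipelineOptions:
    mpnn = MPNNConfig(**cfg.get("mpnn", {}))
    return PipelineOptions(
        families=tuple(cfg.get("families", ("GNN", "DESCRIPTOR", "TARGET"))),
        budget=cfg.get("budget"),
        n_iter=int(cfg.get("n_iter", 15)),
        inner_k=int(cfg.get("inner_k", 3)),
        threshold=float(cfg.get("decision_threshold", 0.5)),
        rfe_step=cfg.get("rfe_step", 0.05),
        mpnn=mpnn,
        seed=int(cfg.get("seed", 0)),
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the configured stages; returns a summary dict of the artifacts."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(version=__version__,
                           created=time.strftime("%Y-%m-%dT%H:%M:%S"),
                           seed=seed, config=config)
    summary: dict[str, Any] = {}

    # --- dataset -----------------------------------------------------------
    if "synth" in config:
        gen = GeneratorConfig(seed=seed, **config["synth"])
        records = generate_dataset(gen)
        rejects: list[dict] = []
        manifest.parameters["generator"] = asdict(gen)
    else:
        data_path = Path(config["dataset"])
        if not data_path.exists():
            raise FileNotFoundError(f"dataset not found: {data_path}")
        manifest.input_digests[str(data_path)] = _digest(data_path)
        records, rejects = read_dataset(data_path)
    write_dataset(records, out / "dataset.csv")
    write_rejects(rejects, out / "rejects.csv")
    labels = np.array([r.label for r in records])
    summary["n_records"] = len(records)
    summary["n_rejects"] = len(rejects)
    summary["active_fraction"] = float(labels.mean())

    # --- clustering + split ------------------------------------------------
    cutoff = float(config.get("cluster_cutoff", 0.4))
    fps = fingerprint_matrix(records).values
    assignment = butina_cluster(list(fps), cutoff)
    ids = [r.id for r in records]
    plan = cluster_train_test_split(assignment, labels, ids,
                                    test_fraction=float(config.get("test_fraction", 0.2)),
                                    seed=seed)
    labels_by_id = {r.id: r.label for r in records}
    plan = add_outer_folds(plan, assignment, labels_by_id, ids,
                           k=int(config.get("k_outer", 5)), seed=seed)
    assert_no_cluster_leakage(plan, assignment, ids)
    plan.save(out / "split.json")
    manifest.parameters["cluster_cutoff"] = cutoff
    manifest.parameters["n_clusters"] = assignment.n_clusters
    manifest.parameters["aromaticity_model"] = AROMATICITY_MODEL
    summary["n_train"] = len(plan.train_ids)
    summary["n_test"] = len(plan.test_ids)

    options = options_from_config(config)
    cluster_of_id = {rid: assignment.cluster_of[i] for i, rid in enumerate(ids)}

    # --- nested CV + final model -------------------------------------------
    bundle = None
    if config.get("nested_cv", True):
        reports, configs = nested_cv(records, plan, cluster_of_id, options)
        (out / "fold_reports.json").write_text(
            "[" + ",".join(r.to_json() for r in reports) + "]")
        summary["cv_roc_auc"] = float(np.mean([r.roc_auc for r in reports]))
        bundle, test_report = fit_final(records, plan, configs, options)
        test_report.save(out / "final_report.json")
        bundle.save(out / "bundle")
        summary["test"] = {k: getattr(test_report, k) for k in
                           ("roc_auc", "mcc", "f1", "precision", "balanced_accuracy")}

    # --- shuffle control -----------------------------------------------------
    if config.get("shuffle_control", False):
        rep = shuffle_control(records, plan, options, seed=seed + 7,
                              booster_config=paper_booster_config())
        rep.save(out / "shuffle_report.json")
        summary["shuffle_balanced_accuracy"] = rep.balanced_accuracy

    # --- interpretation -------------------------------------------------------
    if config.get("interpret", False) and bundle is not None:
        by_id = {r.id: r for r in records}
        test_records = [by_id[i] for i in plan.test_ids]
        feats = bundle.mask.apply(bundle.pipeline.transform(test_records))
        attr = shapley_attributions(bundle.model, feats)
        rank_features(attr, top_k=30).to_csv(out / "top_features.csv", index=False)

    # --- screening -------------------------------------------------------------
    if "screen" in config and bundle is not None:
        lib_path = Path(config["screen"]["library"])
        manifest.input_digests[str(lib_path)] = _digest(lib_path)
        lib_records, lib_rejects = read_dataset(lib_path)
        from .chemio import deduplicate
        by_id = {r.id: r for r in records}
        train_records = [by_id[i] for i in plan.train_ids]
        lib_records = deduplicate(lib_records, reference=train_records)
        probs, scored, score_rejects = predict_library(bundle, lib_records)
        scfg = ScreenConfig(threshold=float(config["screen"].get("threshold", 0.8)))
        import pandas as pd
        ann = None
        if config["screen"].get("annotations"):
            ann = pd.read_csv(config["screen"]["annotations"], index_col="id")
        report = filter_cascade(probs, scored, annotations=ann, config=scfg)
        report.save(out / "screen.csv")
        write_rejects(lib_rejects + score_rejects, out / "screen_rejects.csv")
        summary["screen_stage_counts"] = report.stage_counts

    manifest.save(out / "manifest.json")
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
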