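"""End-to-end orchestration: simulate -> train -> translate -> evaluate ->
classify, with self-describing output directories.

Every run writes a resolved copy of its configuration next to its outputs,
and every CSV table's Mean row is recomputed from the table's own column
values, so reports are reproducible from the directory contents alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ied_classifier import (
    ClassifierConfig,
    CrossValidationPlan,
    inter_subject_eval,
    intra_subject_eval,
    select_training_subjects,
)
from .mapping_eval import evaluate_mapping, mean_of_column, report_to_frame
from .networks import ArchitectureConfig
from .objectives import LossWeights
from .segment_store import SubjectCohort, read_cohort, write_cohort
from .synthetic import SimulationConfig, simulate_cohort
from .trainer import TrainingConfig, save_model, train_cohort, translate
from .ied_classifier import stratified_split

__all__ = ["run_simulate", "run_pipeline", "run_ablations", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "runs/output",
    "simulate": {},         # SimulationConfig fields
    "architecture": {},     # ArchitectureConfig fields; geometry inferred from data
    "training": {},         # TrainingConfig fields
    "classifier": {},       # ClassifierConfig fields
    "selection_threshold": 0.70,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge DEFAULT_CONFIG < YAML file < overrides; unknown keys rejected."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for source in (yaml.safe_load(Path(path).read_text()) if path else None, overrides):
        if not source:
            continue
        unknown = set(source) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"expected a subset of {sorted(cfg)}")
        for key, val in source.items():
            if isinstance(cfg.get(key), dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _resolve_outdir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_resolved(config: dict, outdir: Path, extra: dict | None = None) -> None:
    resolved = dict(config)
    if extra:
        resolved["provenance"] = extra
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))


def run_simulate(config: dict) -> Path:
    """Generate a synthetic cohort and write it (HDF5) with provenance."""
    outdir = _resolve_outdir(config)
    sim = SimulationConfig(**{"seed": config["seed"], **config["simulate"]})
    cohort = simulate_cohort(sim)
    path = outdir / "cohort.h5"
    write_cohort(cohort, path)
    provenance = {
        "stage": "simulate",
        "geometry": {"L": sim.L, "M": sim.M, "M_bar": sim.M_bar},
        "attenuation": cohort.metadata.get("attenuation"),
        "n_segments": int(sum(len(r.segments) for r in cohort.subjects)),
    }
    _write_resolved(config, outdir, provenance)
    logger.info("simulated cohort: %d subjects -> %s", len(cohort), path)
    return path


def _arch_for(cohort: SubjectCohort, config: dict) -> ArchitectureConfig:
    seg = cohort.subjects[0].segments[0]
    geometry = {"L": seg.scalp.L, "M": seg.scalp.n_sensors,
                "M_bar": seg.intracranial.n_sensors}
    return ArchitectureConfig(**{**geometry, **config["architecture"]})


def _training_for(config: dict) -> TrainingConfig:
    fields = dict(config["training"])
    if "loss_weights" in fields:
        fields["loss_weights"] = LossWeights(**fields["loss_weights"])
    return TrainingConfig(**{"seed": config["seed"], **fields})


def run_pipeline(config: dict, cohort_path=None) -> Path:
    """Train per subject, evaluate mapping and both classification protocols.

    Writes ``mapping.csv`` (per-subject MSE/PCORR/COSSIM + Mean),
    ``intra_subject.csv`` and ``inter_subject.csv`` (metric columns + Mean),
    ``history_<subject>.csv``, model checkpoints, and the resolved config.
    """
    outdir = _resolve_outdir(config)
    cohort_path = Path(cohort_path) if cohort_path else outdir / "cohort.h5"
    if not cohort_path.exists():
        raise FileNotFoundError(f"cohort file {cohort_path} (run simulate first)")
    cohort = read_cohort(cohort_path)
    arch = _arch_for(cohort, config)
    tcfg = _training_for(config)
    ccfg = ClassifierConfig(**{"seed": config["seed"], **config["classifier"]})
    plan = CrossValidationPlan(selection_threshold=config["selection_threshold"])

    logger.info("stage: train (%d subjects)", len(cohort))
    models, histories = train_cohort(cohort, arch, tcfg)
    for sid, model in models.items():
        save_model(model, outdir / f"model_{sid}.npz")
        pd.DataFrame({k: getattr(histories[sid], k)
                      for k in ("d_loss", "g_hinge", "kl", "l1", "fm", "g_total")}
                     ).to_csv(outdir / f"history_{sid}.csv", index_label="epoch")

    logger.info("stage: translate + mapping evaluation")
    mapping_pairs = {}
    for rec in cohort.subjects:
        labels = np.array([1 if s.label == "IED" else 0 for s in rec.segments])
        _, _, test_idx = stratified_split(labels, plan, seed=ccfg.seed)
        xs = np.stack([rec.segments[i].scalp.samples for i in test_idx])
        ys = np.stack([rec.segments[i].intracranial.samples for i in test_idx])
        est = translate(models[rec.subject_id], xs, mode="mean")
        mapping_pairs[rec.subject_id] = list(zip(ys, est))
    mapping_frame = report_to_frame(evaluate_mapping(mapping_pairs))
    mapping_frame.to_csv(outdir / "mapping.csv", index_label="subject")

    logger.info("stage: intra-subject classification")
    intra_rows, classifiers, intra_acc = {}, {}, {}
    for rec in cohort.subjects:
        metrics, clf = intra_subject_eval(rec.segments, models[rec.subject_id],
                                          plan, ccfg, return_classifier=True)
        intra_rows[rec.subject_id] = _metrics_row(metrics)
        classifiers[rec.subject_id] = clf
        intra_acc[rec.subject_id] = metrics.ACC
    intra_frame = _frame_with_mean(intra_rows)
    intra_frame.to_csv(outdir / "intra_subject.csv", index_label="subject")

    selected = select_training_subjects(intra_acc, plan.selection_threshold)
    logger.info("selected training subjects (ACC > %.2f): %s",
                plan.selection_threshold, selected)

    inter_rows = {}
    for rec in cohort.subjects:
        ensemble = {sid: (models[sid], classifiers[sid])
                    for sid in selected if sid != rec.subject_id}
        if not ensemble:
            logger.warning("no selected subjects available for test subject %s; skipped",
                           rec.subject_id)
            continue
        inter_rows[rec.subject_id] = _metrics_row(inter_subject_eval(rec.segments, ensemble))
    if inter_rows:
        _frame_with_mean(inter_rows).to_csv(outdir / "inter_subject.csv",
                                            index_label="subject")

    _write_resolved(config, outdir, {
        "stage": "pipeline", "cohort": str(cohort_path),
        "selected_subjects": selected,
        "architecture": asdict(arch),
    })
    return outdir


def run_ablations(config: dict, cohort_path=None,
                  ablations=("full", "no_encoder", "no_spade_resnet")) -> Path:
    """Re-run the pipeline per ablation and collect an ablation summary table
    (intra-subject ACC plus cohort-mean mapping metrics per design)."""
    outdir = _resolve_outdir(config)
    rows = {}
    for ablation in ablations:
        sub = dict(config)
        sub["architecture"] = {**config["architecture"], "ablation": ablation}
        sub["output_dir"] = str(outdir / ablation)
        run_dir = run_pipeline(sub, cohort_path)
        mapping = pd.read_csv(run_dir / "mapping.csv", index_col=0)
        intra = pd.read_csv(run_dir / "intra_subject.csv", index_col=0)
        rows[ablation] = {
            "ACC": intra.loc["Mean", "ACC"],
            "MSE": mapping.loc["Mean", "MSE"],
            "PCORR": mapping.loc["Mean", "PCORR"],
            "COSSIM": mapping.loc["Mean", "COSSIM"],
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.to_csv(outdir / "ablation.csv", index_label="design")
    return outdir


def _metrics_row(metrics) -> dict:
    return {k: getattr(metrics, k) for k in ("ACC", "SEN", "SPC", "PRC", "F1", "AUC")}


def _frame_with_mean(rows: dict) -> pd.DataFrame:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.loc["Mean"] = {col: mean_of_column(frame[col].dropna().to_numpy(), 3)
                         for col in frame.columns}
    return frame
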