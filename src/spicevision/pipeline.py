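"""End-to-end experiment orchestration.

One :func:`run_experiment` call chains simulate -> crop -> channels ->
features -> select -> train (ANN sweep + one-vs-one SVM) -> evaluate and
writes every intermediate artifact (image manifest, feature CSV, selection
JSON, training logs, confusion matrices, metrics, summary table) into the
output directory.  A single global seed deterministically derives every
stage seed, so a rerun with the same config reproduces every file.

Confusion matrices and metrics are reported on two scopes: the full
dataset ("paper-style", the scope on which headline matrices of this kind
of study are usually printed) and the held-out test partition alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (PowderPalette, SimConfig, BLACK_PEPPER, RED_PEPPER,
                       SEA_FOAM, generate_dataset, write_dataset)
from .features import FeatureTable, build_feature_table
from .selection import sfs_select, report_efficient_features
from .classify import (SplitSpec, MLPConfig, SVMConfig, split_dataset,
                       sweep_structures, train_svm_ovo)
from .evaluate import confusion, metrics, report, MetricsReport

_PALETTES = {"black_pepper": BLACK_PEPPER, "red_pepper": RED_PEPPER,
             "sea_foam": SEA_FOAM}


@dataclass
class ExperimentConfig:
    material: str = "black_pepper"
    adulterant: str = "sea_foam"
    sim: SimConfig = field(default_factory=SimConfig)
    crop_keep: float = 0.8
    glcm_levels: int = 8
    hist_bins: int = 256
    selection_cv_folds: int = 5
    selection_max_features: int = 20
    selection_tol: float = 1e-6
    ann_split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    svm_split: tuple[float, float, float] = (0.8, 0.0, 0.2)
    ann: MLPConfig = field(default_factory=MLPConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    out_dir: str = "results"
    seed: int = 0
    write_images: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        if "ann" in kwargs:
            ann = dict(kwargs["ann"])
            if "hidden_sizes_to_sweep" in ann:
                ann["hidden_sizes_to_sweep"] = tuple(ann["hidden_sizes_to_sweep"])
            kwargs["ann"] = MLPConfig(**ann)
        if "svm" in kwargs:
            kwargs["svm"] = SVMConfig(**kwargs["svm"])
        for key in ("ann_split", "svm_split"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        offsets = {"simulate": 1, "select": 2, "ann": 3, "svm": 4}
        return (self.seed * 10 + offsets[stage]) % (2 ** 31)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    table: FeatureTable = field(repr=False)
    selection: object = field(repr=False, default=None)
    ann_sweep: object = field(repr=False, default=None)
    metrics_full: dict = field(default_factory=dict)
    metrics_test: dict = field(default_factory=dict)
    summary: pd.DataFrame = field(default=None, repr=False)


def _palette(name: str) -> PowderPalette:
    try:
        return _PALETTES[name]
    except KeyError:
        raise ValueError(f"unknown palette {name!r}; known: {sorted(_PALETTES)}")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def simulate_stage(cfg: ExperimentConfig, out: Path):
    sim = SimConfig(**{**asdict_sim(cfg.sim), "seed": cfg.stage_seed("simulate")})
    imgset = generate_dataset(_palette(cfg.material), _palette(cfg.adulterant), sim)
    if cfg.write_images:
        write_dataset(imgset, out / "images")
    return imgset


def asdict_sim(sim: SimConfig) -> dict:
    return {"levels": sim.levels, "images_per_level": sim.images_per_level,
            "image_size": sim.image_size, "grain_scale": sim.grain_scale,
            "illumination_gradient": sim.illumination_gradient,
            "sensor_noise_sd": sim.sensor_noise_sd, "seed": sim.seed}


def extract_stage(cfg: ExperimentConfig, imgset, out: Path) -> FeatureTable:
    table = build_feature_table(
        imgset.images, imgset.labels, levels=imgset.per_sample_levels,
        material=cfg.material, crop_keep=cfg.crop_keep,
        glcm_levels=cfg.glcm_levels, hist_bins=cfg.hist_bins)
    table.to_csv(out / "features.csv")
    return table


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "material": cfg.material,
                 "seed": cfg.seed,
                 "stage_seeds": {s: cfg.stage_seed(s)
                                 for s in ("simulate", "select", "ann", "svm")}}

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # tag failures with the stage name
            raise StageError(stage, exc) from exc

    imgset = run("simulate", simulate_stage, cfg, out)
    table = run("extract", extract_stage, cfg, imgset, out)

    sel = run("select", lambda: sfs_select(
        table, cv_folds=cfg.selection_cv_folds,
        max_features=cfg.selection_max_features,
        tol=cfg.selection_tol, seed=cfg.stage_seed("select")))
    sel.to_json(out / "selection.json")
    report_efficient_features(sel, table).to_csv(
        out / "efficient_feature_means.csv", index=False)

    reduced = FeatureTable(features=table.features.iloc[:, sel.selected],
                           labels=table.labels, levels=table.levels,
                           material=table.material)
    n_classes = reduced.n_classes

    # --- ANN protocol: 60/20/20 split, hidden-size sweep -------------------
    def ann_stage():
        tr, va, te = split_dataset(reduced, SplitSpec(
            fractions=cfg.ann_split, seed=cfg.stage_seed("ann")))
        sweep = sweep_structures(tr, va, te, MLPConfig(
            hidden_sizes_to_sweep=cfg.ann.hidden_sizes_to_sweep,
            max_epochs=cfg.ann.max_epochs, patience=cfg.ann.patience,
            learning_rate=cfg.ann.learning_rate, seed=cfg.stage_seed("ann")))
        return tr, va, te, sweep

    tr, va, te, sweep = run("ann", ann_stage)
    sweep.records.to_csv(out / "ann_sweep.csv", index=False)
    sweep.chosen_model.log.to_csv(out / "ann_training_log.csv", index=False)

    ann_pred_full = sweep.chosen_model.predict(reduced)
    ann_pred_test = sweep.chosen_model.predict(te) if te.n_samples else np.array([])

    # --- SVM protocol: 80/20 split, one-vs-one RBF -------------------------
    def svm_stage():
        tr2, _, te2 = split_dataset(reduced, SplitSpec(
            fractions=cfg.svm_split, seed=cfg.stage_seed("svm")))
        model = train_svm_ovo(tr2, SVMConfig(
            C=cfg.svm.C, gamma=cfg.svm.gamma, tol=cfg.svm.tol,
            seed=cfg.stage_seed("svm")))
        return tr2, te2, model

    tr2, te2, svm_model = run("svm", svm_stage)
    svm_pred_full = svm_model.predict(reduced)
    svm_pred_test = svm_model.predict(te2) if te2.n_samples else np.array([])

    # --- evaluation on both scopes -----------------------------------------
    result = ExperimentResult(config=cfg, table=table, selection=sel,
                              ann_sweep=sweep)
    preds = {"ANN": (ann_pred_full, te.labels, ann_pred_test),
             "SVM": (svm_pred_full, te2.labels, svm_pred_test)}
    summary_reports: dict[tuple[str, str], MetricsReport] = {}
    for method, (pred_full, test_labels, pred_test) in preds.items():
        m_full = confusion(reduced.labels, pred_full, n_classes)
        rep_full = metrics(m_full)
        result.metrics_full[method] = rep_full
        summary_reports[(cfg.material, method)] = rep_full
        np.savetxt(out / f"confusion_full_{method}.csv", m_full.counts,
                   fmt="%d", delimiter=",")
        if len(pred_test):
            m_test = confusion(test_labels, pred_test, n_classes)
            result.metrics_test[method] = metrics(m_test)
            np.savetxt(out / f"confusion_test_{method}.csv", m_test.counts,
                       fmt="%d", delimiter=",")

    result.summary = report(summary_reports, out / "summary.csv")
    test_summary = {m: {"test_ccr": rep.overall_ccr,
                        "n_test": rep.total}
                    for m, rep in result.metrics_test.items()}
    log["n_selected_features"] = sel.n_selected
    log["chosen_hidden_size"] = sweep.chosen_hidden_size
    log["test_metrics"] = test_summary
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return result
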