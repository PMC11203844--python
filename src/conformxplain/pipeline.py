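"""End-to-end experiment driver.

Sweeps imbalance-mitigation methods against attribution methods on a
synthetic ensemble: simulate -> featurize -> split -> (per mitigation)
resample the training split -> train the CNN -> metrics -> (per explainer)
contribution maps, robustness, stability -> IQR relevance -> consensus
across explainers and across mitigation methods -> recovery against the
planted ground truth. Every stage derives its own seed from the master
seed, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assess, explain, io
from ._seeds import derive_seed
from .classifier import ModelConfig, split_data, train_cnn
from .featurize import LabelingConfig, label_ensemble
from .imbalance import ResamplerConfig, apply_resampling, class_weights
from .synthdata import STATES, SynthConfig, generate_ensemble

logger = logging.getLogger("conformxplain")


@dataclass
class ExperimentConfig:
    """Full specification of one sweep."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    labeling: LabelingConfig | None = None
    resamplers: tuple = (
        ResamplerConfig(method="none"),
        ResamplerConfig(method="smoteenn"),
    )
    model: ModelConfig = field(default_factory=ModelConfig)
    explainers: tuple = ("lrp", "saliency")
    assessment: assess.RobustnessConfig = field(
        default_factory=assess.RobustnessConfig)
    output_dir: str | Path = "results"
    seed: int = 0
    run_assessment: bool = True

    def validate(self) -> None:
        self.synth.validate()
        for r in self.resamplers:
            r.validate()
        for e in self.explainers:
            if e not in explain.EXPLAINER_NAMES:
                raise ValueError(f"unknown explainer {e!r}")
        self.assessment.validate()


def _digest(arr) -> str:
    import hashlib
    return hashlib.blake2b(np.ascontiguousarray(arr).tobytes(),
                           digest_size=6).hexdigest()


def _stage(log, name, t0, output=None):
    dt = time.perf_counter() - t0
    entry = {"stage": name, "seconds": round(dt, 3)}
    if output is not None:
        entry["output_hash"] = _digest(output)
    logger.info("stage %s finished in %.2fs (hash %s)", name, dt,
                entry.get("output_hash", "-"))
    log.append(entry)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the sweep and write all artifacts under ``output_dir``.

    Returns the report dict (also written as report.json).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log = []

    t0 = time.perf_counter()
    synth_cfg = cfg.synth
    synth_cfg.seed = derive_seed(cfg.seed, "simulate")
    ensemble, truth = generate_ensemble(synth_cfg)
    io.write_trajectory_csv(ensemble, out / "trajectory.csv")
    io.write_residue_table_csv(ensemble.residue_table,
                               out / "residues.csv")
    io.write_ground_truth_json(truth, out / "ground_truth.json")
    _stage(stage_log, "simulate", t0, output=ensemble.coordinates)

    t0 = time.perf_counter()
    labeling = cfg.labeling or LabelingConfig(marker_pair=truth.marker_pair)
    data = label_ensemble(ensemble, labeling)
    io.write_features_csv(data.X, data.y, out / "features.csv")
    _stage(stage_log, "featurize", t0, output=data.X)

    t0 = time.perf_counter()
    (X_tr, y_tr), (X_va, y_va) = split_data(
        data.X, data.y, val_fraction=0.2, seed=derive_seed(cfg.seed, "split"))
    _stage(stage_log, "split", t0)

    report = {"seed": cfg.seed, "resamplers": {}, "stages": stage_log}
    relevant_by_method = {}

    for rcfg in cfg.resamplers:
        name = rcfg.method
        rcfg.seed = derive_seed(cfg.seed, f"resample:{name}")
        t0 = time.perf_counter()
        resampled = apply_resampling(rcfg, X_tr, y_tr)
        _stage(stage_log, f"resample:{name}", t0, output=resampled.X)

        t0 = time.perf_counter()
        mcfg = ModelConfig(**{**cfg.model.__dict__,
                              "seed": derive_seed(cfg.seed, f"train:{name}")})
        weights = resampled.class_weights
        model = train_cnn((resampled.X, resampled.y), mcfg,
                          class_weights=weights)
        _stage(stage_log, f"train:{name}", t0)

        y_pred = model.predict(X_va)
        scores = model.predict_proba(X_va)
        table = assess.confusion_and_rates(y_va, y_pred, labels=STATES)
        table.mcc = assess.mcc(y_va, y_pred)
        table.auc = assess.roc_auc_ova(y_va, scores, labels=STATES)
        entry = {"n_train": len(resampled.y),
                 "class_weights": weights,
                 "metrics": table.to_dict(),
                 "explainers": {}}

        rng = np.random.default_rng(derive_seed(cfg.seed, f"subset:{name}"))
        n_sub = min(cfg.assessment.subset_size, len(y_va))
        sub = rng.choice(len(y_va), size=n_sub, replace=False)

        for ename in cfg.explainers:
            t0 = time.perf_counter()
            explainer = explain.make_explainer(
                ename, model, resampled.X,
                seed=derive_seed(cfg.seed, f"explain:{name}:{ename}"))
            if ename == "perm":
                classes, imp = explain.permutation_importance(
                    model, X_va[sub], y_va[sub],
                    seed=derive_seed(cfg.seed, f"perm:{name}"))
                cmap = explain.ContributionMap(
                    values=np.vstack([imp[classes.index(s)]
                                      if s in classes else
                                      np.full(imp.shape[1], np.nan)
                                      for s in STATES]),
                    states=STATES, method="perm", imbalance_method=name)
                ent = {}
            else:
                vectors = explain.explain_validation_set(
                    explainer, X_va[sub], y_va[sub], sample_ids=sub)
                cmap = explain.aggregate_class_map(
                    vectors, y_va[sub], method=ename, imbalance_method=name)
                ent = {}
                if cfg.run_assessment:
                    acfg = assess.RobustnessConfig(
                        noise_sd=cfg.assessment.noise_sd,
                        stability_repeats=cfg.assessment.stability_repeats,
                        subset_size=n_sub,
                        seed=derive_seed(cfg.seed, f"assess:{name}:{ename}"))
                    ent["robustness"] = assess.robustness_score(
                        explainer, X_va[sub], y_va[sub], acfg)
                    ent["stability"] = assess.stability_score(
                        explainer, X_va[sub], y_va[sub], acfg)
            io.write_contribution_map_csv(
                cmap, out / f"map_{name}_{ename}.csv")
            relevant = assess.iqr_relevant(cmap)
            ent["relevant"] = {s: sorted(r for r, _, _ in members)
                               for s, members in relevant.by_state.items()}
            ent["recovery"] = assess.recovery_score(relevant, truth)
            entry["explainers"][ename] = ent
            relevant_by_method[(name, ename)] = relevant.union()
            _stage(stage_log, f"explain:{name}:{ename}", t0)

        report["resamplers"][name] = entry

    # Consensus across explainers (per mitigation) and across mitigation
    # methods (per explainer).
    report["consensus"] = {"across_explainers": {},
                           "across_resamplers": {}}
    resampler_names = [r.method for r in cfg.resamplers]
    for name in resampler_names:
        sets = {e: relevant_by_method[(name, e)] for e in cfg.explainers}
        if 2 <= len(sets) <= 4:
            report["consensus"]["across_explainers"][name] = (
                assess.consensus(sets))
    for ename in cfg.explainers:
        sets = {n: relevant_by_method[(n, ename)] for n in resampler_names}
        if 2 <= len(sets) <= 4:
            report["consensus"]["across_resamplers"][ename] = (
                assess.consensus(sets))

    io.write_report_json(report, out / "report.json")
    return report
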