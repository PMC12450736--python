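"""End-to-end seeded pipeline: generate -> preprocess -> split -> train
-> tune -> validate -> report.

One master seed deterministically derives every stage seed (a fixed
spawn-key schedule over a ``numpy`` ``SeedSequence``), so identical
config + seed produces a byte-identical report and any stage can be
re-run in isolation.  Test patients are quarantined from the moment the
split is made: the training and tuning stages receive the test ids only
as a forbidden list, and the leakage audit recorded in the report proves
the intersection stayed empty.  Test-set predictions are computed once,
after the operating thresholds are frozen on cross-validated training
predictions.

Wall-clock timings go to a side log, never into the report JSON, so
reports stay byte-comparable across runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_stats import table_one
from .consensus_predict import (
    DEFAULT_CONSTRAINT,
    MODES,
    cross_validated_predictions,
    predict_dataset,
    recall_at,
    roc_curve,
    tune_operating_point,
)
from .diagnostics_impact import (
    ConfusionMatrix,
    ScreeningScenario,
    compute_metrics,
    screening_impact,
)
from .mc_ga_lda import GAConfig, McConfig, SplitConfig, stratified_split, train_ensemble
from .preprocess import PreprocConfig
from .spectra_io import write_wide_csv
from .synthetic_cohort import CohortConfig, covariates_frame, default_bands, generate_dataset

#: fixed stage order; each stage's seed is spawned at its index
STAGE_ORDER = ("cohort", "split", "train", "tune")


def stage_seeds(master_seed: int) -> dict:
    """Fixed master-seed -> stage-seed schedule (all < 2**31)."""
    seeds = {}
    for i, name in enumerate(STAGE_ORDER):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i,))
        seeds[name] = int(ss.generate_state(1)[0] % (2**31))
    return seeds


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    mc: McConfig = field(default_factory=McConfig)
    operating_modes: tuple = ("sensitivity_tuned", "specificity_tuned")
    constraint: float = DEFAULT_CONSTRAINT
    tune_folds: int = 5
    scenario_n: int = 1000
    scenario_prevalence: float = 0.30
    scenario_cost_per_scan: float = 900.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for m in self.operating_modes:
            if m not in MODES:
                raise ValueError(f"unknown operating mode {m!r}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "cohort": {
                k: v for k, v in asdict(self.cohort).items() if k != "bands"
            },
            "cohort_bands": [asdict(b) for b in self.cohort.bands],
            "preproc": self.preproc.to_dict(),
            "split": asdict(self.split),
            "ga": self.ga.to_dict(),
            "mc": self.mc.to_dict(),
            "operating_modes": list(self.operating_modes),
            "constraint": self.constraint,
            "tune_folds": self.tune_folds,
            "scenario": {
                "n": self.scenario_n,
                "prevalence": self.scenario_prevalence,
                "cost_per_scan": self.scenario_cost_per_scan,
            },
            "master_seed": self.master_seed,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


_TOP_KEYS = {
    "cohort", "preproc", "split", "ga", "mc", "tuning", "scenario", "master_seed",
}
_COHORT_KEYS = {
    "n_patients", "prevalence_in_cohort", "replicates_per_patient", "noise_sd",
    "baseline_amplitude", "water_region_amplitude", "patient_effect_sd", "seed",
    "grid_high", "grid_low", "grid_points", "class_effect", "null_signal",
}
_TUNING_KEYS = {"modes", "constraint", "folds"}
_SCENARIO_KEYS = {"n", "prevalence", "cost_per_scan"}


def config_from_dict(raw: dict, master_seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a (YAML-loaded) mapping; unknown keys are
    rejected."""
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def section(name, allowed=None):
        d = dict(raw.get(name) or {})
        if allowed is not None:
            bad = set(d) - allowed
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
        return d

    craw = section("cohort", _COHORT_KEYS)
    effect = craw.pop("class_effect", None)
    null_signal = craw.pop("null_signal", False)
    if null_signal:
        bands = tuple(replace(b, class_effect=0.0) for b in default_bands())
    elif effect is not None:
        bands = default_bands(float(effect))
    else:
        bands = default_bands()
    cohort = CohortConfig(bands=bands, **craw)

    preproc = PreprocConfig.from_dict(section("preproc")) if raw.get("preproc") else PreprocConfig()
    split = SplitConfig(**section("split"))
    ga = GAConfig(**section("ga"))
    mc = McConfig(**section("mc"))
    tun = section("tuning", _TUNING_KEYS)
    scen = section("scenario", _SCENARIO_KEYS)

    cfg = RunConfig(
        cohort=cohort, preproc=preproc, split=split, ga=ga, mc=mc,
        operating_modes=tuple(tun.get("modes", ("sensitivity_tuned", "specificity_tuned"))),
        constraint=float(tun.get("constraint", DEFAULT_CONSTRAINT)),
        tune_folds=int(tun.get("folds", 5)),
        scenario_n=int(scen.get("n", 1000)),
        scenario_prevalence=float(scen.get("prevalence", 0.30)),
        scenario_cost_per_scan=float(scen.get("cost_per_scan", 900.0)),
        master_seed=int(raw.get("master_seed", 0)),
    )
    if master_seed is not None:
        cfg = replace(cfg, master_seed=int(master_seed))
    return cfg


def load_config(path, master_seed: int | None = None) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw, master_seed=master_seed)


def smoke_config(master_seed: int = 0, n_models: int = 5) -> RunConfig:
    """A minutes-scale profile for smoke runs: small GA, few models."""
    return RunConfig(
        cohort=CohortConfig(n_patients=40),
        ga=GAConfig(population_size=12, generations=5, k_min=3, k_max=10),
        mc=McConfig(n_models=n_models),
        tune_folds=3,
        master_seed=master_seed,
    )


def run_pipeline(cfg: RunConfig, output_dir=None) -> dict:
    """Execute the full analysis and return the (JSON-serializable)
    run report; artifacts are written when ``output_dir`` is given."""
    t0 = time.monotonic()
    seeds = stage_seeds(cfg.master_seed)
    log: list[str] = [f"ftirscreen {__version__} run, config {cfg.hash()[:12]}"]

    def mark(stage):
        log.append(f"[{time.monotonic() - t0:8.2f}s] {stage}")

    # --- generate ---------------------------------------------------------
    cohort_cfg = replace(cfg.cohort, seed=seeds["cohort"])
    dataset = generate_dataset(cohort_cfg)
    mark(f"generated cohort: {len(dataset)} patients")

    # --- split ------------------------------------------------------------
    split_cfg = replace(cfg.split, seed=seeds["split"])
    train_ids, test_ids = stratified_split(dataset.patients, split_cfg)
    train_set = dataset.subset(train_ids)
    test_set = dataset.subset(test_ids)
    mark(f"split: {len(train_ids)} train / {len(test_ids)} test")

    consumed: dict[str, list] = {"train": [], "tune": []}

    # --- train ------------------------------------------------------------
    mc_cfg = replace(cfg.mc, seed=seeds["train"])
    ensemble = train_ensemble(
        train_set, cfg.preproc, cfg.ga, mc_cfg, quarantined_ids=test_ids
    )
    consumed["train"] = sorted(train_ids)
    mark(f"trained ensemble: {ensemble.n_models} models")

    # --- tune (cross-validated within the training set) --------------------
    cv_preds = cross_validated_predictions(
        train_set, cfg.preproc, cfg.ga, mc_cfg,
        n_folds=cfg.tune_folds, seed=seeds["tune"],
    )
    consumed["tune"] = sorted({p.patient_id for p in cv_preds})
    labels = dataset.labels()
    cv_roc = roc_curve(cv_preds, labels)
    points = {
        mode: tune_operating_point(cv_preds, labels, mode, cfg.constraint)
        for mode in cfg.operating_modes
    }
    balanced = tune_operating_point(cv_preds, labels, "balanced", cfg.constraint)
    train_cm = ConfusionMatrix.from_predictions(
        recall_at(cv_preds, balanced.theta), labels
    )
    train_report = compute_metrics(train_cm, auc=cv_roc.auc)
    mark(f"tuned thresholds: { {m: round(p.theta, 4) for m, p in points.items()} }")

    # --- validate (test set, exactly once, thresholds frozen) --------------
    base_preds = predict_dataset(ensemble, test_set, theta=0.5)
    test_reports, test_preds = {}, {}
    for mode, op in points.items():
        preds = recall_at(base_preds, op.theta)
        cm = ConfusionMatrix.from_predictions(preds, labels)
        test_reports[mode] = (cm, compute_metrics(cm))
        test_preds[mode] = preds
    mark("validated on test set")

    # --- impact -----------------------------------------------------------
    sens_mode = (
        "sensitivity_tuned" if "sensitivity_tuned" in test_reports
        else next(iter(test_reports))
    )
    _, rep = test_reports[sens_mode]
    impact = screening_impact(ScreeningScenario(
        n=cfg.scenario_n,
        prevalence=cfg.scenario_prevalence,
        sensitivity=rep.sensitivity or 0.0,
        specificity=rep.specificity or 0.0,
        cost_per_scan=cfg.scenario_cost_per_scan,
    ))
    mark("computed screening impact")

    leaked = sorted(
        (set(consumed["train"]) | set(consumed["tune"])) & set(test_ids)
    )
    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seeds": {"master": cfg.master_seed, **seeds},
        "stage_order": list(STAGE_ORDER),
        "split": {"train_ids": sorted(train_ids), "test_ids": sorted(test_ids)},
        "leakage_audit": {
            "train_stage_ids": consumed["train"],
            "tune_stage_ids": consumed["tune"],
            "test_ids": sorted(test_ids),
            "test_ids_consumed_before_validation": leaked,
        },
        "training_cv": {
            "auc": cv_roc.auc,
            "metrics": train_report.to_dict(),
            "balanced_theta": balanced.theta,
            "n_predictions": len(cv_preds),
        },
        "operating_points": {
            m: {
                "theta": p.theta, "tpr": p.tpr, "fpr": p.fpr,
                "constraint": p.constraint, "feasible": p.feasible,
            }
            for m, p in points.items()
        },
        "test": {
            m: {
                "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
                "metrics": rep.to_dict(),
            }
            for m, (cm, rep) in test_reports.items()
        },
        "selection_frequency": {
            "wavenumbers": ensemble.wavenumbers.tolist(),
            "counts": ensemble.selection_frequency.tolist(),
        },
        "impact": impact.to_dict(),
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_wide_csv(dataset, out / "cohort.csv")
        covariates_frame(dataset.patients).to_csv(out / "covariates.csv", index=False)
        table_one(covariates_frame(dataset.patients).drop(columns=["patient_id"])).to_csv(
            out / "table_one.csv", index=False
        )
        ensemble.to_json(out / "ensemble.json")
        for mode, preds in test_preds.items():
            _write_predictions_csv(preds, points[mode], out / f"predictions_{mode}.csv")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
        mark(f"artifacts written to {out}")
        with open(out / "run.log", "w", encoding="utf-8") as fh:
            fh.write("\n".join(log) + "\n")
    return report


def _write_predictions_csv(predictions, op, path) -> None:
    import pandas as pd

    rows = []
    for p in predictions:
        row = {"patient_id": p.patient_id}
        for i, v in enumerate(p.replicate_votes):
            row[f"vote_fraction_r{i}"] = v.vote_fraction
        row.update(
            patient_score=p.patient_score, call=p.call,
            theta=op.theta, mode=op.mode,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
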