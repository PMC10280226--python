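"""End-to-end orchestration: cohort -> bands -> features -> rank -> models.

A :class:`RunConfig` (constructible from YAML) names the input (a manifest
of recorded signals, or a synthetic cohort spec), the feature pools and
selection levels to evaluate, the models, and the split protocol. ``run``
executes the full method and returns a report bundle; with an output
directory it also writes ranking CSVs, prediction CSVs, the per-level
report table and a JSON bundle.

One global seed fans out to per-stage seeds by fixed offsets so that each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, selection
from .exceptions import ConfigError
from .features import FeatureMatrix, build_matrix
from .preprocess import (DEFAULT_BANDPASS, DEFAULT_SMOOTHER, EPOCH_LEN_S,
                         FilterSpec, decompose_bands, denoise, epoch)
from .records import Cohort, load_cohort
from .synth import CohortSpec, simulate_cohort

# fixed per-stage seed offsets fanned out from the global seed
_SEED_SYNTH = 0
_SEED_SPLIT = 1
_SEED_MODELS = 2


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    manifest: str | None = None              # path to a cohort manifest CSV
    synth: CohortSpec | None = None          # or: generate a cohort
    bandpass: FilterSpec = field(default_factory=lambda: DEFAULT_BANDPASS)
    smoother: FilterSpec = field(default_factory=lambda: DEFAULT_SMOOTHER)
    epoch_len_s: float = EPOCH_LEN_S
    pools: tuple = ("ALL",)
    levels: tuple | str = "all-features"     # "all-features" or levels 1..10
    models: tuple = ("knn", "svm", "ensemble_tree", "hybrid")
    split_mode: str = "epoch_random_50_50"
    include_demographics: bool = False
    rank_on_train_only: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.manifest is None and self.synth is None:
            raise ConfigError("config needs either a manifest or a synth spec")
        if not self.pools:
            raise ConfigError("at least one pool required")
        bad = set(self.pools) - set(selection.POOLS)
        if bad:
            raise ConfigError(f"unknown pools {sorted(bad)}")
        if not self.models:
            raise ConfigError("at least one model required")
        if "hybrid" in self.models:
            missing = set(classify.MODEL_KINDS) - set(self.models)
            if missing:
                raise ConfigError(
                    f"hybrid requires all three base models; missing {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "synth" in kw and kw["synth"] is not None:
            kw["synth"] = CohortSpec(**kw["synth"])
        for key in ("bandpass", "smoother"):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = FilterSpec(**kw[key])
        for key in ("pools", "models", "levels"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go excluded)."""
        d = asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_input(config: RunConfig) -> Cohort:
    if config.manifest is not None:
        return load_cohort(config.manifest)
    spec = config.synth
    if spec.seed != config.seed + _SEED_SYNTH:
        # fan the global seed into the generator unless explicitly pinned
        spec = CohortSpec(**{**asdict(spec), "seed": config.seed + _SEED_SYNTH})
    return simulate_cohort(spec)


def compute_features(cohort: Cohort, config: RunConfig) -> FeatureMatrix:
    """Denoise, band-decompose and epoch every record; assemble the matrix."""
    epoch_sets = []
    for rec in cohort:
        clean = denoise(rec, config.bandpass, config.smoother)
        bands = decompose_bands(clean, rec.fs,
                                order=config.bandpass.order,
                                stop_atten_db=config.bandpass.stop_atten_db,
                                transition_ratio=config.bandpass.transition_ratio)
        epoch_sets.append(epoch(bands, config.epoch_len_s,
                                subject_id=rec.subject_id, label=rec.label))
    return build_matrix(epoch_sets, cohort,
                        include_demographics=config.include_demographics)


def _evaluate_models(matrix, feature_ids, train_idx, test_idx, config,
                     wanted_models, compute_reports=True):
    """Fit base models on the training rows and score them on the test rows.

    Per-fold reports are skipped under LOSO (a single-subject test fold has
    one-class truth, so kappa/AUC are undefined until folds are pooled).
    """
    cols = list(feature_ids)
    if config.include_demographics:
        cols += [c for c in matrix.data.columns if c.startswith("demo/")]
    train_rows = matrix.data.iloc[train_idx][cols]
    y_train = matrix.labels[train_idx]
    test_rows = matrix.data.iloc[test_idx][cols]
    y_test = matrix.labels[test_idx]

    models = classify.fit_all(train_rows, y_train,
                              seed=config.seed + _SEED_MODELS)
    reports, predictions = {}, {}
    for name in wanted_models:
        labels, scores = models[name].predict(test_rows)
        if compute_reports:
            reports[name] = evaluate.evaluate_predictions(y_test, labels,
                                                          scores)
        predictions[name] = (labels, scores)
    return reports, predictions, models


def run(config: RunConfig) -> dict:
    """Execute the full method; returns the report bundle dict."""
    cohort = load_input(config)
    matrix = compute_features(cohort, config)

    split_spec = classify.SplitSpec(mode=config.split_mode,
                                    seed=config.seed + _SEED_SPLIT)
    levels = ([None] if config.levels == "all-features"
              else [int(v) for v in config.levels])

    reports: dict = {}
    rankings: dict = {}
    prediction_rows = []

    if config.split_mode == "leave_one_subject_out":
        reports.update(_run_loso(matrix, split_spec, levels, config, rankings))
    else:
        train_idx, test_idx = classify.split(matrix, split_spec)
        for pool in config.pools:
            rank_rows = train_idx if config.rank_on_train_only else None
            ranking = selection.fisher_rank(matrix, pool, rows=rank_rows)
            rankings[pool] = ranking
            for level in levels:
                if level is None:
                    ids = matrix.pool_columns(pool)
                else:
                    ids = selection.level_subset(ranking, level).feature_ids
                reps, preds, _ = _evaluate_models(
                    matrix, ids, train_idx, test_idx, config, config.models)
                for name, rep in reps.items():
                    reports[(pool, level, name)] = rep
                    labels, scores = preds[name]
                    for row_i, lab, sc in zip(test_idx, labels, scores):
                        prediction_rows.append({
                            "pool": pool,
                            "level": "all" if level is None else level,
                            "model": name,
                            "subject_id": matrix.subject_ids[row_i],
                            "epoch_row": int(row_i),
                            "true_label": int(matrix.labels[row_i]),
                            "pred_label": int(lab),
                            "score": float(sc),
                        })

    table = evaluate.report_table(reports)
    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": len(cohort),
        "n_epochs": len(matrix),
        "split_mode": config.split_mode,
        "reports": {
            f"{pool}/{'all' if level is None else level}/{model}":
                _jsonable(rep.as_row()) | {"kappa_band": rep.kappa_band}
            for (pool, level, model), rep in reports.items()
        },
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pool, ranking in rankings.items():
            ranking.to_csv(out / f"ranking_{pool}.csv")
        table.to_csv(out / "report_table.csv", index=False)
        if prediction_rows:
            pd.DataFrame(prediction_rows).to_csv(out / "predictions.csv",
                                                 index=False)
        with open(out / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)

    bundle["table"] = table
    bundle["report_objects"] = reports
    return bundle


def _run_loso(matrix, split_spec, levels, config, rankings):
    """Leave-one-subject-out: per fold, rank on training rows, fit, test.

    Reported per (pool, level, model) from predictions pooled over folds.
    """
    folds = list(classify.split(matrix, split_spec))
    collected: dict = {}
    for pool in config.pools:
        for level in levels:
            for name in config.models:
                collected[(pool, level, name)] = ([], [], [])  # y, yhat, score
    for _sid, train_idx, test_idx in folds:
        for pool in config.pools:
            ranking = selection.fisher_rank(matrix, pool, rows=train_idx)
            rankings.setdefault(pool, ranking)
            for level in levels:
                if level is None:
                    ids = matrix.pool_columns(pool)
                else:
                    ids = selection.level_subset(ranking, level).feature_ids
                _, preds, _ = _evaluate_models(
                    matrix, ids, train_idx, test_idx, config, config.models,
                    compute_reports=False)
                for name in config.models:
                    labels, scores = preds[name]
                    y, yh, sc = collected[(pool, level, name)]
                    y.extend(matrix.labels[test_idx])
                    yh.extend(labels)
                    sc.extend(scores)
    reports = {}
    for key, (y, yh, sc) in collected.items():
        reports[key] = evaluate.evaluate_predictions(
            np.asarray(y), np.asarray(yh), np.asarray(sc))
    return reports
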