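"""End-to-end orchestration: phantom -> features -> stability -> univariate
-> multivariate, with archived config, per-stage artifacts and checksums.

Every stage is a pure function of its inputs plus the run configuration, so
rerunning with the same config reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ExtractionConfig, extract_cohort, family_map
from .multivariate import MODEL_NAMES, external_validate, fit_classifiers, lasso_select
from .phantom import PhantomConfig, generate_cohort
from .stability import attach_size_screen, stability_filter
from .types import wide_to_tidy
from .univariate import univariate_table

log = logging.getLogger("lesionrad")

__all__ = ["RunConfig", "run_all", "RunResult"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    phantom: PhantomConfig = PhantomConfig()
    extraction: ExtractionConfig = ExtractionConfig()
    stability_threshold: float = 0.8
    size_cut_mm: float = 20.0
    alpha: float = 0.05
    n_validation: int = 24  # held-out patients (training gets the rest)
    cv_folds: int = 10
    cv_seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        ex = d.pop("extraction", {})
        for key in ("lesions_per_patient", "diameter_mm", "voxel_spacing_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(phantom=PhantomConfig(**ph), extraction=ExtractionConfig(**ex), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    features_r1: pd.DataFrame
    features_r2: pd.DataFrame
    labels: pd.Series
    stability: object
    univariate: pd.DataFrame
    lasso_selected: list[str]
    reports_all: dict
    reports_selected: dict
    external: object
    counts: dict[str, int]
    train_ids: list = field(default_factory=list)
    validation_ids: list = field(default_factory=list)
    outdir: Path | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, checksums: dict) -> None:
    df.to_csv(path)
    checksums[path.name] = _sha256(path)


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the whole analysis on a synthetic cohort.

    Stages: generate the dual-reader phantom cohort; extract per-patient
    features for both readers; keep reader-stable features (ICC >= the
    threshold) and screen them for lesion-size effects; build the
    univariate ROC table on the training cohort; LASSO-select predictors;
    compare classifiers by stratified CV on the training cohort; validate
    the winning selected-predictor model on the held-out cohort.

    When ``outdir`` is given, all tables are written as CSV/JSON together
    with the archived config and a checksum manifest.
    """
    counts: dict[str, int] = {}
    try:
        records = generate_cohort(config.phantom)
    except Exception as exc:  # pragma: no cover - message shaping only
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc
    counts["patients"] = config.phantom.n_patients
    log.info("phantom: %d patients x 2 readers", counts["patients"])

    try:
        feats_r1, labels = extract_cohort(records, config.extraction, reader=1)
        feats_r2, _ = extract_cohort(records, config.extraction, reader=2)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc
    counts["features_extracted"] = feats_r1.shape[1]
    log.info("features: %d per patient", feats_r1.shape[1])

    max_diam = pd.Series(
        {
            rec.patient_id: rec.max_equivalent_diameter_mm()
            for rec in records
            if rec.reader == 1
        }
    )
    try:
        stab = stability_filter(feats_r1, feats_r2, threshold=config.stability_threshold)
        stab = attach_size_screen(
            stab, feats_r1, max_diam, cut_mm=config.size_cut_mm, alpha=config.alpha
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'stability' failed: {exc}") from exc
    counts["features_stable"] = len(stab.retained)
    log.info("stability: %d features retained", counts["features_stable"])

    stable = feats_r1[stab.retained]
    # degenerate-lesion features propagate as NaN; they cannot enter the
    # models, so any incomplete column is dropped here (logged)
    incomplete = [c for c in stable.columns if stable[c].isna().any()]
    if incomplete:
        log.warning("dropping incomplete features: %s", incomplete)
        stable = stable.drop(columns=incomplete)
    # deterministic, label-stratified train/validation split
    rng = np.random.default_rng(config.cv_seed)
    ids = np.array(stable.index)
    val_ids: list = []
    n_val = min(config.n_validation, len(ids) - 2)
    lab_arr = labels.loc[ids].to_numpy()
    for cls in (0, 1):
        cls_ids = ids[lab_arr == cls]
        take = int(round(n_val * len(cls_ids) / len(ids)))
        val_ids.extend(rng.choice(cls_ids, size=take, replace=False))
    val_ids = sorted(val_ids)
    train_ids = sorted(set(ids) - set(val_ids))
    X_train, y_train = stable.loc[train_ids], labels.loc[train_ids]
    X_val, y_val = stable.loc[val_ids], labels.loc[val_ids]
    counts["train_patients"] = len(train_ids)
    counts["validation_patients"] = len(val_ids)

    try:
        uni = univariate_table(X_train, y_train, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'univariate' failed: {exc}") from exc
    counts["features_significant"] = int(uni["significant"].sum())

    try:
        sel = lasso_select(X_train, y_train, folds=config.cv_folds, seed=config.cv_seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'lasso' failed: {exc}") from exc
    counts["predictors_selected"] = len(sel.selected)
    log.info("lasso: selected %s", sel.selected)

    try:
        reports_all = fit_classifiers(
            X_train, y_train, config.models, folds=config.cv_folds, seed=config.cv_seed
        )
        sel_cols = sel.selected if sel.selected else list(stable.columns)
        reports_sel = fit_classifiers(
            X_train[sel_cols], y_train, config.models,
            folds=config.cv_folds, seed=config.cv_seed,
        )
        winner = next(r for r in reports_sel.values() if r.winner)
        external = external_validate(
            winner.model, X_train[sel_cols], y_train, X_val[sel_cols], y_val,
            seed=config.cv_seed,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'multivariate' failed: {exc}") from exc

    result = RunResult(
        config=config,
        features_r1=feats_r1,
        features_r2=feats_r2,
        labels=labels,
        stability=stab,
        univariate=uni,
        lasso_selected=sel.selected,
        reports_all=reports_all,
        reports_selected=reports_sel,
        external=external,
        counts=counts,
        train_ids=list(train_ids),
        validation_ids=list(val_ids),
    )
    if outdir is not None:
        result.outdir = _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: RunResult, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    cfg_path = outdir / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(result.config.to_dict()))
    checksums[cfg_path.name] = _sha256(cfg_path)
    fam = family_map()
    _write_csv(
        wide_to_tidy(result.features_r1, reader=1, families=fam),
        outdir / "features_reader1.csv", checksums,
    )
    _write_csv(
        wide_to_tidy(result.features_r2, reader=2, families=fam),
        outdir / "features_reader2.csv", checksums,
    )
    _write_csv(result.labels.to_frame(), outdir / "labels.csv", checksums)
    _write_csv(result.stability.to_frame(), outdir / "stability.csv", checksums)
    _write_csv(result.univariate, outdir / "univariate.csv", checksums)
    models_json = {
        "all_stable_predictors": {k: v.to_dict() for k, v in result.reports_all.items()},
        "lasso_predictors": {k: v.to_dict() for k, v in result.reports_selected.items()},
        "lasso_selected": result.lasso_selected,
        "external_validation": result.external.to_dict(),
        "counts": result.counts,
    }
    mj = outdir / "model_reports.json"
    mj.write_text(json.dumps(models_json, indent=2, default=float))
    checksums[mj.name] = _sha256(mj)
    (outdir / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return outdir
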