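"""End-to-end experiment: cohort -> features -> split -> selection -> DPL -> metrics.

The flow mirrors the study design: the cohort is split (stratified, ~2:1)
into a cross-validation set and a held-out test set; sparse-representation
feature selection and the sequential forward search run on the
cross-validation set only; the dictionary-pair classifier is then trained
on the full cross-validation set with the chosen subset and evaluated on
the untouched test set. Each of the three modalities is modelled alone and
the combined model re-runs selection on the 1584-column concatenation of
all three.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dpl as dpl_mod
from .containers import AGGRESSIVE, MODALITIES, FeatureMatrix, MultimodalCase
from .evaluation import MetricsReport, metric_panel, split_cohort
from .features import ExtractionConfig, extract_all
from .phantoms import PhantomConfig, generate_cohort, read_cohort
from .selection import (
    SelectionModel,
    SubsetSearchTrace,
    fit_sparse_weights,
    forward_search,
    standardize_columns,
)

logger = logging.getLogger("ptcrad")

COMBINED = "combined"


@dataclass
class RunConfig:
    """One experiment: input source, model list and all stage settings.

    Defaults follow the reference protocol: sparsity control gamma = 0.1,
    DPL regularizer lambda = 0.01, ~2:1 stratified split, forward search
    over subset sizes 5..100 with stratified 5-fold cross-validation.
    """

    phantom: PhantomConfig | None = None
    manifest: str | None = None
    modalities: tuple[str, ...] = (*MODALITIES, COMBINED)
    gamma: float = 0.1
    lam: float = 0.01
    n_atoms: int | None = None
    folds: int = 5
    size_range: tuple[int, int] = (5, 100)
    split_fraction: float = 2.0 / 3.0
    seed: int = 0
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.lam <= 0:
            raise ValueError("gamma and lambda must be positive")
        if (self.phantom is None) == (self.manifest is None):
            raise ValueError("exactly one of phantom / manifest must be given")
        for m in self.modalities:
            if m not in (*MODALITIES, COMBINED):
                raise ValueError(f"unknown model {m!r}")


@dataclass
class ModelResult:
    """Everything fitted and measured for one modality model."""

    name: str
    selection: SelectionModel
    trace: SubsetSearchTrace
    selected_features: list[str]
    classifier: dpl_mod.DictionaryPairModel
    cv_report: MetricsReport
    test_report: MetricsReport
    cv_scores: np.ndarray
    test_scores: np.ndarray


@dataclass
class ExperimentResult:
    config: RunConfig
    models: dict[str, ModelResult]
    cv_case_ids: list[str]
    test_case_ids: list[str]

    def report_table(self, split: str = "test") -> pd.DataFrame:
        rows = []
        for name, mr in self.models.items():
            rep = mr.test_report if split == "test" else mr.cv_report
            rows.append(rep.to_row())
        return pd.DataFrame(rows)


def _load_cases(config: RunConfig) -> list[MultimodalCase]:
    if config.phantom is not None:
        return generate_cohort(config.phantom)
    return read_cohort(config.manifest)


def _feature_matrix_for(model_name: str, per_modality: Mapping[str, FeatureMatrix]) -> FeatureMatrix:
    from .containers import concat_feature_matrices

    if model_name == COMBINED:
        return concat_feature_matrices([per_modality[m] for m in MODALITIES])
    return per_modality[model_name]


def _out_of_fold_eval(F_cv, y_cv, subset, config, seed):
    """Out-of-fold scores/labels on the cross-validation split."""
    from sklearn.model_selection import StratifiedKFold

    X = F_cv.values[:, subset]
    y = F_cv.labels.to_numpy()
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    pred = np.empty(len(y), dtype=object)
    for fold_i, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, mean, scale = standardize_columns(X[tr])
        Xva, _, _ = standardize_columns(X[va], mean, scale)
        model = dpl_mod.train(
            Xtr, y[tr], lam=config.lam, n_atoms=config.n_atoms, seed=seed + fold_i,
            standardize=False,
        )
        result = dpl_mod.classify(model, Xva)
        scores[va] = dpl_mod.decision_score(result, AGGRESSIVE)
        pred[va] = result.labels
    return scores, pred.astype(str)


def run_model(
    name: str,
    F_all: FeatureMatrix,
    cv_ids: Sequence[str],
    test_ids: Sequence[str],
    config: RunConfig,
) -> ModelResult:
    """Selection + forward search on the CV split, final fit, evaluation."""
    F_cv = F_all.select_cases(cv_ids)
    F_test = F_all.select_cases(test_ids)
    y_cv = F_cv.labels.to_numpy()

    X_cv_std, _, _ = standardize_columns(F_cv.values)
    sel = fit_sparse_weights(
        X_cv_std,
        F_cv.encoded_labels(),
        gamma=config.gamma,
        feature_names=F_cv.feature_names,
        fit_case_ids=list(cv_ids),
    )

    lo, hi = config.size_range
    hi = min(hi, F_cv.n_features)
    trace = forward_search(
        F_cv.values,
        y_cv,
        sel.ranking,
        size_range=(min(lo, hi), hi),
        cv_folds=config.folds,
        seed=config.seed,
        classifier_factory=lambda Xtr, ytr, fold_seed: dpl_mod.train(
            Xtr, ytr, lam=config.lam, n_atoms=config.n_atoms, seed=fold_seed,
            n_iter=25, standardize=False,
        ),
    )
    subset = trace.best_subset
    selected_names = [F_cv.feature_names[j] for j in subset]
    logger.info("%s: best subset size %d (cv acc %.3f)", name, trace.best_size,
                trace.cv_accuracy.max())

    classifier = dpl_mod.train(
        F_cv.values[:, subset],
        y_cv,
        lam=config.lam,
        n_atoms=config.n_atoms,
        seed=config.seed,
        feature_names=selected_names,
        fit_case_ids=list(cv_ids),
    )

    test_result = dpl_mod.classify(classifier, F_test.values[:, subset], feature_names=selected_names)
    test_scores = dpl_mod.decision_score(test_result, AGGRESSIVE)
    test_report = metric_panel(
        F_test.labels.to_numpy(), test_scores, test_result.labels,
        model_name=name,
    )

    cv_scores, cv_pred = _out_of_fold_eval(F_cv, y_cv, subset, config, config.seed)
    cv_report = metric_panel(y_cv, cv_scores, cv_pred, model_name=name)

    return ModelResult(
        name=name,
        selection=sel,
        trace=trace,
        selected_features=selected_names,
        classifier=classifier,
        cv_report=cv_report,
        test_report=test_report,
        cv_scores=cv_scores,
        test_scores=test_scores,
    )


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full experiment described by ``config``.

    Deterministic: identical configs produce identical results, artifacts
    included.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    try:
        cases = _load_cases(config)
        logger.info("loaded %d cases", len(cases))
        per_modality = {
            m: extract_all(cases, config.extraction, modalities=(m,)) for m in MODALITIES
        }
        cv_cases, test_cases = split_cohort(cases, config.split_fraction, config.seed)
        cv_ids = [c.case_id for c in cv_cases]
        test_ids = [c.case_id for c in test_cases]
        logger.info("split: %d cross-validation / %d test", len(cv_ids), len(test_ids))

        models = {}
        for name in config.modalities:
            F_all = _feature_matrix_for(name, per_modality)
            models[name] = run_model(name, F_all, cv_ids, test_ids, config)

        result = ExperimentResult(
            config=config, models=models, cv_case_ids=cv_ids, test_case_ids=test_ids
        )
        if out:
            _write_artifacts(result, per_modality, out)
        return result
    finally:
        if out:
            logger.removeHandler(handler)
            handler.close()


def _write_artifacts(result: ExperimentResult, per_modality, out: Path) -> None:
    from .containers import concat_feature_matrices

    concat_feature_matrices([per_modality[m] for m in MODALITIES]).to_csv(out / "features.csv")
    result.config.extraction.to_json(out / "extraction_config.json")
    cfg = {
        "gamma": result.config.gamma,
        "lambda": result.config.lam,
        "folds": result.config.folds,
        "size_range": list(result.config.size_range),
        "split_fraction": result.config.split_fraction,
        "seed": result.config.seed,
        "modalities": list(result.config.modalities),
        "cv_case_ids": result.cv_case_ids,
        "test_case_ids": result.test_case_ids,
    }
    (out / "run_config.json").write_text(json.dumps(cfg, indent=2))

    reports = {}
    for name, mr in result.models.items():
        pd.DataFrame(
            {"size": mr.trace.subset_sizes, "cv_accuracy": mr.trace.cv_accuracy}
        ).to_csv(out / f"trace_{name}.csv", index=False)
        (out / f"selected_{name}.json").write_text(json.dumps(mr.selected_features, indent=2))
        reports[name] = {
            "cross_validation": mr.cv_report.to_dict(),
            "test": mr.test_report.to_dict(),
        }
    (out / "reports.json").write_text(json.dumps(reports, indent=2))
    result.report_table("test").to_csv(out / "table_test.csv", index=False)
    result.report_table("cv").to_csv(out / "table_cross_validation.csv", index=False)
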