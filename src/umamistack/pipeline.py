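"""End-to-end training and prediction for the umami meta-predictor.

Training runs the full stack: encode the peptides under all seven
schemes, build the 42-model baseline grid, generate out-of-fold PF/CF
meta-features, let the GA select informative meta-feature columns while
tuning the meta-SVM cost C, then fit the final RBF-kernel SVM on the
selected columns and refit every baseline on the full training set for
inference. The shipped default representation is PF (probabilistic
features); CF and CPF are selectable.

Cross-validated evaluation of the whole pipeline is *nested*: inside
each outer training partition the stacking CV, the GA selection and the
meta-SVM fit are all re-run from scratch, so no information from an
outer test fold can reach any training stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .baselines import (
    FittedBaseline,
    PlattScaledSVC,
    build_model_grid,
    derive_seed,
)
from .encoders import EncodingError
from .ga import GAConfig, GAResult, run_ga_sar
from .io import DatasetError, LabeledDataset, Peptide
from .meta import (
    StackingPlan,
    assemble,
    fit_full_grid,
    generate_training_meta_features,
    inference_meta_features,
    probability_to_class,
)
from .metrics import (
    CVProtocol,
    CVResult,
    MetricsReport,
    metrics_from_predictions,
    repeated_stratified_cv,
)


@dataclass
class UmamiPredictor:
    """A trained meta-predictor with everything needed for inference."""

    mode: str
    fitted_baselines: list[FittedBaseline]
    selected_features: list[str]
    C: int
    meta_classifier: PlattScaledSVC
    ga_result: GAResult
    seed: int
    plan: StackingPlan

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "UmamiPredictor":
        return joblib.load(path)


@dataclass
class PredictionRecord:
    """Per-peptide prediction; ``error`` is set when encoding failed."""

    id: str
    probability: float | None
    label: int | None
    error: str | None = None


def train_umami_predictor(
    ds: LabeledDataset,
    mode: str = "PF",
    ga_cfg: GAConfig | None = None,
    plan: StackingPlan | None = None,
    seed: int = 0,
) -> UmamiPredictor:
    """Train the full meta-predictor; reproducible given (ds, config, seed)."""
    counts = np.bincount(ds.labels, minlength=2)
    plan = plan or StackingPlan(seed=derive_seed(seed, "stacking"))
    if counts.min() < plan.k:
        raise ValueError(
            f"each class needs >= {plan.k} members for stacking, "
            f"got {counts.tolist()}"
        )
    grid = build_model_grid()
    pf, cf = generate_training_meta_features(ds, grid, plan)
    M = assemble(pf, cf, mode)
    ga_cfg = ga_cfg or GAConfig(seed=derive_seed(seed, "ga"))
    ga = run_ga_sar(M, ds.labels, ga_cfg)
    if not ga.selected_names:
        raise RuntimeError("GA returned an empty feature mask")
    meta = PlattScaledSVC(C=ga.C, random_state=derive_seed(seed, "meta-svm"))
    meta.fit(M[ga.selected_names].to_numpy(), ds.labels)
    fitted = fit_full_grid(ds, grid, seed=plan.seed)
    return UmamiPredictor(
        mode=mode,
        fitted_baselines=fitted,
        selected_features=ga.selected_names,
        C=ga.C,
        meta_classifier=meta,
        ga_result=ga,
        seed=seed,
        plan=plan,
    )


def predict_probabilities(
    model: UmamiPredictor, peptides: Sequence[Peptide] | LabeledDataset
) -> np.ndarray:
    """P(umami) for valid peptides (raises on any encoding failure)."""
    M = inference_meta_features(model.fitted_baselines, peptides, model.mode)
    X = M[model.selected_features].to_numpy()
    proba = model.meta_classifier.predict_proba(X)
    pos = int(np.flatnonzero(model.meta_classifier.classes_ == 1)[0])
    return proba[:, pos]


def predict(
    model: UmamiPredictor, peptides: Sequence[Peptide] | LabeledDataset
) -> list[PredictionRecord]:
    """Per-peptide predictions; invalid peptides yield error records while
    the remaining peptides are still scored."""
    plist = (
        peptides.peptides if isinstance(peptides, LabeledDataset) else list(peptides)
    )
    valid: list[Peptide] = []
    records: dict[int, PredictionRecord] = {}
    keep: list[int] = []
    for i, p in enumerate(plist):
        try:
            # cheap precondition probe: the strictest encoders need L >= 2
            if len(p) < 2:
                raise EncodingError("DPC/CTDT need L >= 2")
            valid.append(p)
            keep.append(i)
        except EncodingError as exc:
            records[i] = PredictionRecord(p.id, None, None, error=str(exc))
    if valid:
        probs = predict_probabilities(model, valid)
        for i, p, pr in zip(keep, valid, probs):
            records[i] = PredictionRecord(
                p.id, float(pr), int(probability_to_class(pr))
            )
    return [records[i] for i in range(len(plist))]


def _check_disjoint(ds_train: LabeledDataset, ds_test: LabeledDataset) -> None:
    shared = set(ds_train.sequences) & set(ds_test.sequences)
    if shared:
        raise DatasetError(
            f"train and test share {len(shared)} sequence(s), "
            f"e.g. {next(iter(shared))!r}"
        )


def evaluate_model(
    ds_train: LabeledDataset,
    ds_test: LabeledDataset,
    mode: str = "PF",
    ga_cfg: GAConfig | None = None,
    plan: StackingPlan | None = None,
    protocol: CVProtocol | None = None,
    seed: int = 0,
) -> tuple[CVResult, MetricsReport]:
    """Nested cross-validation on the training set plus an independent
    test evaluation from a single full-train model."""
    _check_disjoint(ds_train, ds_test)

    def fit_score(tr: LabeledDataset, te: LabeledDataset, fold_seed: int) -> np.ndarray:
        inner_plan = plan or StackingPlan(seed=derive_seed(fold_seed, "stacking"))
        inner_cfg = ga_cfg or GAConfig(seed=derive_seed(fold_seed, "ga"))
        m = train_umami_predictor(
            tr, mode=mode, ga_cfg=inner_cfg, plan=inner_plan, seed=fold_seed
        )
        return predict_probabilities(m, te)

    cv = repeated_stratified_cv(ds_train, fit_score, protocol or CVProtocol())
    full = train_umami_predictor(ds_train, mode=mode, ga_cfg=ga_cfg, plan=plan, seed=seed)
    scores = predict_probabilities(full, ds_test)
    independent = metrics_from_predictions(ds_test.labels, scores)
    return cv, independent
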