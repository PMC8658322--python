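"""Stacked meta-feature generation from the baseline grid.

Each of the 42 baselines contributes one column to the learned
representation of a peptide:

* **PF** (probabilistic feature): the baseline's P(umami) in [0, 1];
* **CF** (class feature): PF thresholded at 0.5 (strictly greater maps
  to 1, so exactly 0.5 maps to 0);
* **CPF**: the 84-column concatenation [PF | CF].

For training data the PF entries are *out-of-fold* predictions under a
single stratified k-fold partition shared by all baselines: the model
scoring a sample never saw that sample during training, which is what
keeps the stacked representation honest (resubstitution scores would
leak the training labels into the meta-level). A resubstitution variant
is available behind a flag for diagnostics only. At inference time the
columns come from baselines refit on the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .baselines import (
    BaselineSpec,
    FittedBaseline,
    build_model_grid,
    derive_seed,
    fit_baseline,
    predict_proba,
)
from .encoders import encode_dataset
from .io import LabeledDataset, Peptide

MODES: tuple[str, ...] = ("PF", "CF", "CPF")


@dataclass(frozen=True)
class StackingPlan:
    """Cross-validated stacking configuration.

    k folds (default 10), stratified by class; one fold-assignment seed
    shared by all baselines so their columns are comparable.
    """

    k: int = 10
    seed: int = 0
    refit_full: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def probability_to_class(p: float | np.ndarray) -> int | np.ndarray:
    """Threshold a probability at 0.5 (strictly greater than 0.5 -> 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probability outside [0, 1]")
    out = (arr > 0.5).astype(np.int64)
    return int(out) if out.ndim == 0 else out


def _encode_for_grid(
    ds: LabeledDataset | list[Peptide], grid: list[BaselineSpec]
) -> dict[str, pd.DataFrame]:
    schemes = {spec.encoding for spec in grid}
    return {s: encode_dataset(ds, s) for s in sorted(schemes)}


def generate_training_meta_features(
    ds: LabeledDataset,
    grid: list[BaselineSpec] | None = None,
    plan: StackingPlan | None = None,
    method: str = "oof",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Out-of-fold PF and CF matrices for a training dataset.

    Returns (PF, CF), each n x len(grid), columns in grid order and named
    after the baselines. ``method="resub"`` scores each sample with a
    model trained on the full dataset (leaky; diagnostics only).
    """
    grid = grid if grid is not None else build_model_grid()
    plan = plan or StackingPlan()
    if method not in ("oof", "resub"):
        raise ValueError(f"method must be 'oof' or 'resub', got {method!r}")
    y = ds.labels
    counts = np.bincount(y, minlength=2)
    if method == "oof" and counts.min() < plan.k:
        raise ValueError(
            f"each class needs >= k={plan.k} members, got {counts.tolist()}"
        )
    features = _encode_for_grid(ds, grid)
    pf = np.empty((len(ds), len(grid)))
    if method == "resub":
        for j, spec in enumerate(grid):
            X = features[spec.encoding].to_numpy()
            model = fit_baseline(spec, X, y, seed=plan.seed, check_dimension=False)
            pf[:, j] = predict_proba(model, X)
    else:
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        folds = list(skf.split(np.zeros(len(ds)), y))
        for j, spec in enumerate(grid):
            X = features[spec.encoding].to_numpy()
            for train_idx, test_idx in folds:
                model = fit_baseline(
                    spec, X[train_idx], y[train_idx],
                    seed=plan.seed, check_dimension=False,
                )
                pf[test_idx, j] = predict_proba(model, X[test_idx])
    names = [spec.name for spec in grid]
    pf_df = pd.DataFrame(pf, index=ds.ids, columns=names)
    pf_df.attrs["mode"] = "PF"
    cf_df = pd.DataFrame(
        probability_to_class(pf), index=ds.ids, columns=names
    )
    cf_df.attrs["mode"] = "CF"
    return pf_df, cf_df


def assemble(pf: pd.DataFrame, cf: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Select the meta-feature representation: PF, CF, or [PF | CF]."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(pf) != len(cf):
        raise ValueError(f"row mismatch: PF has {len(pf)}, CF has {len(cf)}")
    if mode == "PF":
        out = pf.copy()
    elif mode == "CF":
        out = cf.copy()
    else:
        cf_renamed = cf.add_suffix("#class")
        out = pd.concat([pf, cf_renamed.set_index(pf.index)], axis=1)
    out.attrs["mode"] = mode
    return out


def fit_full_grid(
    ds: LabeledDataset,
    grid: list[BaselineSpec] | None = None,
    seed: int = 0,
) -> list[FittedBaseline]:
    """Refit every baseline on the full training set (inference models)."""
    grid = grid if grid is not None else build_model_grid()
    features = _encode_for_grid(ds, grid)
    return [
        fit_baseline(
            spec, features[spec.encoding].to_numpy(), ds.labels,
            seed=seed, check_dimension=False,
        )
        for spec in grid
    ]


def inference_meta_features(
    fitted_full: list[FittedBaseline],
    peptides: LabeledDataset | list[Peptide],
    mode: str = "PF",
) -> pd.DataFrame:
    """Meta-features for new peptides from full-training-set baselines."""
    if not fitted_full:
        raise ValueError("no fitted baselines supplied")
    grid = [m.spec for m in fitted_full]
    features = _encode_for_grid(peptides, grid)
    plist = peptides.peptides if isinstance(peptides, LabeledDataset) else peptides
    pf = np.empty((len(plist), len(grid)))
    for j, model in enumerate(fitted_full):
        pf[:, j] = predict_proba(model, features[model.spec.encoding].to_numpy())
    names = [m.spec.name for m in fitted_full]
    ids = [p.id for p in plist]
    pf_df = pd.DataFrame(pf, index=ids, columns=names)
    pf_df.attrs["mode"] = "PF"
    cf_df = pd.DataFrame(probability_to_class(pf), index=ids, columns=names)
    cf_df.attrs["mode"] = "CF"
    return assemble(pf_df, cf_df, mode)
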