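"""The 6 x 7 grid of baseline probability models.

Six classical learners (ET, KNN, LR, PLS, RF, SVM) are each paired with
the seven sequence encodings, giving 42 baseline models named
``ALGORITHM-ENCODING`` (e.g. ``RF-PAAC``). Each fitted baseline exposes a
single contract: a probability of the positive (umami) class in [0, 1]
per input peptide.

Hyperparameters are pinned explicitly rather than inherited from library
defaults, so behaviour is reproducible:

* ET / RF: 100 trees
* KNN: k = 5, Euclidean distance
* LR: L2 penalty, C = 1
* SVM: RBF kernel, C = 1, gamma scaled by 1/(d * Var(X)), Platt-style
  monotone probability calibration
* PLS: 2 components (capped by feature count and sample count),
  regression on {0, 1} targets with the response clipped into [0, 1]

Stochastic trainers are seeded from a master seed combined with the
baseline name, so the whole grid is reproducible from one integer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .encoders import DIMENSIONS, SCHEMES

ALGORITHMS: tuple[str, ...] = ("ET", "KNN", "LR", "PLS", "RF", "SVM")


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable sub-seed below 2^31 from a master seed and context labels."""
    key = ":".join([str(master_seed), *map(str, parts)])
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31)


@dataclass(frozen=True)
class BaselineSpec:
    """One (algorithm, encoding) cell of the baseline grid."""

    algorithm: str
    encoding: str
    hyperparams: tuple[tuple[str, Any], ...] = ()

    @property
    def name(self) -> str:
        return f"{self.algorithm}-{self.encoding}"

    @property
    def params(self) -> dict[str, Any]:
        return dict(self.hyperparams)


def build_model_grid() -> list[BaselineSpec]:
    """All 42 baseline specs, algorithm-major then encoding-minor order."""
    return [
        BaselineSpec(algorithm=a, encoding=e) for a in ALGORITHMS for e in SCHEMES
    ]


class PlattScaledSVC:
    """RBF-kernel SVM with a monotone score-to-probability mapping.

    A logistic (Platt-style) sigmoid is fitted on the training decision
    scores, so predicted probabilities are a monotone transform of the
    SVM margin and lie in [0, 1].
    """

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state
        self._svc: SVC | None = None
        self._platt: LogisticRegression | None = None
        self.classes_ = np.array([0, 1])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlattScaledSVC":
        self._svc = SVC(kernel="rbf", C=self.C, gamma="scale",
                        random_state=self.random_state)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        d = self._svc.decision_function(X).reshape(-1, 1)
        self._platt = LogisticRegression(max_iter=1000)
        self._platt.fit(d, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(d)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(X)


class PLSProbabilityModel:
    """Partial-least-squares regression used as a binary scorer.

    Regresses on {0, 1} targets and clips the continuous response into
    [0, 1] as a pseudo-probability.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components
        self._pls: PLSRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSProbabilityModel":
        nc = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self._pls = PLSRegression(n_components=nc)
        self._pls.fit(X, y.astype(float))
        return self

    def raw_response(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._pls.predict(X)).ravel()

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.raw_response(X), 0.0, 1.0)


def _make_estimator(spec: BaselineSpec, seed: int):
    p = spec.params
    if spec.algorithm == "ET":
        return ExtraTreesClassifier(
            n_estimators=p.get("n_estimators", 100), random_state=seed
        )
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100), random_state=seed
        )
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5), metric="euclidean"
        )
    if spec.algorithm == "LR":
        # L2 penalty with C=1 (the library default, pinned here)
        return LogisticRegression(C=p.get("C", 1.0), max_iter=2000, random_state=seed)
    if spec.algorithm == "SVM":
        return PlattScaledSVC(C=p.get("C", 1.0), random_state=seed)
    if spec.algorithm == "PLS":
        return PLSProbabilityModel(n_components=p.get("n_components", 2))
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


@dataclass
class FittedBaseline:
    """A trained baseline with its spec and a training-data fingerprint."""

    spec: BaselineSpec
    estimator: Any
    training_fingerprint: str
    n_features: int


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def fit_baseline(
    spec: BaselineSpec,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    check_dimension: bool = True,
) -> FittedBaseline:
    """Train one baseline; deterministic given (spec, X, y, seed).

    KNN's neighbourhood size is capped at the training-set size so small
    folds remain fittable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and row-parallel to y")
    if check_dimension and X.shape[1] != DIMENSIONS[spec.encoding]:
        raise ValueError(
            f"{spec.name}: expected {DIMENSIONS[spec.encoding]} features, "
            f"got {X.shape[1]}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError(f"{spec.name}: training labels contain a single class")
    est = _make_estimator(spec, derive_seed(seed, spec.name))
    if isinstance(est, KNeighborsClassifier) and est.n_neighbors > X.shape[0]:
        est.set_params(n_neighbors=X.shape[0])
    est.fit(X, y)
    return FittedBaseline(
        spec=spec,
        estimator=est,
        training_fingerprint=_fingerprint(X, y),
        n_features=X.shape[1],
    )


def predict_proba(model: FittedBaseline, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """P(umami) per row, always in [0, 1]; empty input gives empty output."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"{model.spec.name}: expected width {model.n_features}, "
            f"got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    est = model.estimator
    if isinstance(est, PLSProbabilityModel):
        return est.predict_proba_positive(X)
    proba = est.predict_proba(X)
    pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
    return proba[:, pos_col]
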