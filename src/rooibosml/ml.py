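"""The four ML comparison classifiers: LR, SVM, RF, kNN.

Each arm is trained by exhaustive grid search under stratified k-fold
cross-validation (selection by mean CV accuracy, ties broken by grid order)
and refit on the full training set. Distance/margin methods (LR, SVM, kNN)
standardize features with training-set statistics because the assays differ
by an order of magnitude (TEAC ~2400 vs TPC ~280); random forests are
scale-invariant and skip standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ML_METHODS: tuple[str, ...] = ("LR", "SVM", "RF", "KNN")

#: Default hyperparameter grids — small, standard, overridable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "SVM": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0],
        "kernel": ["linear", "rbf"],
        "gamma": ["scale", 0.1, 1.0],
    },
    "RF": {"n_estimators": [100, 300], "max_depth": [2, 4, None]},
    "KNN": {"n_neighbors": [1, 3, 5, 7, 9], "weights": ["uniform", "distance"]},
}

#: Single-candidate grids: grid search degenerates to a plain fit. Used for
#: the full 84-cell jackknife sweep, where 8232 separate optimizations must
#: stay tractable on one CPU.
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [1.0]},
    "SVM": {"C": [1.0], "kernel": ["linear"], "gamma": ["scale"]},
    "RF": {"n_estimators": [50], "max_depth": [4]},
    "KNN": {"n_neighbors": [5], "weights": ["uniform"]},
}


@dataclass(frozen=True)
class MLMethodSpec:
    """Configuration for one ML arm."""

    method: str
    grid: dict[str, list] = field(default_factory=dict)
    standardize: bool | None = None  # None -> method default (off for RF)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ML_METHODS:
            raise ValueError(f"method {self.method!r} not in {ML_METHODS}")
        grid = self.grid or {k: list(v) for k, v in DEFAULT_GRIDS[self.method].items()}
        for name, candidates in grid.items():
            if not candidates:
                raise ValueError(f"empty candidate list for hyperparameter {name!r}")
        object.__setattr__(self, "grid", grid)
        if self.standardize is None:
            object.__setattr__(self, "standardize", self.method != "RF")

    @property
    def n_candidates(self) -> int:
        out = 1
        for v in self.grid.values():
            out *= len(v)
        return out


@dataclass
class FittedArm:
    """A trained ML arm: chosen hyperparameters plus the fitted pipeline."""

    method_spec: MLMethodSpec
    chosen_hyperparameters: dict[str, Any]
    pipeline: Pipeline
    cv_folds: int


def default_method_specs(seed: int = 0, reduced: bool = False) -> dict[str, MLMethodSpec]:
    grids = REDUCED_GRIDS if reduced else DEFAULT_GRIDS
    return {
        m: MLMethodSpec(method=m, grid={k: list(v) for k, v in grids[m].items()}, seed=seed)
        for m in ML_METHODS
    }


def _base_estimator(spec: MLMethodSpec):
    if spec.method == "LR":
        return LogisticRegression(max_iter=5000)
    if spec.method == "SVM":
        return SVC()
    if spec.method == "RF":
        return RandomForestClassifier(random_state=spec.seed)
    return KNeighborsClassifier()


def _build_pipeline(spec: MLMethodSpec) -> Pipeline:
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", _base_estimator(spec)))
    return Pipeline(steps)


def train_arm(
    spec: MLMethodSpec,
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 3,
) -> FittedArm:
    """Grid search with stratified CV, then refit on the full training set.

    A grid with a single candidate combination skips cross-validation and
    fits directly. Deterministic given (spec, data, cv_folds).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training data contains a single class: {classes.tolist()}")
    if X.shape[0] < cv_folds:
        raise ValueError(f"n={X.shape[0]} training samples < cv_folds={cv_folds}")

    pipe = _build_pipeline(spec)
    if spec.n_candidates == 1:
        chosen = {k: v[0] for k, v in spec.grid.items()}
        pipe.set_params(**{f"model__{k}": v for k, v in chosen.items()})
        pipe.fit(X, y)
        return FittedArm(spec, chosen, pipe, cv_folds)

    # explicit candidate list preserves grid order so CV-score ties break
    # toward the earliest candidate
    names = list(spec.grid.keys())
    candidates = [
        {f"model__{n}": [v] for n, v in zip(names, combo)}
        for combo in product(*(spec.grid[n] for n in names))
    ]
    search = GridSearchCV(
        pipe,
        param_grid=candidates,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=spec.seed),
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    chosen = {k.removeprefix("model__"): v for k, v in search.best_params_.items()}
    return FittedArm(spec, chosen, search.best_estimator_, cv_folds)


def predict_arm(arm: FittedArm, features: np.ndarray) -> np.ndarray:
    """Apply stored standardization (if any) and the fitted model."""
    X = np.asarray(features, dtype=float)
    expected = arm.pipeline.n_features_in_
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(
            f"query matrix has shape {X.shape}; arm expects (n, {expected})"
        )
    return np.asarray(arm.pipeline.predict(X), dtype=object)
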