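"""Nonlinear BP regressors with subject-grouped splitting and CV.

Four regressor families are supported — RBF-kernel support vector
regression (SVR), random forest (RFR), decision tree (DTR) and
K-nearest-neighbor (KNR) regression — with published default
hyperparameters.  Splitting is always *by subject*: a subject's segments
never straddle the train/test boundary or a CV fold, which would leak
morphology across the split.  Features are standardized inside each
training fold only (fit on train, applied to validation/test), since the
RBF kernel and Euclidean neighbors are scale-sensitive.

The estimator internals are delegated to scikit-learn; this module owns
the grouping, fold construction, grid search bookkeeping and reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelSpec",
    "SplitPlan",
    "TrainedModel",
    "DEFAULT_HYPERPARAMETERS",
    "make_split",
    "train",
    "predict",
]

#: Published defaults per family.
DEFAULT_HYPERPARAMETERS = {
    "svr": {"C": 100.0, "epsilon": 0.1, "kernel": "rbf"},
    "rfr": {"n_estimators": 150, "criterion": "absolute_error", "max_depth": 13},
    "dtr": {
        "criterion": "absolute_error",
        "min_samples_leaf": 17,
        "max_depth": 12,
        "min_samples_split": 5,
    },
    "knr": {"n_neighbors": 51, "leaf_size": 45, "metric": "euclidean"},
}


@dataclass(frozen=True)
class ModelSpec:
    """A regressor family plus hyperparameters and an optional search grid."""

    family: str = "svr"
    hyperparameters: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"family must be one of {sorted(DEFAULT_HYPERPARAMETERS)}, "
                f"got {self.family!r}"
            )

    def resolved(self, n_train: int | None = None, **overrides) -> dict:
        params = {**DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters, **overrides}
        if self.family == "knr" and n_train is not None:
            k = params["n_neighbors"]
            if k >= n_train:
                warnings.warn(
                    f"K={k} >= training size {n_train}; clamping to {n_train - 1}"
                )
                params["n_neighbors"] = max(1, n_train - 1)
        return params

    def build(self, n_train: int | None = None, **overrides) -> Pipeline:
        params = self.resolved(n_train, **overrides)
        if self.family == "svr":
            est = SVR(**params)
        elif self.family == "rfr":
            est = RandomForestRegressor(random_state=self.seed, n_jobs=1, **params)
        elif self.family == "dtr":
            est = DecisionTreeRegressor(random_state=self.seed, **params)
        else:
            est = KNeighborsRegressor(**params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass(frozen=True)
class SplitPlan:
    """Subject-grouped 80/20 split plus CV folds over the training subjects."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_subjects), set(self.test_subjects)
        if train & test:
            raise ValueError("train and test subjects overlap")
        fold_union = set().union(*map(set, self.folds)) if self.folds else set()
        if fold_union != train:
            raise ValueError("CV folds must partition the training subjects")


def make_split(
    subject_ids,
    seed: int = 0,
    test_fraction: float = 0.2,
    n_folds: int = 10,
) -> SplitPlan:
    """Deterministic subject-level 80/20 split with ``n_folds`` CV folds.

    Subjects (deduplicated, order-independent) are shuffled by ``seed``;
    the first 20% become the held-out test set and the rest are dealt into
    folds of near-equal size.
    """
    subjects = sorted({str(s) for s in subject_ids})
    if len(subjects) < max(n_folds, 2):
        raise ValueError(
            f"need at least {max(n_folds, 2)} subjects, got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    n_test = max(1, int(round(test_fraction * len(subjects))))
    test = tuple(sorted(shuffled[:n_test]))
    train = [s for s in shuffled if s not in test]
    if len(train) < n_folds:
        raise ValueError("fewer training subjects than folds")
    folds = tuple(
        tuple(sorted(fold.tolist())) for fold in np.array_split(np.array(train), n_folds)
    )
    return SplitPlan(tuple(sorted(train)), test, folds, seed)


@dataclass
class TrainedModel:
    """A fitted regressor plus the metadata needed to apply it safely."""

    spec: ModelSpec
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    target: str
    best_params: dict
    cv_report: pd.DataFrame

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _check_matrix(X, feature_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = feature_names or tuple(str(i) for i in range(arr.shape[1]))
    if not np.all(np.isfinite(arr)):
        rows, cols = np.where(~np.isfinite(arr))
        raise ValueError(
            f"non-finite features at row {rows[0]}, column {names[cols[0]]!r}"
        )
    return arr, tuple(names)


def _grid_points(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def train(
    X,
    y,
    subject_ids,
    spec: ModelSpec,
    split_plan: SplitPlan,
    target: str = "",
) -> TrainedModel:
    """Fit one regressor on the training subjects of ``split_plan``.

    If ``spec.grid`` is nonempty every grid point is scored by its mean
    CV MAE over the plan's folds (validation fold held out by subject) and
    the best point wins; otherwise the defaults are used directly.  The
    final model is refit on all training-subject rows.  The CV report has
    one row per (grid point, fold) with MAE and RMSE.
    """
    arr, names = _check_matrix(X)
    y = np.asarray(y, dtype=float)
    subject_ids = np.asarray([str(s) for s in subject_ids])
    if not (arr.shape[0] == y.size == subject_ids.size):
        raise ValueError("X, y and subject_ids must be aligned")

    train_mask = np.isin(subject_ids, split_plan.train_subjects)
    Xtr_all, ytr_all, subj_tr = arr[train_mask], y[train_mask], subject_ids[train_mask]

    rows = []
    best_params: dict = {}
    best_mae = np.inf
    for point in _grid_points(spec.grid):
        fold_maes = []
        for fold_idx, fold_subjects in enumerate(split_plan.folds):
            val_mask = np.isin(subj_tr, fold_subjects)
            if not val_mask.any() or val_mask.all():
                continue
            n_fit = int((~val_mask).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                pipe = spec.build(n_train=n_fit, **point)
                pipe.fit(Xtr_all[~val_mask], ytr_all[~val_mask])
            err = ytr_all[val_mask] - pipe.predict(Xtr_all[val_mask])
            mae = float(np.mean(np.abs(err)))
            rmse = float(np.sqrt(np.mean(err**2)))
            fold_maes.append(mae)
            rows.append(
                {"fold": fold_idx, "target": target, "family": spec.family,
                 **{f"param_{k}": v for k, v in point.items()},
                 "mae": mae, "rmse": rmse}
            )
        mean_mae = float(np.mean(fold_maes)) if fold_maes else np.inf
        if mean_mae < best_mae:
            best_mae, best_params = mean_mae, point

    pipe = spec.build(n_train=Xtr_all.shape[0], **best_params)
    pipe.fit(Xtr_all, ytr_all)
    return TrainedModel(
        spec=spec,
        pipeline=pipe,
        feature_names=names,
        target=target,
        best_params=spec.resolved(Xtr_all.shape[0], **best_params),
        cv_report=pd.DataFrame(rows),
    )


def predict(model: TrainedModel, X) -> np.ndarray:
    """Apply a trained model; columns must match training exactly."""
    arr, names = _check_matrix(X, model.feature_names)
    if names != model.feature_names:
        missing = set(model.feature_names) - set(names)
        extra = set(names) - set(model.feature_names)
        raise ValueError(
            f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    out = model.pipeline.predict(arr)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("model produced non-finite predictions")
    return out
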