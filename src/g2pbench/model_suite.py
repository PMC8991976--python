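"""Four-way model benchmark: XGBoost, random forest, CNN and DNN.

Builds the four model families on a one-hot genotype design matrix with
fixed architectures, tunes XGBoost hyperparameters by Bayesian
(GP-surrogate) search over the benchmark's search space, fits each family
with k-fold cross-validation keeping the best fold's model, and evaluates
on a disjoint holdout set with the benchmark's two metrics:

* classification accuracy in percent, and
* RMSE as a percentage of the trait mean for continuous traits, where the
  denominator is the full-dataset trait mean fixed before splitting so
  the metric is comparable across models and datasets.

Cross-model summaries report, per task type, how much better or worse the
tree-ensemble families perform than the average of the two deep-learning
families, plus a best-model tally over every trait x dataset cell.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

from . import nn

__all__ = [
    "TaskSpec",
    "TuneSpace",
    "CVConfig",
    "Metrics",
    "ComparisonSummary",
    "CrossValResult",
    "FAMILY_ORDER",
    "build_model",
    "tune_xgboost",
    "crossval_fit",
    "evaluate",
    "rmse_percent_of_mean",
    "compare_models",
    "save_model",
    "load_model",
    "cnn_min_features",
]

FAMILY_ORDER = ("XGB", "RF", "CNN", "DNN")

# fixed architecture constants
CNN_FILTERS = (12, 10, 8)
CNN_KERNELS = (14, 10, 8)
CNN_DROPOUTS = (0.20, 0.10)  # between conv stages 1-2 and 2-3
CNN_POOL = 2
CNN_DENSE = (48, 32, 16)
DNN_DENSE = (200, 100, 64, 32, 16)
DNN_DROPOUTS = (0.03, 0.02, 0.01)  # after the first three dense layers
RF_TREES = 100
LEARNING_RATE = 0.003  # Adamax
BATCH_DIVISOR = 50  # batch size = n_train / 50


@dataclass(frozen=True)
class TaskSpec:
    """Prediction task: ``binary``, ``multiclass`` (with ``n_classes``) or ``regression``."""

    trait_type: str
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "multiclass", "regression"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "multiclass" and (self.n_classes is None or self.n_classes < 3):
            raise ValueError("multiclass task requires n_classes >= 3")

    @property
    def is_classification(self) -> bool:
        return self.trait_type != "regression"


# ---------------------------------------------------------------------------
# hyperparameter search space
# ---------------------------------------------------------------------------

# (low, high, log-scale, integer)
_TUNE_BOUNDS: dict[str, tuple[float, float, bool, bool]] = {
    "learning_rate": (0.01, 1.0, True, False),
    "min_child_weight": (0.0, 10.0, False, False),
    "max_depth": (0, 50, False, True),  # 0 = unlimited depth under the hist tree method
    "max_delta_step": (0.0, 20.0, False, False),
    "subsample": (0.01, 1.0, False, False),
    "colsample_bytree": (0.01, 1.0, False, False),
    "colsample_bylevel": (0.01, 1.0, False, False),
    "reg_lambda": (1e-9, 1000.0, True, False),
    "reg_alpha": (1e-9, 1.0, True, False),
    "gamma": (1e-9, 0.5, True, False),
    "n_estimators": (50, 200, False, True),
    "scale_pos_weight": (1e-6, 500.0, True, False),
}


@dataclass
class TuneSpace:
    """XGBoost search space: per-parameter (low, high) bounds and a search budget."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (v[0], v[1]) for k, v in _TUNE_BOUNDS.items()}
    )
    n_search_iterations: int = 25
    inner_cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (low, high) in self.bounds.items():
            if name not in _TUNE_BOUNDS:
                raise KeyError(f"unknown tunable parameter {name!r}")
            if not low < high:
                raise ValueError(f"bound for {name} must satisfy low < high")

    def _from_unit(self, u: np.ndarray) -> dict[str, float | int]:
        """Map a point in the unit hypercube to parameter values inside the bounds."""
        out: dict[str, float | int] = {}
        for ui, name in zip(u, self.bounds):
            low, high = self.bounds[name]
            _, _, log, integer = _TUNE_BOUNDS[name]
            if log:
                val = float(np.exp(np.log(low) + ui * (np.log(high) - np.log(low))))
            else:
                val = float(low + ui * (high - low))
            if integer:
                val = int(np.clip(round(val), low, high))
            else:
                val = float(np.clip(val, low, high))
            out[name] = val
        return out


@dataclass
class CVConfig:
    """k-fold cross-validation settings; stratification follows the task type."""

    k: int = 10
    seed: int = 0


@dataclass
class Metrics:
    """Holdout metric plus the per-fold validation scores behind the model choice."""

    metric_name: str  # "accuracy_pct" or "rmse_pct_of_mean"
    holdout: float
    fold_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric_name == "accuracy_pct" and not 0.0 <= self.holdout <= 100.0:
            raise ValueError("accuracy must lie in [0, 100]")
        if self.metric_name == "rmse_pct_of_mean" and self.holdout < 0.0:
            raise ValueError("RMSE%% must be non-negative")


@dataclass
class ComparisonSummary:
    """Cross-model differences and best-model tallies.

    ``xgb_dl_diff_classification`` is the mean over classification cells of
    XGB accuracy minus the unweighted CNN/DNN mean accuracy (positive =
    XGBoost more accurate). ``xgb_dl_diff_regression`` is the mean over
    regression cells of the CNN/DNN mean error minus XGB error (positive =
    XGBoost lower error). RF analogues likewise. ``best_counts`` tallies,
    for every trait x dataset cell, the family with the best holdout metric;
    ties go to the earlier family in FAMILY_ORDER.
    """

    xgb_dl_diff_classification: float | None
    rf_dl_diff_classification: float | None
    xgb_dl_diff_regression: float | None
    rf_dl_diff_regression: float | None
    best_counts: dict[str, int]
    n_cells: int
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# model wrappers — one fit/predict surface across the four families
# ---------------------------------------------------------------------------


class _SupervisedModel:
    family: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SupervisedModel":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_features_in_(self) -> int:
        raise NotImplementedError


class _SKWrapper(_SupervisedModel):
    def __init__(self, estimator: Any, family: str, task: TaskSpec):
        self.estimator = estimator
        self.family = family
        self.task = task

    def fit(self, X, y):
        self.estimator.fit(np.asarray(X), np.asarray(y))
        return self

    def predict(self, X):
        return self.estimator.predict(np.asarray(X))

    @property
    def n_features_in_(self) -> int:
        return int(self.estimator.n_features_in_)

    def get_booster(self):
        return self.estimator.get_booster()


class _NetWrapper(_SupervisedModel):
    """Trains a Network with the fixed batch-size rule; standardises regression targets."""

    def __init__(self, build: Callable[[], nn.Network], family: str, task: TaskSpec,
                 n_features: int, max_epochs: int, patience: int, as_sequence: bool):
        self._build = build
        self.family = family
        self.task = task
        self._n_features = n_features
        self.max_epochs = max_epochs
        self.patience = patience
        self.as_sequence = as_sequence  # CNN consumes (n, length, 1)
        self.net: nn.Network | None = None
        self._y_mean = 0.0
        self._y_sd = 1.0

    def _shape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, :, None] if self.as_sequence else X

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if self.task.trait_type == "regression":
            self._y_mean = float(y.mean())
            self._y_sd = float(y.std()) or 1.0
            y_fit = ((y - self._y_mean) / self._y_sd)[:, None]
        elif self.task.trait_type == "binary":
            y_fit = y[:, None]
        else:
            y_fit = y
        self.net = self._build()
        batch = max(1, round(X.shape[0] / BATCH_DIVISOR))
        self.net.fit(self._shape(X), y_fit, batch_size=batch,
                     max_epochs=self.max_epochs, patience=self.patience)
        return self

    def predict(self, X):
        out = self.net.predict(self._shape(X))
        if self.task.trait_type == "regression":
            return out[:, 0] * self._y_sd + self._y_mean
        if self.task.trait_type == "binary":
            return (out[:, 0] >= 0.5).astype(int)
        return out.argmax(axis=1)

    @property
    def n_features_in_(self) -> int:
        return self._n_features


def cnn_min_features() -> int:
    """Smallest input length the CNN accepts given its kernel and pooling chain."""
    length_loss = sum(k - 1 for k in CNN_KERNELS)
    return length_loss + CNN_POOL  # conv chain leaves >= pool_size positions


def _build_cnn(n_features: int, task: TaskSpec, seed: int) -> nn.Network:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length, channels = n_features, 1
    for stage, (filters, kernel) in enumerate(zip(CNN_FILTERS, CNN_KERNELS)):
        conv = nn.Conv1D(channels, filters, kernel, rng)
        layers += [conv, nn.ReLU()]
        length, channels = conv.out_length(length), filters
        if stage < len(CNN_DROPOUTS):
            layers.append(nn.Dropout(CNN_DROPOUTS[stage]))
    layers.append(nn.MaxPool1D(CNN_POOL))
    length //= CNN_POOL
    layers += [nn.BatchNorm(channels), nn.Flatten()]
    width = length * channels
    for units in CNN_DENSE:
        layers += [nn.Dense(width, units, rng), nn.ReLU(), nn.BatchNorm(units)]
        width = units
    return _attach_head(layers, width, task, rng, seed)


def _build_dnn(n_features: int, task: TaskSpec, seed: int) -> nn.Network:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    width = n_features
    for i, units in enumerate(DNN_DENSE):
        layers += [nn.Dense(width, units, rng), nn.ReLU()]
        if i < len(DNN_DROPOUTS):
            layers.append(nn.Dropout(DNN_DROPOUTS[i]))
        width = units
    layers.append(nn.BatchNorm(width))  # after the final dense layer
    return _attach_head(layers, width, task, rng, seed)


def _attach_head(layers: list[nn.Layer], width: int, task: TaskSpec,
                 rng: np.random.Generator, seed: int) -> nn.Network:
    if task.trait_type == "regression":
        layers.append(nn.Dense(width, 1, rng, zero_init=True))
        loss = "mse"
    elif task.trait_type == "binary":
        layers.append(nn.Dense(width, 1, rng, zero_init=True))
        loss = "bce"
    else:
        layers.append(nn.Dense(width, task.n_classes, rng, zero_init=True))
        loss = "cce"
    return nn.Network(layers, loss, seed=seed, learning_rate=LEARNING_RATE)


def build_model(
    family: str,
    task: TaskSpec,
    n_features: int,
    seed: int = 0,
    params: dict[str, Any] | None = None,
    max_epochs: int = 200,
    patience: int = 20,
) -> _SupervisedModel:
    """Construct an untrained model of the given family for the given task.

    ``params`` passes tuned hyperparameters through to XGBoost. ``max_epochs``
    and ``patience`` bound the deep-learning training loop.
    """
    params = dict(params or {})
    if family == "XGB":
        common = dict(random_state=seed, n_jobs=1, tree_method="hist", **params)
        if task.trait_type == "regression":
            est = XGBRegressor(**common)
        elif task.trait_type == "binary":
            est = XGBClassifier(objective="binary:logistic", **common)
        else:
            est = XGBClassifier(
                objective="multi:softprob", num_class=task.n_classes, **common
            )
        return _SKWrapper(est, "XGB", task)
    if family == "RF":
        cls = RandomForestClassifier if task.is_classification else RandomForestRegressor
        est = cls(n_estimators=RF_TREES, max_features="sqrt", random_state=seed, n_jobs=1)
        return _SKWrapper(est, "RF", task)
    if family == "CNN":
        minimum = cnn_min_features()
        if n_features < minimum:
            raise ValueError(
                f"CNN requires at least {minimum} input features, got {n_features}"
            )
        return _NetWrapper(lambda: _build_cnn(n_features, task, seed), "CNN", task,
                           n_features, max_epochs, patience, as_sequence=True)
    if family == "DNN":
        return _NetWrapper(lambda: _build_dnn(n_features, task, seed), "DNN", task,
                           n_features, max_epochs, patience, as_sequence=False)
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILY_ORDER}")


# ---------------------------------------------------------------------------
# XGBoost Bayesian hyperparameter search
# ---------------------------------------------------------------------------


def _cv_score(params: dict, X: np.ndarray, y: np.ndarray, task: TaskSpec,
              folds: int, seed: int) -> float:
    """Inner-CV objective: mean fold accuracy, or negative mean fold RMSE."""
    if task.is_classification:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    use = dict(params)
    if task.trait_type != "binary":
        use.pop("scale_pos_weight", None)  # binary-only knob
    scores = []
    for tr, va in splitter.split(X, y if task.is_classification else None):
        model = build_model("XGB", task, X.shape[1], seed=seed, params=use)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        if task.is_classification:
            scores.append(float(np.mean(pred == y[va])))
        else:
            scores.append(-float(np.sqrt(np.mean((pred - y[va]) ** 2))))
    return float(np.mean(scores))


def tune_xgboost(
    X: np.ndarray,
    y: np.ndarray,
    space: TuneSpace,
    task: TaskSpec,
) -> dict[str, Any]:
    """Sequential model-based hyperparameter optimisation for XGBoost.

    Random exploration seeds a Gaussian-process surrogate (Matern 5/2 on
    the unit hypercube); subsequent iterations pick the expected-
    improvement maximiser over a candidate pool. Returns the best
    configuration by inner-CV score. Deterministic under ``space.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task.is_classification:
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("degenerate labels: a single class cannot be tuned")
        if counts.min() < 2:
            raise ValueError(
                f"class {classes[counts.argmin()]!r} has fewer than 2 samples"
            )
    rng = np.random.default_rng(space.seed)
    dim = len(space.bounds)
    n_iter = space.n_search_iterations
    n_init = min(max(5, dim // 2), n_iter)

    tried_u: list[np.ndarray] = []
    scores: list[float] = []
    for it in range(n_iter):
        if it < n_init or len(set(np.round(scores, 12))) < 2:
            u = rng.random(dim)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3),
                              length_scale_bounds=(1e-2, 1e2)),
                alpha=1e-6, normalize_y=True, random_state=int(space.seed % (2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.array(tried_u), np.array(scores))
            cand = rng.random((256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(scores)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / sd
                ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd < 1e-12] = 0.0
            u = cand[int(np.argmax(ei))]
        params = space._from_unit(u)
        score = _cv_score(params, X, y, task, space.inner_cv_folds, space.seed)
        tried_u.append(u)
        scores.append(score)
    return space._from_unit(tried_u[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# cross-validation, evaluation, comparison
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    model: _SupervisedModel
    fold_scores: list[float]
    best_fold: int
    metric_name: str


def _fold_score(model: _SupervisedModel, X: np.ndarray, y: np.ndarray,
                task: TaskSpec) -> float:
    pred = model.predict(X)
    if task.is_classification:
        return float(np.mean(pred == y))
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def crossval_fit(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    task: TaskSpec,
    params: dict[str, Any] | None = None,
    max_epochs: int = 200,
    patience: int = 20,
) -> CrossValResult:
    """Fit ``cv.k`` fold models and keep the one with the best fold-validation score.

    Classification uses stratified folds and selects by highest fold
    accuracy; regression uses plain k-fold and selects by lowest fold RMSE.
    Fold membership is reproducible under ``cv.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < cv.k:
        raise ValueError(f"need at least k={cv.k} training samples, got {X.shape[0]}")
    if task.is_classification:
        classes, counts = np.unique(y, return_counts=True)
        short = classes[counts < cv.k]
        if short.size:
            raise ValueError(
                f"class {short[0]!r} has {counts[counts < cv.k][0]} members, "
                f"fewer than k={cv.k}; cannot stratify"
            )
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)

    fold_scores: list[float] = []
    models: list[_SupervisedModel] = []
    for fold, (tr, va) in enumerate(
        splitter.split(X, y if task.is_classification else None)
    ):
        model = build_model(family, task, X.shape[1], seed=cv.seed + fold,
                            params=params, max_epochs=max_epochs, patience=patience)
        model.fit(X[tr], y[tr])
        fold_scores.append(_fold_score(model, X[va], y[va], task))
        models.append(model)
    arr = np.asarray(fold_scores)
    best = int(arr.argmax()) if task.is_classification else int(arr.argmin())
    metric = "fold_accuracy" if task.is_classification else "fold_rmse"
    return CrossValResult(models[best], fold_scores, best, metric)


def rmse_percent_of_mean(
    predictions: np.ndarray, truths: np.ndarray, reference_mean: float
) -> float:
    """RMSE of predictions expressed as a percentage of the trait mean.

    ``reference_mean`` is the full-dataset trait mean, fixed per trait
    before splitting, so the figure is comparable across models.
    """
    truths = np.asarray(truths, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if truths.size == 0:
        raise ValueError("empty evaluation set")
    if reference_mean == 0:
        raise ValueError("reference trait mean is zero; RMSE%% undefined")
    rmse = float(np.sqrt(np.mean((predictions - truths) ** 2)))
    return 100.0 * rmse / reference_mean


def evaluate(
    model: _SupervisedModel,
    X_holdout: np.ndarray,
    y_holdout: np.ndarray,
    task: TaskSpec,
    train_line_ids: Sequence[str],
    holdout_line_ids: Sequence[str],
    reference_mean: float | None = None,
    fold_scores: Sequence[float] | None = None,
) -> Metrics:
    """Holdout evaluation with a train/holdout leakage guard on line ids."""
    overlap = set(train_line_ids) & set(holdout_line_ids)
    if overlap:
        raise ValueError(f"train/holdout overlap on line ids: {sorted(overlap)[:5]}")
    y_holdout = np.asarray(y_holdout)
    if y_holdout.size == 0:
        raise ValueError("empty holdout set")
    pred = model.predict(np.asarray(X_holdout, dtype=float))
    if task.is_classification:
        value = 100.0 * float(np.mean(pred == y_holdout))
        name = "accuracy_pct"
    else:
        if reference_mean is None:
            raise ValueError("regression evaluation requires reference_mean")
        value = rmse_percent_of_mean(pred, y_holdout, reference_mean)
        name = "rmse_pct_of_mean"
    return Metrics(name, value, list(fold_scores or []))


def compare_models(table: pd.DataFrame) -> ComparisonSummary:
    """Summarise a metric table with columns trait, dataset, family, task_type, value.

    ``value`` is holdout accuracy (percent) for classification cells and
    holdout RMSE%% for regression cells. Every family must have a value for
    every (trait, dataset) cell.
    """
    required = {"trait", "dataset", "family", "task_type", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"metric table needs columns {sorted(required)}")
    cells = table[["trait", "dataset"]].drop_duplicates()
    for _, cell in cells.iterrows():
        present = set(
            table[(table.trait == cell.trait) & (table.dataset == cell.dataset)].family
        )
        missing = set(FAMILY_ORDER) - present
        if missing:
            raise ValueError(
                f"missing metrics for {sorted(missing)} on trait={cell.trait!r} "
                f"dataset={cell.dataset!r}"
            )

    wide = table.pivot_table(
        index=["trait", "dataset", "task_type"], columns="family", values="value"
    ).reset_index()
    is_clf = wide.task_type != "regression"
    dl = (wide.CNN + wide.DNN) / 2.0

    def _mean(mask: pd.Series, series: pd.Series) -> float | None:
        return float(series[mask].mean()) if mask.any() else None

    summary = ComparisonSummary(
        xgb_dl_diff_classification=_mean(is_clf, wide.XGB - dl),
        rf_dl_diff_classification=_mean(is_clf, wide.RF - dl),
        xgb_dl_diff_regression=_mean(~is_clf, dl - wide.XGB),
        rf_dl_diff_regression=_mean(~is_clf, dl - wide.RF),
        best_counts={f: 0 for f in FAMILY_ORDER},
        n_cells=len(wide),
        table=wide,
    )
    for _, row in wide.iterrows():
        values = [row[f] for f in FAMILY_ORDER]
        if row.task_type == "regression":
            best_val = min(values)
        else:
            best_val = max(values)
        winner = FAMILY_ORDER[values.index(best_val)]  # first in order wins ties
        summary.best_counts[winner] += 1
    return summary


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: _SupervisedModel, path: str | Path,
               metadata: dict[str, Any] | None = None) -> None:
    """Pickle a fitted model with a JSON sidecar recording config and seeds."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh, protocol=5)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"family": model.family, **(metadata or {})}, fh, indent=2)


def load_model(path: str | Path) -> _SupervisedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
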