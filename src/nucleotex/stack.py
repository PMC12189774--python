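"""Three-block stacked-probability classification with TPE model search.

Block 1 trains on deep tile embeddings, block 2 on aggregated handcrafted
nucleus features, and block 3 on the concatenated class-probability
outputs of the first two. Each block is a scaler → selector → classifier
pipeline whose components and hyperparameters are chosen by a TPE search
maximizing the composite weighted-average metric (the mean of
support-weighted precision, recall, F1, accuracy, and specificity) on a
held-out split.

Stacking leakage control: block 3's training features are out-of-fold
probabilities from 5-fold cross-fitting of the first-stage configurations
within the training split; the first-stage models are then refit on the
full training split to produce test-time probabilities. Splits are
stratified by image so tiles of one image never straddle the partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from functools import partial
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, SelectKBest, mutual_info_classif
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (MaxAbsScaler, MinMaxScaler, RobustScaler,
                                   StandardScaler)
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .search import TPESampler

logger = logging.getLogger(__name__)

SCALERS = ("standard", "minmax", "robust", "maxabs")
SELECTORS = ("rfe", "pca", "mi")
KEEP_FRACTIONS = (0.25, 0.5, 0.7, 0.85, 1.0)

#: classifier roster and per-classifier hyperparameter grids
CLASSIFIER_GRID: dict[str, dict[str, tuple]] = {
    "logreg": {"C": (0.1, 1.0, 10.0)},
    "svm_linear": {"C": (0.1, 1.0, 10.0)},
    "svm_rbf": {"C": (1.0, 10.0), "gamma": ("scale", 0.1)},
    "random_forest": {"n_estimators": (100, 200), "max_depth": (None, 8)},
    "gradient_boosting": {"n_estimators": (50, 100), "learning_rate": (0.05, 0.1)},
    "knn": {"n_neighbors": (3, 5, 7), "weights": ("uniform", "distance")},
    "sgd": {"alpha": (1e-4, 1e-3, 1e-2)},
    "mlp": {"hidden": ((64,), (128,), (64, 32)), "alpha": (1e-4, 1e-3)},
    "gnb": {"var_smoothing": (1e-9, 1e-8)},
    "dtree": {"max_depth": (None, 5, 10)},
}

METRIC_NAMES = ("precision", "recall", "f1", "accuracy", "specificity")


class ConfigError(ValueError):
    """Unknown scaler/selector/classifier identifier."""


@dataclass(frozen=True)
class PipelineConfig:
    """One point in the search space: scaler, selector, classifier."""

    scaler: str = "standard"
    selector: str = "pca"
    keep_fraction: float = 1.0
    classifier: str = "logreg"
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaler not in SCALERS:
            raise ConfigError(f"unknown scaler {self.scaler!r}; valid: {SCALERS}")
        if self.selector not in SELECTORS:
            raise ConfigError(f"unknown selector {self.selector!r}; valid: {SELECTORS}")
        if not (0 < self.keep_fraction <= 1):
            raise ConfigError("keep_fraction must lie in (0, 1]")
        if self.classifier not in CLASSIFIER_GRID:
            raise ConfigError(
                f"unknown classifier {self.classifier!r}; "
                f"valid: {tuple(CLASSIFIER_GRID)}"
            )


@dataclass
class RunMetrics:
    """Support-weighted metrics for one train/test run.

    ``composite`` is exactly the arithmetic mean of the five metrics —
    the weighted-average score used as the tuning objective.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    specificity: float
    seed: int = 0

    @property
    def composite(self) -> float:
        return (self.precision + self.recall + self.f1
                + self.accuracy + self.specificity) / 5.0

    def as_dict(self) -> dict[str, float]:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["composite"] = self.composite
        return d


@dataclass
class BlockModel:
    """Fitted scaler+selector+classifier pipeline for one block."""

    pipeline: Pipeline
    config: PipelineConfig
    classes: list
    block_kind: str  # handcrafted | embedded | stacked

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.pipeline.predict_proba(np.asarray(X))
        order = [list(self.pipeline.classes_).index(c) for c in self.classes]
        return proba[:, order]

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X), axis=1)
        return np.asarray(self.classes)[idx]


@dataclass
class TrialRecord:
    """One search trial: configuration, outcome, timestamp."""

    index: int
    config: PipelineConfig
    metrics: RunMetrics
    timestamp: str = ""

    def to_json_dict(self) -> dict:
        return {
            "index": self.index,
            "config": {
                "scaler": self.config.scaler,
                "selector": self.config.selector,
                "keep_fraction": self.config.keep_fraction,
                "classifier": self.config.classifier,
                "params": dict(self.config.params),
                "seed": self.config.seed,
            },
            "metrics": self.metrics.as_dict(),
            "timestamp": self.timestamp,
        }


class SoftmaxProbability(BaseEstimator, ClassifierMixin):
    """Expose calibrated probabilities for margin classifiers.

    Wraps an estimator that only provides ``decision_function`` and maps
    decision scores through a softmax; binary scores are expanded to the
    two-column form first.
    """

    def __init__(self, estimator: BaseEstimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator_ = clone(self.estimator).fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def decision_function(self, X):
        return self.estimator_.decision_function(X)

    def predict(self, X):
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        scores = self.estimator_.decision_function(X)
        if scores.ndim == 1:
            scores = np.stack([-scores, scores], axis=1)
        return softmax(scores, axis=1)


def _make_classifier(name: str, params: Mapping[str, Any], seed: int):
    p = dict(params)
    if name == "logreg":
        return LogisticRegression(C=p.get("C", 1.0), max_iter=2000,
                                  random_state=seed)
    if name == "svm_linear":
        return SoftmaxProbability(SVC(kernel="linear", C=p.get("C", 1.0),
                                      random_state=seed))
    if name == "svm_rbf":
        return SoftmaxProbability(SVC(kernel="rbf", C=p.get("C", 1.0),
                                      gamma=p.get("gamma", "scale"),
                                      random_state=seed))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=p.get("n_estimators", 100),
                                      max_depth=p.get("max_depth"),
                                      random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 100),
            learning_rate=p.get("learning_rate", 0.1), random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5),
                                    weights=p.get("weights", "uniform"))
    if name == "sgd":
        return SGDClassifier(loss="log_loss", alpha=p.get("alpha", 1e-4),
                             max_iter=2000, random_state=seed)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=p.get("hidden", (64,)),
                             alpha=p.get("alpha", 1e-4), max_iter=500,
                             random_state=seed)
    if name == "gnb":
        return GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9))
    if name == "dtree":
        return DecisionTreeClassifier(max_depth=p.get("max_depth"),
                                      random_state=seed)
    raise ConfigError(f"unknown classifier {name!r}")


def build_pipeline(cfg: PipelineConfig, n_features: int) -> Pipeline:
    """Compose the scaler → selector → classifier pipeline.

    The selector keeps ``ceil(keep_fraction · n_features)`` features (RFE,
    MI) or principal components (PCA, additionally capped by the sample
    count at fit time); ``keep_fraction == 1`` makes it the identity.
    """
    scaler = {
        "standard": StandardScaler(),
        "minmax": MinMaxScaler(),
        "robust": RobustScaler(),
        "maxabs": MaxAbsScaler(),
    }[cfg.scaler]
    k = int(np.ceil(cfg.keep_fraction * n_features))
    if cfg.keep_fraction >= 1.0:
        selector: Any = "passthrough"
    elif cfg.selector == "rfe":
        selector = RFE(LogisticRegression(max_iter=500, random_state=cfg.seed),
                       n_features_to_select=k, step=0.1)
    elif cfg.selector == "pca":
        selector = _CappedPCA(n_components=k, random_state=cfg.seed)
    else:  # mi
        selector = SelectKBest(
            partial(mutual_info_classif, random_state=cfg.seed), k=k)
    clf = _make_classifier(cfg.classifier, cfg.params, cfg.seed)
    return Pipeline([("scaler", scaler), ("selector", selector),
                     ("classifier", clf)])


class _CappedPCA(PCA):
    """PCA whose component count is capped by what the data can support."""

    def fit(self, X, y=None):
        cap = min(np.asarray(X).shape)
        if isinstance(self.n_components, (int, np.integer)):
            self.n_components = min(int(self.n_components), cap)
        return super().fit(X, y)

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return super().transform(X)


def evaluate(y_true: Sequence, y_pred: Sequence,
             classes: Sequence, seed: int = 0) -> RunMetrics:
    """Support-weighted one-vs-rest metrics plus overall accuracy.

    A class absent from ``y_true`` carries zero weight (its one-vs-rest
    table is undefined for recall); specificity per class is TN/(TN+FP)
    from the multiclass confusion matrix.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    classes = list(classes)
    if not set(y_true) <= set(classes) or not set(y_pred) <= set(classes):
        raise ValueError("labels outside the declared class list")
    missing = [c for c in classes if c not in set(y_true)]
    if missing:
        logger.warning("classes absent from y_true get zero weight: %s", missing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0)
    acc = accuracy_score(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    support = cm.sum(axis=1)
    total = cm.sum()
    spec_w = 0.0
    for i in range(len(classes)):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        spec_i = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        spec_w += support[i] * spec_i
    spec = spec_w / total if total else 0.0
    return RunMetrics(precision=float(prec), recall=float(rec), f1=float(f1),
                      accuracy=float(acc), specificity=float(spec), seed=seed)


def composite_score(precision: float, recall: float, f1: float,
                    accuracy: float, specificity: float) -> float:
    """The weighted-average composite: plain mean of the five metrics."""
    return RunMetrics(precision, recall, f1, accuracy, specificity).composite


def split_dataset(samples: np.ndarray, labels: Sequence,
                  test_fraction: float = 0.15, seed: int = 0,
                  groups: Sequence | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split returning index arrays.

    When ``groups`` is given (e.g. image ids for tiles), whole groups are
    assigned to one side and stratification is by group label, which
    prevents leakage between tiles of the same image.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    n = len(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to split")
    groups = np.arange(n) if groups is None else np.asarray(groups)
    uniq, first = np.unique(groups, return_index=True)
    group_labels = labels[first]
    counts = pd.Series(group_labels).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 groups; got {counts.to_dict()}")
    tr_g, te_g = train_test_split(uniq, test_size=test_fraction,
                                  random_state=seed, stratify=group_labels)
    tr_mask = np.isin(groups, tr_g)
    return np.where(tr_mask)[0], np.where(~tr_mask)[0]


def fit_block(X_train: np.ndarray, y_train: Sequence, cfg: PipelineConfig,
              block_kind: str = "handcrafted") -> BlockModel:
    """Fit one block pipeline on training data."""
    X_train = np.asarray(X_train, dtype=np.float64)
    if not np.all(np.isfinite(X_train)):
        bad = np.where(~np.isfinite(X_train).all(axis=0))[0]
        raise ValueError(f"non-finite feature columns: {bad.tolist()}")
    pipe = build_pipeline(cfg, X_train.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X_train, np.asarray(y_train))
    classes = sorted(set(y_train))
    return BlockModel(pipeline=pipe, config=cfg, classes=classes,
                      block_kind=block_kind)


def train_block(features: np.ndarray, labels: Sequence, cfg: PipelineConfig,
                seed: int = 0, test_fraction: float = 0.15,
                groups: Sequence | None = None,
                block_kind: str = "handcrafted"
                ) -> tuple[BlockModel, RunMetrics]:
    """Split, fit, and evaluate one block; seed fixes split and fits."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    tr, te = split_dataset(X, y, test_fraction=test_fraction, seed=seed,
                           groups=groups)
    model = fit_block(X[tr], y[tr], replace(cfg, seed=seed), block_kind)
    metrics = evaluate(y[te], model.predict(X[te]), model.classes, seed=seed)
    return model, metrics


def concatenate_probabilities(p_a: np.ndarray, p_b: np.ndarray,
                              ids_a: Sequence | None = None,
                              ids_b: Sequence | None = None) -> np.ndarray:
    """Row-wise concatenation of two aligned probability matrices.

    Alignment is verified through shared sample ids when given;
    misaligned ids raise rather than silently reorder.
    """
    p_a, p_b = np.asarray(p_a), np.asarray(p_b)
    if p_a.shape[0] != p_b.shape[0]:
        raise ValueError("probability matrices have different sample counts")
    if ids_a is not None or ids_b is not None:
        if ids_a is None or ids_b is None or list(ids_a) != list(ids_b):
            raise ValueError("sample ids of the two probability matrices differ")
    for name, p in (("first", p_a), ("second", p_b)):
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{name} matrix rows do not sum to 1")
    return np.concatenate([p_a, p_b], axis=1)


# -- TPE search ------------------------------------------------------------

def _search_space() -> dict[str, tuple]:
    space: dict[str, tuple] = {
        "scaler": tuple(SCALERS),
        "selector": tuple(SELECTORS),
        "keep_fraction": tuple(KEEP_FRACTIONS),
        "classifier": tuple(CLASSIFIER_GRID),
    }
    for clf, grid in CLASSIFIER_GRID.items():
        for pname, choices in grid.items():
            space[f"clf/{clf}/{pname}"] = tuple(choices)
    return space


def _is_active(name: str, partial_params: Mapping[str, Any]) -> bool:
    if not name.startswith("clf/"):
        return True
    clf = name.split("/", 2)[1]
    return partial_params.get("classifier") == clf


def _params_to_config(params: Mapping[str, Any], seed: int) -> PipelineConfig:
    clf = params["classifier"]
    hp = {k.split("/", 2)[2]: v for k, v in params.items()
          if k.startswith(f"clf/{clf}/")}
    return PipelineConfig(scaler=params["scaler"], selector=params["selector"],
                          keep_fraction=params["keep_fraction"],
                          classifier=clf, params=hp, seed=seed)


def tpe_search(block_kind: str, X: np.ndarray, y: Sequence,
               n_trials: int = 50, seed: int = 0,
               test_fraction: float = 0.15,
               groups: Sequence | None = None,
               space: Mapping[str, tuple] | None = None
               ) -> tuple[TrialRecord, list[TrialRecord]]:
    """TPE search over scaler/selector/classifier configurations.

    Each trial fits on the train side of a fixed seeded split and scores
    the composite on the held-out side. Every trial is appended to the
    history; the best record is the argmax composite with ties broken by
    the earliest trial. Failed trials score 0 and carry their cause in
    the history; if every trial fails an error lists the causes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    tr, te = split_dataset(X, y, test_fraction=test_fraction, seed=seed,
                           groups=groups)
    sampler = TPESampler(seed=seed)
    space = dict(space) if space is not None else _search_space()
    history: list[TrialRecord] = []
    sampler_hist: list[tuple[Mapping[str, Any], float]] = []
    failures: list[str] = []
    for i in range(n_trials):
        params = sampler.suggest(space, sampler_hist, _is_active)
        cfg = _params_to_config(params, seed)
        try:
            model = fit_block(X[tr], y[tr], cfg, block_kind)
            metrics = evaluate(y[te], model.predict(X[te]), model.classes,
                               seed=seed)
        except Exception as exc:  # noqa: BLE001 - trial failures are data
            failures.append(f"trial {i} ({cfg.classifier}): {exc}")
            metrics = RunMetrics(0, 0, 0, 0, 0, seed=seed)
        history.append(TrialRecord(
            index=i, config=cfg, metrics=metrics,
            timestamp=datetime.now(timezone.utc).isoformat()))
        sampler_hist.append((params, metrics.composite))
    if len(failures) == n_trials:
        raise RuntimeError("all trials failed: " + "; ".join(failures))
    best = max(history, key=lambda r: (r.metrics.composite, -r.index))
    return best, history


def write_history(history: Sequence[TrialRecord], path) -> None:
    """Append-only JSON-lines history file, one trial per line."""
    import json

    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec.to_json_dict()) + "\n")


# -- multi-run experiment --------------------------------------------------

def _cross_fit_probabilities(X: np.ndarray, y: np.ndarray,
                             cfg: PipelineConfig, block_kind: str,
                             classes: list, seed: int,
                             n_folds: int = 5) -> np.ndarray:
    """Out-of-fold class probabilities via stratified k-fold cross-fitting."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = np.zeros((len(y), len(classes)))
    for fold_tr, fold_va in skf.split(X, y):
        model = fit_block(X[fold_tr], y[fold_tr], cfg, block_kind)
        order = [list(model.pipeline.classes_).index(c) for c in classes]
        proba[fold_va] = model.pipeline.predict_proba(X[fold_va])[:, order]
    return proba


def run_experiment(handcrafted: np.ndarray, embedded: np.ndarray,
                   labels: Sequence, seeds: Sequence[int],
                   sample_ids: Sequence | None = None,
                   groups: Sequence | None = None,
                   n_trials: int = 50, test_fraction: float = 0.15,
                   retune: str = "always") -> pd.DataFrame:
    """Tune and evaluate the three blocks over multiple independent runs.

    Per run (one seed): split once; TPE-tune block 1 (embedded) and
    block 2 (handcrafted) inside the training split; refit the best
    configurations on the full training split and score on the test
    split; build block 3 on out-of-fold concatenated probabilities and
    score it on the test-side concatenated probabilities.
    ``retune="once"`` reuses the first run's configurations.

    Returns a tidy table (run, seed, block, metric, value). A failed run
    is recorded with metric ``error`` and the experiment continues.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if retune not in ("always", "once"):
        raise ValueError("retune must be 'always' or 'once'")
    Xh = np.asarray(handcrafted, dtype=np.float64)
    Xe = np.asarray(embedded, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(set(y))
    rows: list[dict] = []
    cached_cfgs: dict[str, PipelineConfig] | None = None

    for run, seed in enumerate(seeds):
        try:
            tr, te = split_dataset(Xh, y, test_fraction=test_fraction,
                                   seed=seed, groups=groups)
            grp_tr = None if groups is None else np.asarray(groups)[tr]
            if retune == "once" and cached_cfgs is not None:
                cfg1 = replace(cached_cfgs["embedded"], seed=seed)
                cfg2 = replace(cached_cfgs["handcrafted"], seed=seed)
            else:
                best1, _ = tpe_search("embedded", Xe[tr], y[tr],
                                      n_trials=n_trials, seed=seed,
                                      groups=grp_tr)
                best2, _ = tpe_search("handcrafted", Xh[tr], y[tr],
                                      n_trials=n_trials, seed=seed,
                                      groups=grp_tr)
                cfg1, cfg2 = best1.config, best2.config

            model1 = fit_block(Xe[tr], y[tr], cfg1, "embedded")
            model2 = fit_block(Xh[tr], y[tr], cfg2, "handcrafted")
            m1 = evaluate(y[te], model1.predict(Xe[te]), classes, seed)
            m2 = evaluate(y[te], model2.predict(Xh[te]), classes, seed)

            p1_tr = _cross_fit_probabilities(Xe[tr], y[tr], cfg1, "embedded",
                                             classes, seed)
            p2_tr = _cross_fit_probabilities(Xh[tr], y[tr], cfg2,
                                             "handcrafted", classes, seed)
            S_tr = concatenate_probabilities(p1_tr, p2_tr)
            S_te = concatenate_probabilities(model1.predict_proba(Xe[te]),
                                             model2.predict_proba(Xh[te]))
            if retune == "once" and cached_cfgs is not None:
                cfg3 = replace(cached_cfgs["stacked"], seed=seed)
            else:
                best3, _ = tpe_search("stacked", S_tr, y[tr],
                                      n_trials=n_trials, seed=seed)
                cfg3 = best3.config
            model3 = fit_block(S_tr, y[tr], cfg3, "stacked")
            m3 = evaluate(y[te], model3.predict(S_te), classes, seed)

            if cached_cfgs is None:
                cached_cfgs = {"embedded": cfg1, "handcrafted": cfg2,
                               "stacked": cfg3}
            for block, metrics in (("embedded", m1), ("handcrafted", m2),
                                   ("stacked", m3)):
                for metric, value in metrics.as_dict().items():
                    rows.append({"run": run, "seed": seed, "block": block,
                                 "metric": metric, "value": value})
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.error("run %d (seed %d) failed: %s", run, seed, exc)
            rows.append({"run": run, "seed": seed, "block": "all",
                         "metric": "error", "value": float("nan")})
    return pd.DataFrame(rows)
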