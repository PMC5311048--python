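"""Class balancing, normalization, classifiers, and feature importance.

Three classifier families operate on RQA feature tables:

* decision tree — CART with the Gini criterion, grown until all leaves
  are pure (scikit-learn's implementation);
* random forest — an in-package bagged ensemble of such trees with
  floor(sqrt(d)) candidate features per split.  Each tree's bootstrap
  row set is retained so Breiman's out-of-bag permutation importance
  (mean OOB error increase after permuting a feature, divided by the
  standard deviation of the per-tree differences) can be computed
  exactly;
* linear SVM — libsvm via scikit-learn's SVC, one-vs-one for the
  multi-class problem, with features z-scored against the training data.

Training data is balanced by under-sampling the majority (unknown)
class and resampling the minority SMM classes to a common count; test
data keeps its natural class distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_streams import LABELS, SMM_LABELS, UNKNOWN
from .segmentation import feature_columns

#: Hyperparameter grids searched during model selection.
RF_N_TREES_GRID = (100, 250, 500)
SVM_C_GRID = (1.0, 100.0, 10_000.0, 100_000.0)

MODEL_KINDS = ("random_forest", "linear_svm", "decision_tree")


@dataclass(frozen=True)
class ModelConfig:
    """One point of the classifier grid."""

    kind: str
    n_trees: int = 100
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")

    @property
    def capacity(self) -> float:
        """Ordering key used to break selection ties toward smaller models."""
        if self.kind == "random_forest":
            return float(self.n_trees)
        if self.kind == "linear_svm":
            return float(self.C)
        return 0.0

    def describe(self) -> dict:
        out = {"kind": self.kind}
        if self.kind == "random_forest":
            out["n_trees"] = self.n_trees
        elif self.kind == "linear_svm":
            out["C"] = self.C
        return out


def default_model_grid(kind: str) -> list:
    """The full hyperparameter grid for one classifier family."""
    if kind == "random_forest":
        return [ModelConfig("random_forest", n_trees=n)
                for n in RF_N_TREES_GRID]
    if kind == "linear_svm":
        return [ModelConfig("linear_svm", C=c) for c in SVM_C_GRID]
    if kind == "decision_tree":
        return [ModelConfig("decision_tree")]
    raise ValueError(f"kind must be one of {MODEL_KINDS}")


# ---------------------------------------------------------------------------
# Leakage guard: evaluation marks test tables; fitting refuses them.


def mark_test(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy flagged as test data; fitting on it raises."""
    out = table.copy()
    out["_test"] = True
    return out


def _ensure_training(table: pd.DataFrame, what: str) -> None:
    if "_test" in table.columns and bool(table["_test"].any()):
        raise ValueError(f"{what} must only see training rows, but the "
                         f"table is flagged as test data")


# ---------------------------------------------------------------------------
# Balancing


def balance_training_set(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Equalize class counts: under-sample unknown, resample SMM classes.

    The target count is the largest SMM-class count.  Unknown rows are
    drawn without replacement (they are always a subset of the input
    unknown rows when the class is larger than the target); smaller SMM
    classes are resampled with replacement; a class already at the
    target is kept verbatim.  Classes with zero rows are dropped with a
    warning.  Deterministic given the seed.
    """
    _ensure_training(table, "balancing")
    counts = table["label"].value_counts()
    if len(table) == 0 or counts.size < 2:
        raise ValueError("balancing needs rows from at least two classes")
    smm_counts = [int(counts.get(lab, 0)) for lab in SMM_LABELS]
    if max(smm_counts) == 0:
        raise ValueError("balancing needs at least one SMM-labeled row")
    target = max(smm_counts)

    rng = np.random.default_rng(seed)
    parts = []
    for label in LABELS:
        rows = table[table["label"] == label]
        n = len(rows)
        if n == 0:
            warnings.warn(f"class {label!r} has no rows and is dropped",
                          stacklevel=2)
            continue
        if n == target:
            take = rows
        elif n > target:
            take = rows.iloc[np.sort(rng.choice(n, target, replace=False))]
        else:
            take = rows.iloc[np.sort(rng.choice(n, target, replace=True))]
        parts.append(take)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# z-score normalization (fit on training data only)


@dataclass
class ZScoreParams:
    mean: pd.Series
    std: pd.Series  # population sd; zero-variance columns map to 0


def fit_zscore(table: pd.DataFrame) -> ZScoreParams:
    """Per-feature mean and population standard deviation of training rows."""
    _ensure_training(table, "z-score fitting")
    cols = feature_columns(table)
    return ZScoreParams(mean=table[cols].mean(),
                        std=table[cols].std(ddof=0))


def apply_zscore(params: ZScoreParams, table: pd.DataFrame) -> pd.DataFrame:
    """Transform rows with training parameters; constant columns become 0."""
    out = table.copy()
    cols = list(params.mean.index)
    safe = params.std.mask(params.std == 0, np.inf)
    out[cols] = (table[cols] - params.mean) / safe
    return out


# ---------------------------------------------------------------------------
# Random forest with out-of-bag bookkeeping


class BaggedForest:
    """Bagged CART ensemble retaining per-tree bootstrap row sets.

    Each tree is fit on a bootstrap of the n training rows with
    floor(sqrt(d)) candidate features per split and grown to purity.
    Prediction is the majority vote of the ensemble (ties go to the
    lexicographically smallest class).  The retained bootstrap indices
    give each tree's out-of-bag rows, enabling exact OOB error and OOB
    permutation importance.
    """

    def __init__(self, n_trees: int = 100, random_state: int = 0):
        self.n_trees = int(n_trees)
        self.random_state = int(random_state)

    def fit(self, X, y) -> "BaggedForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        self.trees_ = []
        self.bootstrap_idx_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features="sqrt",
                random_state=int(rng.integers(2 ** 31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_idx_.append(idx)
        self._X = X
        self._y = y
        return self

    def _vote(self, X) -> np.ndarray:
        counts = np.zeros((len(X), len(self.classes_)), dtype=np.int32)
        rows = np.arange(len(X))
        for tree in self.trees_:
            codes = np.searchsorted(self.classes_, tree.predict(X))
            counts[rows, codes] += 1
        return counts

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.classes_[np.argmax(self._vote(X), axis=1)]

    def _oob_masks(self):
        n = len(self._X)
        for idx in self.bootstrap_idx_:
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            yield mask

    def oob_error(self) -> float:
        """Ensemble OOB error: each row voted on by trees that missed it."""
        n = len(self._X)
        counts = np.zeros((n, len(self.classes_)), dtype=np.int32)
        for tree, mask in zip(self.trees_, self._oob_masks()):
            if not mask.any():
                continue
            codes = np.searchsorted(self.classes_,
                                    tree.predict(self._X[mask]))
            counts[np.flatnonzero(mask), codes] += 1
        voted = counts.sum(axis=1) > 0
        pred = self.classes_[np.argmax(counts[voted], axis=1)]
        return float(np.mean(pred != self._y[voted]))

    def permutation_importance_scores(self, random_state: int = 0
                                      ) -> np.ndarray:
        """Per-feature OOB permutation importance.

        For every tree, feature values are permuted among that tree's
        out-of-bag rows and the increase in the tree's OOB error is
        recorded; the score is the mean increase over trees divided by
        the standard deviation of the per-tree increases (the raw mean
        when that deviation is zero).
        """
        rng = np.random.default_rng(random_state)
        d = self._X.shape[1]
        diffs = np.zeros((self.n_trees, d))
        for t, (tree, mask) in enumerate(zip(self.trees_,
                                             self._oob_masks())):
            if not mask.any():
                continue
            Xo = self._X[mask]
            yo = self._y[mask]
            base = np.mean(tree.predict(Xo) != yo)
            for j in range(d):
                perm = rng.permutation(len(Xo))
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                diffs[t, j] = np.mean(tree.predict(Xp) != yo) - base
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=0)
        return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean)


# ---------------------------------------------------------------------------
# Unified train / predict surface


@dataclass
class Classifier:
    """A fitted model plus everything needed to apply it to new rows."""

    config: ModelConfig
    feature_names: list
    model: object
    classes_: np.ndarray
    zscore: ZScoreParams | None = None
    seed: int = 0


def train(config: ModelConfig, table: pd.DataFrame,
          seed: int = 0) -> Classifier:
    """Fit one classifier on a (balanced) training table.

    For the linear SVM the features are z-scored against this table and
    the parameters stored for prediction time.  Raises on a single-class
    table.  Deterministic given the seed.
    """
    _ensure_training(table, "training")
    cols = feature_columns(table)
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class")

    zscore = None
    if config.kind == "linear_svm":
        zscore = fit_zscore(table)
        X = apply_zscore(zscore, table)[cols].to_numpy(dtype=float)
        model = SVC(kernel="linear", C=config.C)  # libsvm, one-vs-one
        model.fit(X, y)
    elif config.kind == "random_forest":
        X = table[cols].to_numpy(dtype=float)
        model = BaggedForest(n_trees=config.n_trees,
                             random_state=seed).fit(X, y)
    elif config.kind == "decision_tree":
        X = table[cols].to_numpy(dtype=float)
        model = DecisionTreeClassifier(criterion="gini",
                                       random_state=seed).fit(X, y)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(config.kind)
    return Classifier(config=config, feature_names=cols, model=model,
                      classes_=np.unique(y), zscore=zscore, seed=seed)


def predict(classifier: Classifier, table: pd.DataFrame) -> np.ndarray:
    """Predict labels for the rows of a feature table."""
    if classifier.zscore is not None:
        table = apply_zscore(classifier.zscore, table)
    X = table[classifier.feature_names].to_numpy(dtype=float)
    return np.asarray(classifier.model.predict(X))


# ---------------------------------------------------------------------------
# Importance and model selection


def fit_predict(config: ModelConfig, train_table: pd.DataFrame,
                test_table: pd.DataFrame, seed: int = 0,
                balance_seed: int | None = None) -> np.ndarray:
    """Balance, fit, and predict in one deterministic step.

    When the training rows cannot support a classifier — a single class,
    or no SMM rows to set the balancing target, as happens with very
    small training subsamples — the majority training label is predicted
    throughout instead of raising.
    """
    _ensure_training(train_table, "training")
    bseed = seed if balance_seed is None else balance_seed
    try:
        balanced = balance_training_set(train_table, bseed)
    except ValueError:
        balanced = train_table
    if len(balanced) == 0:
        raise ValueError("empty training table")
    if balanced["label"].nunique() < 2:
        majority = balanced["label"].mode().iloc[0]
        return np.full(len(test_table), majority, dtype=object)
    classifier = train(config, balanced, seed)
    return predict(classifier, test_table)


def permutation_importance(classifier: Classifier,
                           seed: int = 0) -> list:
    """Descending (feature, score) ranking from OOB permutation.

    Requires a random-forest classifier fitted by :func:`train`, whose
    forest keeps the per-tree out-of-bag bookkeeping.
    """
    if not isinstance(classifier.model, BaggedForest):
        raise ValueError("permutation importance requires a forest with "
                         "out-of-bag bookkeeping")
    scores = classifier.model.permutation_importance_scores(seed)
    ranking = sorted(zip(classifier.feature_names, scores),
                     key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(score)) for name, score in ranking]


def select_hyperparameters(model_grid, eps_grid, folds, seed: int = 0):
    """Grid search over epsilon x model configurations.

    ``folds`` is a callable mapping an epsilon to a sequence of
    ``(train_table, val_table)`` pairs (feature tables extracted at that
    epsilon).  Each fold's training table is balanced once, before any
    normalization, and every configuration is scored by mean validation
    accuracy.  Ties break toward smaller epsilon, then smaller model
    capacity.  Returns ``(best_epsilon, best_config, best_score)``.
    """
    best_key = None
    best = None
    for eps in eps_grid:
        fold_pairs = list(folds(eps))
        if not fold_pairs:
            raise ValueError("model selection needs at least one fold")
        for config in model_grid:
            accs = []
            for i, (tr, val) in enumerate(fold_pairs):
                pred = fit_predict(config, tr, val, seed=seed,
                                   balance_seed=seed + i)
                accs.append(float(np.mean(pred == val["label"].to_numpy())))
            key = (float(np.mean(accs)), -float(eps), -config.capacity)
            if best_key is None or key > best_key:
                best_key = key
                best = (float(eps), config, float(np.mean(accs)))
    return best
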