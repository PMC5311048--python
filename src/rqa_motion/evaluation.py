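"""The three evaluation protocols plus metrics and reports.

* :func:`session_kfold` — within-participant accuracy: k-fold over a
  participant's recording sessions, one fold per session, training on
  balanced data from the remaining sessions with (epsilon, model)
  selected inside the training folds, testing on the held-out session's
  natural class distribution.
* :func:`leave_one_participant_out` — person-independent accuracy with
  training-size curves: train on all other participants, subsampling
  the pooled training rows by a factor K from a 15-point geometric
  grid, test on every window of the left-out participant.
* :func:`sensor_ablation` — the session k-fold repeated per sensor
  configuration (each wrist alone, torso alone, all three), d = 9 for a
  single sensor and 27 for the full array.
* :func:`importance_report` — top-k out-of-bag permutation importances
  of per-participant random forests, with sensor-qualified feature
  names.

Test rows are tainted with a flag that every fitting routine checks, so
balancing, normalization and hyperparameter selection can only ever see
training rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_streams import LABELS, Session
from .models import (
    ModelConfig,
    balance_training_set,
    default_model_grid,
    fit_predict,
    mark_test,
    permutation_importance,
    select_hyperparameters,
    train,
)
from .recurrence import RQAConfig, epsilon_grid
from .segmentation import (
    SegmentationConfig,
    feature_table_from_windows,
    segment_session,
)

#: All four sensor configurations of the ablation experiment.
ABLATION_CONFIGS = (
    ("left_wrist",),
    ("right_wrist",),
    ("torso",),
    ("left_wrist", "right_wrist", "torso"),
)


def training_size_grid() -> np.ndarray:
    """The 15 descending training-set size factors {0.5**i, i = 0..14}."""
    return 0.5 ** np.arange(15)


def training_size(K: float, n_rows: int) -> int:
    """N_K = round(K * N), at least 1."""
    return max(1, int(round(K * n_rows)))


# ---------------------------------------------------------------------------
# Metrics


def confusion_table(y_true, y_pred, labels=LABELS) -> pd.DataFrame:
    """Confusion counts, truth on rows, prediction on columns."""
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        counts[index[t], index[p]] += 1
    return pd.DataFrame(counts, index=labels, columns=labels)


def metrics(confusion: pd.DataFrame) -> dict:
    """Accuracy and per-class precision/recall from a confusion matrix.

    A class absent from the truth gets recall ``None`` (undefined, not
    zero); a class never predicted gets precision ``None``.
    """
    counts = confusion.to_numpy()
    total = counts.sum()
    if confusion.empty or total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    precision = {
        lab: (float(diag[i] / col_sums[i]) if col_sums[i] else None)
        for i, lab in enumerate(confusion.columns)
    }
    recall = {
        lab: (float(diag[i] / row_sums[i]) if row_sums[i] else None)
        for i, lab in enumerate(confusion.index)
    }
    return {
        "accuracy": float(diag.sum() / total),
        "precision": precision,
        "recall": recall,
    }


def _macro(values: dict) -> float:
    defined = [v for v in values.values() if v is not None]
    return float(np.mean(defined)) if defined else float("nan")


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold."""

    fold_id: str
    confusion: pd.DataFrame
    accuracy: float
    precision: dict
    recall: dict
    epsilon: float
    model_config: ModelConfig

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "confusion": {t: {p: int(self.confusion.loc[t, p])
                              for p in self.confusion.columns}
                          for t in self.confusion.index},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "epsilon": self.epsilon,
            "model": self.model_config.describe(),
        }


# ---------------------------------------------------------------------------
# Experiment 1: session k-fold


class _FeatureCache:
    """Per-(epsilon, session) feature tables; windows segmented once."""

    def __init__(self, sessions, sensors, seg_config, rqa_kwargs):
        self.sensors = tuple(sensors)
        self.rqa_kwargs = dict(rqa_kwargs)
        self.windows = {
            (s.participant_id, s.session_id):
                segment_session(s, seg_config, self.sensors)
            for s in sessions
        }
        self._tables: dict = {}

    def table(self, eps: float, session_key) -> pd.DataFrame:
        key = (float(eps), session_key)
        if key not in self._tables:
            config = RQAConfig(epsilon=float(eps), **self.rqa_kwargs)
            self._tables[key] = feature_table_from_windows(
                self.windows[session_key], self.sensors, config
            )
        return self._tables[key]

    def concat(self, eps: float, session_keys) -> pd.DataFrame:
        return pd.concat([self.table(eps, k) for k in session_keys],
                         ignore_index=True)


def session_kfold(sessions, sensors, *,
                  seg_config: SegmentationConfig | None = None,
                  model_grid=None, eps_grid=None, seed: int = 0,
                  rqa_kwargs=None) -> list:
    """Within-participant k-fold over sessions (k = number of sessions).

    All sessions must belong to one participant and there must be at
    least two.  Hyperparameters are selected inside the training
    sessions: leave-one-session-out when three or more sessions remain,
    otherwise a seeded 80/20 window split of the single training
    session.  The final model trains on balanced data from all training
    sessions and is scored on the held-out session's natural
    distribution.  Returns one :class:`FoldResult` per session.
    """
    sessions = list(sessions)
    participants = {s.participant_id for s in sessions}
    if len(participants) != 1:
        raise ValueError("session_kfold expects sessions of one participant")
    if len(sessions) < 2:
        raise ValueError(
            f"participant {sessions[0].participant_id} has a single "
            f"session; no folds can be formed"
        )
    seg_config = seg_config or SegmentationConfig()
    model_grid = list(model_grid) if model_grid is not None \
        else default_model_grid("random_forest")
    eps_grid = list(eps_grid) if eps_grid is not None else list(epsilon_grid())
    cache = _FeatureCache(sessions, sensors, seg_config, rqa_kwargs or {})

    session_keys = [(s.participant_id, s.session_id) for s in sessions]
    results = []
    rng = np.random.default_rng(seed)
    for held_out in session_keys:
        fold_seed = int(rng.integers(2 ** 31 - 1))
        train_ids = [k for k in session_keys if k != held_out]

        if len(train_ids) >= 2:
            def folds(eps, _train_ids=train_ids):
                return [
                    (cache.concat(eps, [t for t in _train_ids if t != v]),
                     cache.table(eps, v))
                    for v in _train_ids
                ]
        else:
            only = train_ids[0]
            n_rows = len(cache.table(eps_grid[0], only))
            perm = np.random.default_rng(fold_seed).permutation(n_rows)
            cut = max(1, int(round(0.8 * n_rows)))
            tr_idx, va_idx = perm[:cut], perm[cut:]

            def folds(eps, _only=only, _tr=tr_idx, _va=va_idx):
                table = cache.table(eps, _only)
                return [(table.iloc[_tr].reset_index(drop=True),
                         table.iloc[_va].reset_index(drop=True))]

        best_eps, best_config, _ = select_hyperparameters(
            model_grid, eps_grid, folds, seed=fold_seed
        )
        test_table = mark_test(cache.table(best_eps, held_out))
        y_pred = fit_predict(best_config, cache.concat(best_eps, train_ids),
                             test_table, seed=fold_seed)
        confusion = confusion_table(test_table["label"].to_numpy(), y_pred)
        m = metrics(confusion)
        results.append(FoldResult(
            fold_id=held_out[1], confusion=confusion,
            accuracy=m["accuracy"], precision=m["precision"],
            recall=m["recall"], epsilon=best_eps,
            model_config=best_config,
        ))
    return results


def mean_accuracy(fold_results) -> float:
    return float(np.mean([r.accuracy for r in fold_results]))


def modal_hyperparameters(fold_results) -> tuple:
    """The (epsilon, model config) pair chosen most often across folds."""
    pairs = [(r.epsilon, r.model_config) for r in fold_results]
    uniq = sorted(set(pairs), key=lambda p: (p[0], p[1].capacity))
    return max(uniq, key=lambda p: pairs.count(p))


# ---------------------------------------------------------------------------
# Experiment 2: leave-one-participant-out with training-size curves


def leave_one_participant_out(sessions, sensors, *, epsilon: float,
                              model_config: ModelConfig,
                              K_grid=None,
                              seg_config: SegmentationConfig | None = None,
                              seed: int = 0,
                              rqa_kwargs=None) -> pd.DataFrame:
    """Person-independent evaluation over a training-size grid.

    For every left-out participant and factor K the pooled training rows
    of the other participants are uniformly subsampled to
    ``N_K = round(K * N)`` (minimum 1), balanced, used to fit the given
    model at the given epsilon, and scored on every window of the
    left-out participant.  If a subsample degenerates to a single class
    the majority label is predicted throughout.  Returns one row per
    (participant, K).
    """
    sessions = list(sessions)
    participants = sorted({s.participant_id for s in sessions})
    if len(participants) < 2:
        raise ValueError("leave-one-participant-out needs >= 2 participants")
    seg_config = seg_config or SegmentationConfig()
    K_grid = np.asarray(K_grid if K_grid is not None else training_size_grid(),
                        dtype=float)
    cache = _FeatureCache(sessions, sensors, seg_config, rqa_kwargs or {})
    by_participant = {
        p: [(s.participant_id, s.session_id) for s in sessions
            if s.participant_id == p]
        for p in participants
    }

    rng = np.random.default_rng(seed)
    records = []
    for participant in participants:
        train_ids = [sid for p in participants if p != participant
                     for sid in by_participant[p]]
        train_table = cache.concat(epsilon, train_ids)
        test_table = mark_test(cache.concat(epsilon,
                                            by_participant[participant]))
        y_test = test_table["label"].to_numpy()
        n_rows = len(train_table)
        for K in K_grid:
            sub_seed = int(rng.integers(2 ** 31 - 1))
            n_k = training_size(K, n_rows)
            idx = np.random.default_rng(sub_seed).choice(
                n_rows, size=n_k, replace=False
            )
            subsample = train_table.iloc[np.sort(idx)].reset_index(drop=True)
            y_pred = fit_predict(model_config, subsample, test_table,
                                 seed=sub_seed)
            confusion = confusion_table(y_test, y_pred)
            m = metrics(confusion)
            records.append({
                "participant": participant,
                "K": float(K),
                "N_K": n_k,
                "n_test": len(test_table),
                "accuracy": m["accuracy"],
                "macro_precision": _macro(m["precision"]),
                "macro_recall": _macro(m["recall"]),
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Experiment 3: sensor ablation and feature importance


def sensor_ablation(sessions, *, sensor_configs=ABLATION_CONFIGS,
                    seg_config: SegmentationConfig | None = None,
                    model_grid=None, eps_grid=None, seed: int = 0,
                    rqa_kwargs=None) -> pd.DataFrame:
    """Session k-fold accuracy per sensor configuration per participant.

    Emits one row per (participant, configuration) plus an ``average``
    row per configuration across participants; d = 9 per single sensor,
    27 for the full array.
    """
    sessions = list(sessions)
    participants = sorted({s.participant_id for s in sessions})
    records = []
    for sensors in sensor_configs:
        name = "+".join(sensors)
        accs = []
        for participant in participants:
            psessions = [s for s in sessions
                         if s.participant_id == participant]
            results = session_kfold(
                psessions, sensors, seg_config=seg_config,
                model_grid=model_grid, eps_grid=eps_grid, seed=seed,
                rqa_kwargs=rqa_kwargs,
            )
            acc = mean_accuracy(results)
            accs.append(acc)
            records.append({
                "participant": participant,
                "sensors": name,
                "d": 9 * len(sensors),
                "accuracy": acc,
            })
        records.append({
            "participant": "average",
            "sensors": name,
            "d": 9 * len(sensors),
            "accuracy": float(np.mean(accs)),
        })
    return pd.DataFrame.from_records(records)


def importance_report(sessions, sensors, *, epsilon: float,
                      n_trees: int = 100, top_k: int = 5,
                      seg_config: SegmentationConfig | None = None,
                      seed: int = 0, rqa_kwargs=None) -> dict:
    """Top-k OOB permutation importances per participant.

    Trains one random forest per participant on that participant's
    balanced windows at the given epsilon and ranks the sensor-qualified
    features by the forest's out-of-bag permutation importance.
    """
    sessions = list(sessions)
    participants = sorted({s.participant_id for s in sessions})
    seg_config = seg_config or SegmentationConfig()
    cache = _FeatureCache(sessions, sensors, seg_config, rqa_kwargs or {})
    report = {}
    rng = np.random.default_rng(seed)
    for participant in participants:
        session_keys = [(s.participant_id, s.session_id) for s in sessions
                        if s.participant_id == participant]
        p_seed = int(rng.integers(2 ** 31 - 1))
        table = balance_training_set(cache.concat(epsilon, session_keys),
                                     p_seed)
        clf = train(ModelConfig("random_forest", n_trees=n_trees),
                    table, p_seed)
        ranking = permutation_importance(clf, seed=p_seed)
        report[participant] = ranking[:top_k]
    return report


# ---------------------------------------------------------------------------
# Serialization helpers for experiment results


def fold_results_to_dict(fold_results) -> dict:
    return {
        "folds": [r.to_dict() for r in fold_results],
        "mean_accuracy": mean_accuracy(fold_results),
    }
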