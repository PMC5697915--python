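"""Predicting turn outcome from reactivation content.

Each event contributes three predictors: a continuous congruence measure
(Pc - Pi)/(Pc + Pi) from the posterior mass on the congruent vs incongruent
run direction, a locality measure (Pl - Pr)/(Pl + Pr) from the mass on the
arms adjacent vs remote to the animal (both run directions pooled), and the
mean ripple-band LFP power during the event.  A binary classification tree
(CART, Gini impurity) predicts correct vs error.  Because errors are rare,
correct events are subsampled to match the error count; the subsample /
10-fold cross-validation procedure is repeated 10 times, and significance
comes from 100 outcome-label shuffles per iteration (1,000 null accuracies;
the predictor columns are never permuted relative to each other).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .decoding import ArmProbabilities
from .synthetic_data import INBOUND, OUTBOUND, TrackModel

FEATURES_ALL = ("congruence", "locality", "ripple_power")


@dataclass
class PredictionResult:
    accuracy: float
    shuffle_accuracies: np.ndarray
    p_value: float
    n_iterations: int
    cv_folds: int
    n_events_per_class: int
    features: tuple


def congruence_measure(p_congruent: float, p_incongruent: float) -> float:
    """(Pc - Pi) / (Pc + Pi); in [-1, 1], positive for congruent content."""
    denom = p_congruent + p_incongruent
    if denom <= 0:
        raise ValueError("zero posterior mass")
    return (p_congruent - p_incongruent) / denom


def locality_measure(p_local: float, p_remote: float) -> float:
    """(Pl - Pr) / (Pl + Pr); computed for all events regardless of congruence."""
    denom = p_local + p_remote
    if denom <= 0:
        raise ValueError("zero posterior mass")
    return (p_local - p_remote) / denom


def measures_from_arm_probs(arm_probs: ArmProbabilities, corner_id: int,
                            run_direction: str, track: TrackModel = None):
    """Event-level (congruence, locality) from the six arm-probability sums."""
    track = track or TrackModel()
    incong = INBOUND if run_direction == OUTBOUND else OUTBOUND
    pc = sum(arm_probs.sums[(a, run_direction)] for a in (1, 2, 3))
    pi = sum(arm_probs.sums[(a, incong)] for a in (1, 2, 3))
    adjacent = track.adjacent_arms(corner_id)
    pl = sum(arm_probs.sums[(a, d)] for a in adjacent for d in (OUTBOUND, INBOUND))
    pr = sum(arm_probs.sums[(a, d)] for a in (1, 2, 3) if a not in adjacent
             for d in (OUTBOUND, INBOUND))
    return congruence_measure(pc, pi), locality_measure(pl, pr)


def build_predictor_table(rows: list) -> pd.DataFrame:
    """Assemble PredictorRow dicts (congruence, locality, ripple_power,
    outcome, section) into a table, dropping rows with undefined measures."""
    df = pd.DataFrame(rows)
    n0 = len(df)
    df = df.dropna(subset=[c for c in FEATURES_ALL if c in df.columns])
    df.attrs["n_dropped_undefined"] = n0 - len(df)
    return df.reset_index(drop=True)


def _cv_accuracy(X, y, n_folds, rng):
    """Pooled proportion-correct over stratified folds."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    correct = 0
    for train, test in skf.split(X, y):
        tree = DecisionTreeClassifier(criterion="gini",
                                      random_state=int(rng.integers(2**31 - 1)))
        tree.fit(X[train], y[train])
        correct += int((tree.predict(X[test]) == y[test]).sum())
    return correct / y.size


def train_predict(table: pd.DataFrame, seed: int = 0, features=FEATURES_ALL,
                  n_iterations: int = 10, cv_folds: int = 10,
                  n_shuffles_per_iteration: int = 100) -> PredictionResult:
    """Subsampled, cross-validated decision-tree prediction of turn outcome.

    Accuracy is the proportion of events classified correctly, pooled over
    folds and subsample iterations.  The null distribution reallocates the
    outcome labels (predictors kept jointly intact); add-one p-value against
    the 1,000 shuffle accuracies.
    """
    rng = np.random.default_rng(seed)
    features = tuple(features)
    y_all = (table["outcome"].to_numpy() == "error").astype(int)
    X_all = table[list(features)].to_numpy(dtype=float)
    n_err = int(y_all.sum())
    n_cor = int(y_all.size - n_err)
    if n_err < 2 or n_cor < 2:
        raise ValueError("need at least two events of each outcome")
    n_per = min(n_err, n_cor)
    cv_folds = min(cv_folds, n_per)
    err_idx = np.nonzero(y_all == 1)[0]
    cor_idx = np.nonzero(y_all == 0)[0]

    accs, null_accs = [], []
    for _ in range(n_iterations):
        sub_cor = rng.choice(cor_idx, size=n_per, replace=False)
        sub_err = (err_idx if n_err == n_per
                   else rng.choice(err_idx, size=n_per, replace=False))
        idx = np.concatenate([sub_cor, sub_err])
        X, y = X_all[idx], y_all[idx]
        accs.append(_cv_accuracy(X, y, cv_folds, rng))
        for _ in range(n_shuffles_per_iteration):
            y_sh = rng.permutation(y)
            null_accs.append(_cv_accuracy(X, y_sh, cv_folds, rng))
    accuracy = float(np.mean(accs))
    null_accs = np.asarray(null_accs)
    p = (1.0 + float((null_accs >= accuracy).sum())) / (1.0 + null_accs.size)
    return PredictionResult(accuracy=accuracy, shuffle_accuracies=null_accs,
                            p_value=p, n_iterations=n_iterations, cv_folds=cv_folds,
                            n_events_per_class=n_per, features=features)
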