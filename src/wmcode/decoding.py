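"""Cross-validated ensemble decoding of target location from spike counts.

A linear support-vector classifier (liblinear, one-vs-rest multiclass)
decodes the remembered target's grid column (left / center / right; or all
nine locations) from z-scored epoch-averaged firing rates of simultaneously
recorded units. Classes are balanced by subsampling without replacement,
repeated ``n_balance`` times; accuracy is the mean held-out accuracy over
stratified folds and balancing repeats. Ensembles grow greedily from the
best single unit up to 16 units. Chance level is estimated by label
shuffling with the identical protocol.

Feature standardisation and the SVM penalty C are fit on training folds
only (the scaler sits inside the cross-validated pipeline; C is selected by
an inner 3-fold search), so no test information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._utils import child_seed, rng_for

#: Default inner search grid for the SVM penalty.
C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

MAX_ENSEMBLE = 16


class SpikeCountSVM(ClassifierMixin, BaseEstimator):
    """Linear SVM over z-scored spike counts, sklearn-estimator shaped.

    Parameters
    ----------
    c_grid : tuple or None
        Values searched by an inner 3-fold cross-validation on the training
        data; ``None`` fixes the penalty at ``C``.
    C : float
        Penalty used when no grid search is requested.
    random_state : int
        Seeds the inner fold split.
    """

    def __init__(self, c_grid: tuple | None = C_GRID, C: float = 1.0,
                 random_state: int = 0):
        self.c_grid = c_grid
        self.C = C
        self.random_state = random_state

    def _build(self):
        # liblinear: linear kernel, one-vs-rest multiclass reduction
        svc = LinearSVC(C=self.C)
        pipe = make_pipeline(StandardScaler(), svc)
        if self.c_grid is None:
            return pipe
        inner = StratifiedKFold(3, shuffle=True,
                                random_state=self.random_state)
        return GridSearchCV(
            pipe, {"linearsvc__C": list(self.c_grid)}, cv=inner,
            scoring="accuracy", n_jobs=None)

    def fit(self, X, y):
        self.model_ = self._build().fit(np.asarray(X, dtype=float), y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome for one ensemble and label set."""

    accuracy: float
    confusion: np.ndarray          # rows: true class, cols: predicted
    classes: np.ndarray
    per_repeat: np.ndarray = field(default_factory=lambda: np.empty(0))


def _balance_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(idx))


def decode_cv(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    n_balance: int = 20,
    seed: int = 0,
    c_grid: tuple | None = C_GRID,
) -> DecodingResult:
    """Balanced, cross-validated decoding accuracy and confusion matrix.

    Classes are subsampled without replacement to the smallest class count,
    ``n_balance`` times; each balanced draw is decoded with stratified
    ``k_folds``-fold cross-validation and results are averaged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding requires at least two classes")
    short = classes[counts < k_folds]
    if len(short):
        raise ValueError(
            f"classes {short.tolist()} have fewer than {k_folds} trials")

    accs, cms = [], []
    for rep in range(n_balance):
        rng = rng_for(seed, "balance", rep)
        idx = _balance_indices(y, rng)
        Xb, yb = X[idx], y[idx]
        rs = child_seed(seed, "fold", rep)
        skf = StratifiedKFold(k_folds, shuffle=True, random_state=rs)
        clf = SpikeCountSVM(c_grid=c_grid, random_state=rs)
        pred = cross_val_predict(clf, Xb, yb, cv=skf)
        accs.append(float(np.mean(pred == yb)))
        cms.append(confusion_matrix(yb, pred, labels=classes))
    return DecodingResult(
        accuracy=float(np.mean(accs)),
        confusion=np.sum(cms, axis=0),
        classes=classes,
        per_repeat=np.asarray(accs),
    )


@dataclass
class GreedyEnsemble:
    """Greedily grown ensemble: ordered unit ids and the accuracy curve."""

    unit_ids: list
    accuracy_curve: list
    truncated: bool  # True when fewer candidates than the requested size


def greedy_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    unit_ids: list,
    max_size: int = MAX_ENSEMBLE,
    seed: int = 0,
    k_folds: int = 5,
    n_balance: int = 2,
    c_grid: tuple | None = None,
) -> GreedyEnsemble:
    """Grow an ensemble by exhaustive augmentation.

    Starts from the unit with the best single-unit decoding accuracy, then
    repeatedly adds the candidate that maximises the ensemble's accuracy,
    until ``max_size`` units. Ties go to the lowest unit id (candidates are
    scanned in id order and a strict improvement is required to switch).

    The search evaluates candidates with a lighter protocol than the final
    reported accuracies (fewer balancing repeats, fixed C by default);
    evaluate the returned ensemble with :func:`decode_cv` for reporting.
    """
    X = np.asarray(X, dtype=float)
    unit_ids = list(unit_ids)
    order = np.argsort(unit_ids)  # scan in id order for the tie-break
    truncated = len(unit_ids) < max_size
    target = min(max_size, len(unit_ids))

    chosen: list[int] = []      # column indices into X
    chosen_ids: list = []
    curve: list[float] = []
    remaining = [int(i) for i in order]
    step = 0
    while len(chosen) < target:
        best_acc, best_col = -np.inf, None
        for col in remaining:
            cols = chosen + [col]
            res = decode_cv(X[:, cols], y, k_folds=k_folds,
                            n_balance=n_balance,
                            seed=child_seed(seed, "greedy", step),
                            c_grid=c_grid)
            if res.accuracy > best_acc:
                best_acc, best_col = res.accuracy, col
        chosen.append(best_col)
        chosen_ids.append(unit_ids[best_col])
        remaining.remove(best_col)
        curve.append(best_acc)
        step += 1
    return GreedyEnsemble(unit_ids=chosen_ids, accuracy_curve=curve,
                          truncated=truncated)


@dataclass
class ShuffleNull:
    """Label-shuffle null distribution of decoding accuracy."""

    accuracies: np.ndarray  # one mean accuracy per shuffle
    chance: float
    flagged: bool  # null centred above the binomial chance band


def shuffle_null(
    X: np.ndarray,
    y: np.ndarray,
    n_shuffle: int = 10,
    k_folds: int = 5,
    n_balance: int = 20,
    seed: int = 0,
    c_grid: tuple | None = C_GRID,
) -> ShuffleNull:
    """Chance performance via label randomisation, all else unchanged.

    Each shuffle permutes the class labels and reruns the full balanced
    cross-validation; a session whose null mean exceeds the upper 2-SE
    binomial chance bound is flagged for exclusion.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    chance = 1.0 / len(classes)
    n_test = counts.min() * len(classes)
    accs = []
    for s in range(n_shuffle):
        rng = rng_for(seed, "shuffle", s)
        y_perm = rng.permutation(y)
        res = decode_cv(X, y_perm, k_folds=k_folds, n_balance=n_balance,
                        seed=child_seed(seed, "shuffle_cv", s),
                        c_grid=c_grid)
        accs.append(res.accuracy)
    accs = np.asarray(accs)
    se = np.sqrt(chance * (1 - chance) / n_test)
    flagged = bool(accs.mean() > chance + 2.0 * se)
    return ShuffleNull(accuracies=accs, chance=chance, flagged=flagged)
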