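"""Classifiers over pair vectors and the leakage-aware cross-validation driver.

The in-repo baseline is a from-scratch k-nearest-neighbours classifier
(``KnnClassifier``) supporting Euclidean and cosine distance with uniform or
inverse-distance vote weighting.  All other families (random forest, the four
SVM kernels, gradient boosting) are thin adapters over scikit-learn and
xgboost behind a single ``ClassifierSpec`` contract, since those solvers are
commodity components; only the KNN baseline is reimplemented and oracle-tested.

Scores are always the probability of the *cross-feeding* class; the decision
threshold defaults to 0.5 and a score exactly at the threshold predicts
cross-feeding (the majority class under the prevalences this tool targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._exceptions import CapabilityError, ValidationError
from .encoding import (
    COMPETITION,
    CROSS_FEEDING,
    OrganismProfile,
    PairDataset,
    encode_pair,
)
from .folding import FoldAssignment, audit_leakage
from .metrics import ConfusionCounts

EPSILON = 1e-12  # guards inverse-distance weights against zero distances
DEFAULT_THRESHOLD = 0.5

FAMILIES = (
    "knn",
    "random_forest",
    "svm_linear",
    "svm_rbf",
    "svm_poly",
    "svm_sigmoid",
    "gradient_boosting",
)


def _score_to_label(scores: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    return np.where(scores >= threshold, CROSS_FEEDING, COMPETITION).astype(object)


class KnnClassifier:
    """k-nearest-neighbours on binary pair vectors, written from scratch.

    Parameters
    ----------
    k : number of neighbours (must not exceed the training-set size).
    metric : ``"euclidean"`` or ``"cosine"``.
    weighting : ``"uniform"`` (score = fraction of neighbours labelled
        cross-feeding) or ``"distance"`` (votes weighted by 1/(d+eps)).

    Ties at the k-th distance are broken by stable training-index order, so
    predictions are deterministic.
    """

    def __init__(self, k: int = 3, metric: str = "euclidean", weighting: str = "uniform"):
        if k < 1:
            raise ValidationError("k must be >= 1")
        if metric not in ("euclidean", "cosine"):
            raise ValidationError(f"unknown metric {metric!r}")
        if weighting not in ("uniform", "distance"):
            raise ValidationError(f"unknown weighting {weighting!r}")
        self.k = k
        self.metric = metric
        self.weighting = weighting
        self._X: Optional[np.ndarray] = None
        self._y: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "KnnClassifier":
        X = np.asarray(X, dtype=np.float64)
        labels = np.asarray(labels, dtype=object)
        if X.ndim != 2 or len(labels) != X.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        if self.k > X.shape[0]:
            raise ValidationError(f"k={self.k} exceeds training size {X.shape[0]}")
        self._X = X
        self._y = (labels == CROSS_FEEDING).astype(np.float64)
        return self

    def _distances(self, Q: np.ndarray) -> np.ndarray:
        assert self._X is not None
        X = self._X
        if Q.shape[1] != X.shape[1]:
            raise ValidationError(f"query dimension {Q.shape[1]} != training {X.shape[1]}")
        cross = Q @ X.T
        if self.metric == "euclidean":
            sq = (Q * Q).sum(1)[:, None] + (X * X).sum(1)[None, :] - 2.0 * cross
            return np.sqrt(np.clip(sq, 0.0, None))
        qn = np.sqrt((Q * Q).sum(1))[:, None]
        xn = np.sqrt((X * X).sum(1))[None, :]
        denom = qn * xn
        if np.any(denom == 0):
            raise ValidationError("cosine distance undefined for all-zero vectors")
        return 1.0 - cross / denom

    def kneighbors(self, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices and distances of the k nearest training vectors per query."""
        if self._X is None:
            raise ValidationError("classifier is not fitted")
        Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
        dist = self._distances(Q)
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        return order, np.take_along_axis(dist, order, axis=1)

    def predict_scores(self, Q: np.ndarray) -> np.ndarray:
        """Probability-of-cross-feeding score per query row."""
        idx, dist = self.kneighbors(Q)
        votes = self._y[idx]
        if self.weighting == "uniform":
            return votes.mean(axis=1)
        w = 1.0 / (dist + EPSILON)
        return (w * votes).sum(axis=1) / w.sum(axis=1)

    def predict(self, Q: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        return _score_to_label(self.predict_scores(Q), threshold)


class _SklearnAdapter:
    """Wrap an sklearn-style estimator under the fit/predict_scores contract."""

    def __init__(self, estimator, score_mode: str):
        self.estimator = estimator
        self.score_mode = score_mode  # "proba" or "decision"
        self._classes: Optional[np.ndarray] = None

    def fit(self, X, labels):
        y = (np.asarray(labels, dtype=object) == CROSS_FEEDING).astype(int)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")
        self.estimator.fit(np.asarray(X, dtype=np.float64), y)
        return self

    def predict_scores(self, Q) -> np.ndarray:
        Q = np.asarray(Q, dtype=np.float64)
        if self.score_mode == "proba":
            proba = self.estimator.predict_proba(Q)
            return proba[:, list(self.estimator.classes_).index(1)]
        from scipy.special import expit

        return expit(self.estimator.decision_function(Q))

    def predict(self, Q, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        return _score_to_label(self.predict_scores(Q), threshold)


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of a classifier run."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown classifier family {self.family!r}; choose from {FAMILIES}")

    def build(self):
        """Instantiate the (unfitted) classifier behind this spec."""
        hp = dict(self.hyperparameters)
        if self.family == "knn":
            return KnnClassifier(
                k=int(hp.pop("k", 3)),
                metric=hp.pop("metric", "euclidean"),
                weighting=hp.pop("weighting", "uniform"),
            )
        try:
            if self.family == "random_forest":
                from sklearn.ensemble import RandomForestClassifier

                return _SklearnAdapter(
                    RandomForestClassifier(
                        n_estimators=int(hp.pop("n_estimators", 100)),
                        random_state=self.seed,
                        **hp,
                    ),
                    "proba",
                )
            if self.family.startswith("svm_"):
                from sklearn.svm import SVC

                kernel = {"svm_linear": "linear", "svm_rbf": "rbf",
                          "svm_poly": "poly", "svm_sigmoid": "sigmoid"}[self.family]
                return _SklearnAdapter(SVC(kernel=kernel, random_state=self.seed, **hp), "decision")
            if self.family == "gradient_boosting":
                from xgboost import XGBClassifier

                return _SklearnAdapter(
                    XGBClassifier(
                        n_estimators=int(hp.pop("n_estimators", 100)),
                        random_state=self.seed,
                        eval_metric="logloss",
                        **hp,
                    ),
                    "proba",
                )
        except ImportError as exc:
            raise CapabilityError(f"classifier family {self.family!r} unavailable: {exc}") from exc
        raise CapabilityError(f"no builder for family {self.family!r}")

    def describe(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in sorted(self.hyperparameters.items()))
        return f"{self.family}({hp})" if hp else self.family


@dataclass
class PredictionSet:
    """Pooled per-vector predictions from a cross-validation run."""

    pair_keys: list[tuple[str, str]]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray          # probability of cross-feeding
    fold_indices: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValidationError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "pair_key": ["|".join(k) for k in self.pair_keys],
            "true_label": self.true_labels,
            "predicted_label": self.predicted_labels,
            "score_cf": self.scores,
            "fold": self.fold_indices,
        })


def cross_validate(
    spec: ClassifierSpec,
    dataset: PairDataset,
    folds: FoldAssignment,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[PredictionSet, ConfusionCounts]:
    """K-fold cross-validation with pair-level (leakage-free) splits.

    For each fold, trains on the oriented vectors of every other fold and
    predicts the held-out fold's oriented vectors; predictions and confusion
    counts are pooled over folds.
    """
    report = audit_leakage(folds, dataset)
    if not report.ok:
        raise ValidationError(f"fold assignment leaks: {report.violations[:5]}")

    X = dataset.matrix().astype(np.float64)
    y = dataset.labels()
    fold_of = np.array([folds.assignment[v.pair_key] for v in dataset.vectors])

    keys: list[tuple[str, str]] = []
    true, pred, scores, fold_ix = [], [], [], []
    for f in range(folds.n_folds):
        test_mask = fold_of == f
        if not test_mask.any():
            continue
        model = spec.build()
        model.fit(X[~test_mask], y[~test_mask])
        s = model.predict_scores(X[test_mask])
        keys.extend(v.pair_key for v, m in zip(dataset.vectors, test_mask) if m)
        true.append(y[test_mask])
        pred.append(_score_to_label(s, threshold))
        scores.append(s)
        fold_ix.append(np.full(int(test_mask.sum()), f))

    predictions = PredictionSet(
        pair_keys=keys,
        true_labels=np.concatenate(true),
        predicted_labels=np.concatenate(pred),
        scores=np.concatenate(scores),
        fold_indices=np.concatenate(fold_ix),
    )
    counts = ConfusionCounts.from_labels(predictions.true_labels, predictions.predicted_labels)
    return predictions, counts


def select_k(
    dataset: PairDataset,
    k_values: Sequence[int] = tuple(range(1, 31)),
    train_fraction: float = 0.67,
    data_fraction: float = 1.0,
    seed: int = 0,
    metric: str = "euclidean",
    weighting: str = "uniform",
) -> tuple[int, dict[int, float]]:
    """Pick k for the KNN baseline on a single leakage-aware hold-out split.

    A fraction ``data_fraction`` of the unordered pairs is sampled first
    (both orientations together), then split ``train_fraction`` /
    1-train_fraction at the pair level.  Returns the accuracy-maximising k
    (ties broken toward smaller k) and the full accuracy-per-k table.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    keys = dataset.pair_keys_unique()
    if data_fraction < 1.0:
        n_keep = max(2, int(round(data_fraction * len(keys))))
        keep_ix = rng.choice(len(keys), size=n_keep, replace=False)
        keys = [keys[i] for i in sorted(keep_ix)]
    keyset = set(keys)
    perm = rng.permutation(len(keys))
    n_train = int(round(train_fraction * len(keys)))
    train_keys = {keys[i] for i in perm[:n_train]}

    X = dataset.matrix().astype(np.float64)
    y = dataset.labels()
    in_subset = np.array([v.pair_key in keyset for v in dataset.vectors])
    in_train = np.array([v.pair_key in train_keys for v in dataset.vectors]) & in_subset
    in_test = in_subset & ~in_train
    n_train_vec = int(in_train.sum())
    if n_train_vec < max(k_values):
        raise ValidationError(
            f"training set ({n_train_vec} vectors) smaller than max k ({max(k_values)})"
        )
    if not in_test.any():
        raise ValidationError("empty test split")

    # one distance matrix, reused across k values
    probe = KnnClassifier(k=max(k_values), metric=metric, weighting=weighting)
    probe.fit(X[in_train], y[in_train])
    idx, dist = probe.kneighbors(X[in_test])
    votes = probe._y[idx]
    y_test = y[in_test]

    accuracies: dict[int, float] = {}
    for k in k_values:
        if weighting == "uniform":
            s = votes[:, :k].mean(axis=1)
        else:
            w = 1.0 / (dist[:, :k] + EPSILON)
            s = (w * votes[:, :k]).sum(axis=1) / w.sum(axis=1)
        predicted = _score_to_label(s)
        accuracies[int(k)] = float((predicted == y_test).mean())
    best_k = min(accuracies, key=lambda k: (-accuracies[k], k))
    return best_k, accuracies


def predict_pair(model, a: OrganismProfile, b: OrganismProfile,
                 threshold: float = DEFAULT_THRESHOLD) -> tuple[str, float]:
    """Orientation-invariant prediction for one pair of organisms.

    Scores both concatenation orders and averages, so the result does not
    depend on which organism is listed first.
    """
    ab = encode_pair(a, b).bits.astype(np.float64)
    ba = encode_pair(b, a).bits.astype(np.float64)
    scores = model.predict_scores(np.vstack([ab, ba]))
    score = float(scores.mean())
    label = CROSS_FEEDING if score >= threshold else COMPETITION
    return label, score


def predict_all_pairs(model, profiles: Sequence[OrganismProfile],
                      threshold: float = DEFAULT_THRESHOLD):
    """Predict every unordered pair among the given organisms.

    Returns a DataFrame with one row per unordered pair (m organisms give
    m*(m-1)/2 rows) carrying the orientation-averaged score and label.
    """
    import pandas as pd

    if len({p.pool_hash for p in profiles}) > 1:
        raise ValidationError("profiles come from different pools")
    rows = []
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            label, score = predict_pair(model, a, b, threshold)
            rows.append((a.organism_id, b.organism_id, label, score))
    return pd.DataFrame(rows, columns=["organism_a", "organism_b", "label", "score_cf"])
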