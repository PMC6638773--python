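"""Base learners behind a uniform fit / predict / confidence contract.

Five classifier families (naive Bayes, decision tree, logistic regression,
RBF SVM, multilayer perceptron) wrap scikit-learn estimators.  Confidence is
the estimated probability of the predicted class: predicted-class posterior
for NB/LR/MLP, leaf class proportion for the tree, and a Platt-calibrated
probability for the SVM (a margin is not a probability).  Feature vectors
are name->value mappings vectorised with a DictVectorizer fitted on the
training set, so train/apply feature alignment is automatic.

Default hyper-parameters follow the tuned settings of the study this package
operationalises: LR with L2 and C=1e-5; SVM with an RBF kernel and C=0.01;
MLP with two 128-unit hidden layers, learning rate 0.001, alpha=1e-4, batch
size 200, 100 epochs, Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("naive_bayes", "decision_tree", "logistic_regression", "svm", "mlp")

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

_DEFAULTS: dict[str, dict] = {
    "naive_bayes": {"alpha": 1.0},
    "decision_tree": {},
    # sklearn's LogisticRegression penalises L2 by default; C sets strength.
    "logistic_regression": {"C": 1e-5, "max_iter": 1000},
    "svm": {"kernel": "rbf", "C": 0.01},
    "mlp": {
        "hidden_layer_sizes": (128, 128),
        "learning_rate_init": 0.001,
        "alpha": 1e-4,
        "batch_size": 200,
        "max_iter": 100,
        "solver": "adam",
    },
}


@dataclass(frozen=True)
class LearnerSpec:
    """A classifier family plus hyper-parameters and a seed."""

    family: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family: {self.family!r}")

    def with_seed(self, seed: int) -> "LearnerSpec":
        return replace(self, seed=seed)

    def resolved_params(self) -> dict:
        params = dict(_DEFAULTS[self.family])
        params.update(self.hyperparams)
        return params


def _index32(M):
    """Downcast sparse indices to int32 (SVC refuses int64 indices)."""
    if hasattr(M, "indices"):
        M.indices = M.indices.astype(np.int32, copy=False)
        M.indptr = M.indptr.astype(np.int32, copy=False)
    return M


def _make_estimator(spec: LearnerSpec):
    p = spec.resolved_params()
    if spec.family == "naive_bayes":
        return MultinomialNB(**p)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.family == "logistic_regression":
        return LogisticRegression(random_state=spec.seed, **p)
    if spec.family == "svm":
        return SVC(probability=True, random_state=spec.seed, **p)
    if spec.family == "mlp":
        return MLPClassifier(random_state=spec.seed, **p)
    raise AssertionError(spec.family)


@dataclass
class LearnerModel:
    """A fitted classifier over dict feature vectors."""

    spec: LearnerSpec
    vectorizer: DictVectorizer
    estimator: object
    classes: tuple[str, ...]

    @property
    def feature_names(self) -> list[str]:
        return list(self.vectorizer.get_feature_names_out())

    def _matrix(self, X: Sequence[Mapping[str, float]]):
        return _index32(self.vectorizer.transform(X))

    def predict(self, X: Sequence[Mapping[str, float]]) -> np.ndarray:
        return self.estimator.predict(self._matrix(X))

    def predict_proba(self, X: Sequence[Mapping[str, float]]) -> np.ndarray:
        return self.estimator.predict_proba(self._matrix(X))

    def predict_with_confidence(
        self, X: Sequence[Mapping[str, float]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels and the probability of the predicted class."""
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        labels = np.asarray(self.estimator.classes_)[idx]
        conf = proba[np.arange(len(idx)), idx]
        return labels, conf


def fit(
    spec: LearnerSpec,
    X: Sequence[Mapping[str, float]],
    y: Sequence[str],
) -> LearnerModel:
    """Train one model.  Requires both classes present and finite features."""
    if len(X) != len(y) or len(X) == 0:
        raise ValueError("X and y must be equal-length and non-empty")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training data must contain two classes")
    vectorizer = DictVectorizer(sparse=True)
    M = _index32(vectorizer.fit_transform(X))
    if not np.all(np.isfinite(M.data)):
        raise ValueError("feature matrix contains non-finite values")
    est = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(M, np.asarray(y))
    return LearnerModel(spec=spec, vectorizer=vectorizer, estimator=est, classes=tuple(classes))


def predict_with_confidence(
    model: LearnerModel, x: Mapping[str, float]
) -> tuple[str, float]:
    """Single-instance convenience wrapper over the batched method."""
    labels, conf = model.predict_with_confidence([x])
    return str(labels[0]), float(conf[0])


def oversample(
    X: Sequence[Mapping[str, float]],
    y: Sequence[str],
    target_minority_fraction: float = 0.47,
    seed: int = 0,
) -> tuple[list, list]:
    """Random duplication oversampling of the minority class.

    Minority instances are duplicated with replacement (appended after the
    originals) until the minority fraction reaches the target.  The original
    set is always a sub-multiset of the output.  Never apply this to test
    data.
    """
    if not (0 < target_minority_fraction <= 0.5):
        raise ValueError("target_minority_fraction must be in (0, 0.5]")
    y = list(y)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("oversampling needs two classes")
    counts = {c: y.count(c) for c in classes}
    minority = min(classes, key=lambda c: (counts[c], c))
    n_min, n_maj = counts[minority], len(y) - counts[minority]
    X_out, y_out = list(X), list(y)
    if n_min / (n_min + n_maj) >= target_minority_fraction:
        return X_out, y_out
    t = target_minority_fraction
    needed = int(np.ceil(t * n_maj / (1 - t))) - n_min
    rng = np.random.default_rng(seed)
    pool = [i for i, lbl in enumerate(y) if lbl == minority]
    for i in rng.choice(pool, size=needed, replace=True):
        X_out.append(X[int(i)])
        y_out.append(minority)
    return X_out, y_out


def grid_search(
    spec_grid: Sequence[LearnerSpec],
    X: Sequence[Mapping[str, float]],
    y: Sequence[str],
    holdout_fraction: float = 0.1,
    metric: str = "F2",
    seed: int = 0,
) -> LearnerSpec:
    """Pick the spec maximising F-beta on a held-out slice of the training
    partition (ties broken by first-in-grid order)."""
    from .evaluation import confusion, f_beta, prf_accuracy

    if not spec_grid:
        raise ValueError("empty spec grid")
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must be in (0,1)")
    beta = {"F1": 1.0, "F2": 2.0}[metric]

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    n_hold = max(1, int(round(holdout_fraction * len(X))))
    hold, train = idx[:n_hold], idx[n_hold:]
    X_tr = [X[i] for i in train]
    y_tr = [y[i] for i in train]
    X_ho = [X[i] for i in hold]
    y_ho = [y[i] for i in hold]
    if len(set(y_tr)) < 2:  # degenerate split: fall back to training on all
        X_tr, y_tr, X_ho, y_ho = list(X), list(y), list(X), list(y)

    best_spec, best_score = None, -np.inf
    for spec in spec_grid:
        model = fit(spec, X_tr, y_tr)
        pred = model.predict(X_ho)
        cm = confusion(pred, y_ho)
        p, r, _ = prf_accuracy(cm)
        score = f_beta(p, r, beta) if np.isfinite(p) and np.isfinite(r) else 0.0
        if score > best_score:
            best_spec, best_score = spec, score
    return best_spec
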