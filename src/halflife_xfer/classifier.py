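"""Feedforward classifier routing proteins to half-life clusters.

A single-hidden-layer network (24 units by default, logistic activation,
softmax-style 3-class output) maps the seven transformed cellular
properties to a probability distribution over the bands C1/C2/C3. The
empirical cluster sizes act as class priors and can reweight the
network's probabilities at classification time, mirroring the use of the
observed cluster distribution when routing unseen proteins. Features are
z-scored on the training set; the scaling is stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .datamodel import (Dataset, DomainError, InsufficientDataError,
                        ProteinRecord, TransformConfig, feature_matrix,
                        transform_features)
from .clustering import CLUSTERS, ClusterAssignment


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training settings for the cluster classifier."""

    hidden_units: int = 24
    activation: str = "logistic"
    max_epochs: int = 2000
    alpha: float = 1e-4           # L2 regularization
    seed: int = 0
    use_priors_default: bool = True


@dataclass
class TrainedClassifier:
    """Fitted network plus its scaler, priors and training diagnostics."""

    net: MLPClassifier
    scaler: StandardScaler
    classes: tuple[str, ...]
    class_priors: np.ndarray
    spec: ClassifierSpec
    transform: TransformConfig
    training_accuracy: float


def _labeled_features(dataset: Dataset, assignment: ClusterAssignment,
                      transform: TransformConfig):
    by_id = {r.protein_id: r for r in dataset.common}
    recs = [by_id[pid] for pid in assignment.labels if pid in by_id]
    X = feature_matrix(recs, transform)
    y = np.array([assignment.labels[r.protein_id] for r in recs])
    return X, y


def _fit_net(X, y, spec: ClassifierSpec) -> tuple[MLPClassifier, StandardScaler]:
    scaler = StandardScaler().fit(X)
    net = MLPClassifier(hidden_layer_sizes=(spec.hidden_units,),
                        activation=spec.activation, solver="lbfgs",
                        alpha=spec.alpha, max_iter=spec.max_epochs,
                        random_state=spec.seed)
    net.fit(scaler.transform(X), y)
    return net, scaler


def train_classifier(dataset: Dataset, assignment: ClusterAssignment,
                     spec: ClassifierSpec = ClassifierSpec(),
                     transform: TransformConfig = TransformConfig()
                     ) -> TrainedClassifier:
    """Train the cluster classifier on the labeled common proteins."""
    X, y = _labeled_features(dataset, assignment, transform)
    for c in CLUSTERS:
        n_c = int(np.sum(y == c))
        if n_c < 10:
            raise InsufficientDataError(
                f"class {c} has {n_c} labeled protein(s); need >= 10")
    net, scaler = _fit_net(X, y, spec)
    acc = float(np.mean(net.predict(scaler.transform(X)) == y))
    priors = np.array([np.mean(y == c) for c in CLUSTERS])
    return TrainedClassifier(net=net, scaler=scaler, classes=CLUSTERS,
                             class_priors=priors, spec=spec,
                             transform=transform, training_accuracy=acc)


def _reorder(proba: np.ndarray, net_classes, classes) -> np.ndarray:
    order = [list(net_classes).index(c) for c in classes]
    return proba[:, order]


def classify(record: ProteinRecord, clf: TrainedClassifier,
             use_priors: bool | None = None) -> tuple[str, np.ndarray]:
    """Route one protein to a cluster; returns (label, probabilities).

    With ``use_priors`` the network's class probabilities are multiplied
    by the empirical cluster priors and renormalized before the argmax.
    """
    if use_priors is None:
        use_priors = clf.spec.use_priors_default
    fv = transform_features(record, clf.transform)  # raises on missing feature
    X = clf.scaler.transform(fv.as_array()[None, :])
    proba = _reorder(clf.net.predict_proba(X), clf.net.classes_, clf.classes)[0]
    if use_priors:
        proba = proba * clf.class_priors
        proba = proba / proba.sum()
    label = clf.classes[int(np.argmax(proba))]
    return label, proba


def classify_many(records: list[ProteinRecord], clf: TrainedClassifier,
                  use_priors: bool | None = None
                  ) -> tuple[list[str], np.ndarray]:
    """Vectorized ``classify`` over a list of records."""
    if use_priors is None:
        use_priors = clf.spec.use_priors_default
    X = clf.scaler.transform(feature_matrix(records, clf.transform))
    proba = _reorder(clf.net.predict_proba(X), clf.net.classes_, clf.classes)
    if use_priors:
        proba = proba * clf.class_priors
        proba = proba / proba.sum(axis=1, keepdims=True)
    labels = [clf.classes[i] for i in np.argmax(proba, axis=1)]
    return labels, proba


def cross_validated_accuracy(dataset: Dataset, assignment: ClusterAssignment,
                             spec: ClassifierSpec = ClassifierSpec(),
                             transform: TransformConfig = TransformConfig(),
                             n_folds: int = 3) -> float:
    """Stratified k-fold accuracy of the classifier configuration."""
    X, y = _labeled_features(dataset, assignment, transform)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=spec.seed)
    correct = 0
    for tr, te in skf.split(X, y):
        net, scaler = _fit_net(X[tr], y[tr], spec)
        correct += int(np.sum(net.predict(scaler.transform(X[te])) == y[te]))
    return correct / len(y)


def pick_best_candidate(accuracies: dict[int, float]) -> int:
    """Highest cross-validated accuracy; ties go to the smallest count."""
    return max(sorted(accuracies), key=lambda h: (accuracies[h], -h))


def select_hidden_units(dataset: Dataset, assignment: ClusterAssignment,
                        candidate_counts=(4, 8, 16, 24, 32),
                        spec: ClassifierSpec = ClassifierSpec(),
                        transform: TransformConfig = TransformConfig(),
                        n_folds: int = 3) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer width by cross-validated accuracy.

    Ties go to the smallest candidate. Returns (best count, accuracy per
    candidate).
    """
    if not candidate_counts:
        raise DomainError("candidate_counts must be nonempty")
    accs: dict[int, float] = {}
    for h in candidate_counts:
        s = ClassifierSpec(hidden_units=h, activation=spec.activation,
                           max_epochs=spec.max_epochs, alpha=spec.alpha,
                           seed=spec.seed,
                           use_priors_default=spec.use_priors_default)
        accs[h] = cross_validated_accuracy(dataset, assignment, s,
                                           transform, n_folds)
    return pick_best_candidate(accs), accs


__all__ = ["ClassifierSpec", "TrainedClassifier", "train_classifier",
           "classify", "classify_many", "cross_validated_accuracy",
           "pick_best_candidate", "select_hidden_units"]
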