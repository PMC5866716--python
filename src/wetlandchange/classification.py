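"""Supervised per-pixel classification with a fixed ten-algorithm roster.

The roster mirrors the algorithm families commonly compared in thematic
mapping studies: discriminant analysis (``amdai``, ``mda``), a model-averaged
shallow neural network (``avNNet``), stochastic gradient boosting (``gbm``),
k-nearest neighbours (``knn``), a partial-least-squares classifier (``pls``),
random forest (``rf``) and support vector machines with linear, polynomial
and radial-basis kernels. Learner implementations are off-the-shelf
scikit-learn estimators; the package's contribution is the surrounding
contract — the roster, name-bound features, seeding, and full-scene map
production. Two families without a scikit-learn mixture-discriminant
implementation alias to the closest discriminant-analysis estimator and the
alias is recorded in :data:`ROSTER_NOTES`.

Features bind by *name*, not position: a stack with permuted feature order
yields an identical map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .raster import FeatureStack, HabitatMap, NODATA_LABEL
from .sampling import LabeledSamples

log = logging.getLogger(__name__)


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares discriminant analysis.

    PLS regression on one-hot class indicators; prediction is the argmax of
    the fitted indicator scores — the standard PLS-DA construction.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        Y = (np.asarray(y)[:, None] == self.classes_[None, :]).astype(float)
        ncomp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=ncomp)
        self.pls_.fit(X, Y)
        return self

    def predict(self, X):
        scores = self.pls_.predict(X)
        return self.classes_[np.argmax(scores, axis=1)]


class AveragedMLPClassifier(BaseEstimator, ClassifierMixin):
    """Model-averaged shallow neural network.

    Averages the class probabilities of ``n_models`` single-hidden-layer
    perceptrons trained from different random initialisations.
    """

    def __init__(self, hidden: int = 16, n_models: int = 5, max_iter: int = 400,
                 random_state: int = 0):
        self.hidden = hidden
        self.n_models = n_models
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.models_ = []
        for i in range(self.n_models):
            m = MLPClassifier(hidden_layer_sizes=(self.hidden,),
                              max_iter=self.max_iter,
                              random_state=self.random_state + i)
            import warnings
            from sklearn.exceptions import ConvergenceWarning
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                m.fit(X, y)
            self.models_.append(m)
        return self

    def predict(self, X):
        proba = np.mean([m.predict_proba(X) for m in self.models_], axis=0)
        return self.classes_[np.argmax(proba, axis=1)]


def _factory(builder: Callable[[dict, int], BaseEstimator], scale: bool = True):
    def make(hyper: dict, seed: int):
        est = builder(dict(hyper), seed)
        return make_pipeline(StandardScaler(), est) if scale else est
    return make


ROSTER: dict[str, Callable[[dict, int], BaseEstimator]] = {
    "amdai": _factory(lambda h, s: QuadraticDiscriminantAnalysis(
        reg_param=h.pop("reg_param", 0.02), **h)),
    "avNNet": _factory(lambda h, s: AveragedMLPClassifier(
        random_state=s, **h)),
    "gbm": _factory(lambda h, s: GradientBoostingClassifier(
        n_estimators=h.pop("n_estimators", 100),
        max_depth=h.pop("max_depth", 3), random_state=s, **h), scale=False),
    "knn": _factory(lambda h, s: KNeighborsClassifier(
        n_neighbors=h.pop("n_neighbors", 5), **h)),
    "mda": _factory(lambda h, s: LinearDiscriminantAnalysis(**h)),
    "pls": _factory(lambda h, s: PLSDAClassifier(
        n_components=h.pop("n_components", 4), **h)),
    "rf": _factory(lambda h, s: RandomForestClassifier(
        n_estimators=h.pop("n_estimators", 200), random_state=s, **h),
        scale=False),
    "svmLinear": _factory(lambda h, s: SVC(
        kernel="linear", C=h.pop("C", 1.0), random_state=s, **h)),
    "svmPoly": _factory(lambda h, s: SVC(
        kernel="poly", degree=h.pop("degree", 3), C=h.pop("C", 1.0),
        random_state=s, **h)),
    "svmRadial": _factory(lambda h, s: SVC(
        kernel="rbf", C=h.pop("C", 1.0), random_state=s, **h)),
}

#: Where a named algorithm family has no exact scikit-learn counterpart, the
#: concrete estimator standing in for it.
ROSTER_NOTES = {
    "amdai": "adaptive mixture discriminant analysis -> regularized QDA",
    "mda": "mixture discriminant analysis -> LDA",
    "pls": "PLS classifier realised as PLS-DA (one-hot regression + argmax)",
    "avNNet": "averaged neural net -> soft-vote mean of 5 seeded MLPs",
}


def register_algorithm(algorithm_id: str,
                       factory: Callable[[dict, int], BaseEstimator]) -> None:
    """Register a custom learner under a new roster id."""
    ROSTER[algorithm_id] = factory


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm_id: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ROSTER:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; roster: "
                f"{sorted(ROSTER)}")


@dataclass
class FittedModel:
    """A trained classifier bound to its feature names and legend."""

    spec: ClassifierSpec
    estimator: BaseEstimator
    feature_names: list[str]
    classes: list[int]
    legend: dict[int, str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))


def train(samples: LabeledSamples, spec: ClassifierSpec) -> FittedModel:
    """Fit one roster algorithm on the training-role samples.

    Deterministic given (samples, spec): all stochastic learners receive
    ``spec.seed``. Raises on a single-class training set.
    """
    tr = samples.subset("training") if (samples.role != "training").any() else samples
    classes = np.unique(tr.y)
    if len(tr) == 0:
        raise ValueError("no training samples")
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if spec.algorithm_id in ROSTER_NOTES:
        log.info("roster alias: %s", ROSTER_NOTES[spec.algorithm_id])
    est = ROSTER[spec.algorithm_id](dict(spec.hyperparameters), spec.seed)
    est.fit(tr.X, tr.y)
    return FittedModel(spec, est, list(samples.feature_names),
                       [int(c) for c in classes], dict(samples.legend))


def predict_map(model: FittedModel, stack: FeatureStack,
                legend: Mapping[int, str] | None = None) -> HabitatMap:
    """Predict a full-scene habitat map from a feature stack.

    The stack is reordered to the model's training feature names (raising
    on any mismatch); nodata pixels propagate as the map's nodata code.
    """
    missing = [n for n in model.feature_names if n not in stack.feature_names]
    extra = [n for n in stack.feature_names if n not in model.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature mismatch: stack lacks {missing}, has extra {extra}")
    aligned = stack.select(model.feature_names)
    X, rr, cc = aligned.as_table()
    labels = np.full(stack.grid.shape, NODATA_LABEL, dtype=np.int64)
    if len(X):
        labels[rr, cc] = model.predict(X)
    if legend is None:
        legend = model.legend or {int(c): str(c) for c in np.unique(labels)
                                  if c != NODATA_LABEL}
    legend = {int(k): v for k, v in legend.items()}
    for c in np.unique(labels):
        if c != NODATA_LABEL and int(c) not in legend:
            legend[int(c)] = str(int(c))
    return HabitatMap(labels, legend, stack.grid, nodata=NODATA_LABEL)
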