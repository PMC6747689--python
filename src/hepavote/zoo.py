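"""The nine base classifiers behind one uniform fit/predict_proba surface.

Roster (in canonical column order): logistic regression (LR), RBF-kernel
support vector machine (SVM), gradient boosting (GDBT), AdaBoost (AdaBT),
XGBoost (XGBT), random forest (RF), extremely randomized trees
(ExtraTrees), LightGBM (LGBT), and a histogram-based gradient-boosting
machine filling the categorical-boosting slot (CatBT).

Hyperparameters default to each backend's defaults and can be overridden
per algorithm. The scale-sensitive learners (LR, SVM) are wrapped in a
standardization pipeline fitted on the training data of each fit call;
tree and boosting learners consume raw features.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

try:
    from xgboost import XGBClassifier
except ImportError:  # pragma: no cover
    XGBClassifier = None
try:
    from lightgbm import LGBMClassifier
except ImportError:  # pragma: no cover
    LGBMClassifier = None

#: canonical algorithm order; grid columns and all tie-breaks follow it
ALGORITHMS: tuple[str, ...] = (
    "LR",
    "SVM",
    "GDBT",
    "AdaBT",
    "XGBT",
    "RF",
    "ExtraTrees",
    "LGBT",
    "CatBT",
)

#: algorithms that get within-fit feature standardization
STANDARDIZED = frozenset({"LR", "SVM"})


def make_backend(algorithm: str, seed: int, hyperparameters: Mapping | None = None):
    """Instantiate the sklearn-compatible backend for one algorithm name."""
    hp = dict(hyperparameters or {})
    if algorithm == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed, **hp)
    elif algorithm == "SVM":
        # radial-basis kernel with probability outputs, per the protocol
        est = SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    elif algorithm == "GDBT":
        est = GradientBoostingClassifier(random_state=seed, **hp)
    elif algorithm == "AdaBT":
        est = AdaBoostClassifier(random_state=seed, **hp)
    elif algorithm == "XGBT":
        if XGBClassifier is None:  # pragma: no cover
            raise ImportError("xgboost is required for the XGBT algorithm")
        est = XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **hp
        )
    elif algorithm == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    elif algorithm == "ExtraTrees":
        est = ExtraTreesClassifier(random_state=seed, n_jobs=1, **hp)
    elif algorithm == "LGBT":
        if LGBMClassifier is None:  # pragma: no cover
            raise ImportError("lightgbm is required for the LGBT algorithm")
        est = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)
    elif algorithm == "CatBT":
        est = HistGradientBoostingClassifier(random_state=seed, **hp)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if algorithm in STANDARDIZED:
        est = make_pipeline(StandardScaler(), est)
    return est


class ZooClassifier(ClassifierMixin, BaseEstimator):
    """One named base classifier with a controlled seed.

    Parameters
    ----------
    algorithm : str
        One of :data:`ALGORITHMS`.
    seed : int
        Random state forwarded to the backend.
    hyperparameters : mapping, optional
        Backend keyword overrides (empty = backend defaults).
    """

    def __init__(self, algorithm: str = "RF", seed: int = 0, hyperparameters=None):
        self.algorithm = algorithm
        self.seed = seed
        self.hyperparameters = hyperparameters

    # -- sklearn plumbing -------------------------------------------------
    def _validate_X(self, X, reset: bool):
        names = list(X.columns.astype(str)) if isinstance(X, pd.DataFrame) else None
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if np.isnan(Xv).any():
            raise ValueError("X contains NaN; missing values are not supported")
        if reset:
            self.n_features_in_ = Xv.shape[1]
            self.feature_names_in_ = names
        else:
            if Xv.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {Xv.shape[1]} features; model was fitted with {self.n_features_in_}"
                )
            if names is not None and self.feature_names_in_ is not None:
                if names != self.feature_names_in_:
                    raise ValueError("feature names differ from those seen during fit")
        return Xv

    def fit(self, X, y):
        Xv = self._validate_X(X, reset=True)
        y = np.asarray(y, dtype=int)
        if y.shape != (Xv.shape[0],):
            raise ValueError("y length must match the number of rows in X")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("y must be binary {0,1}")
        if classes.size < 2:
            raise ValueError("y contains a single class; both classes are required to fit")
        self.classes_ = np.array([0, 1])
        self.model_ = make_backend(self.algorithm, self.seed, self.hyperparameters)
        self.model_.fit(Xv, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        Xv = self._validate_X(X, reset=False)
        with warnings.catch_warnings():
            # lightgbm invents feature_names_in_ ("Column_0", ...) even when
            # fitted on a plain array, tripping sklearn's name check here;
            # the backend only ever sees unnamed arrays, so this is noise
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            proba = self.model_.predict_proba(Xv)
        return np.clip(proba, 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def clone_with_seed(self, seed: int) -> "ZooClassifier":
        new = clone(self)
        new.set_params(seed=seed)
        return new
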