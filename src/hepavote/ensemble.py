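"""Weighted dual-block soft-voting ensemble for DILI classification.

The final predictor trains the five selected algorithms twice: once on the
concatenated top-ranked fingerprint blocks and once on the 7-descriptor
physicochemical block. Within each side the members' hepatotoxicity
probabilities are averaged (soft vote); the two sides are then fused as

    p = w * p_fingerprints + (1 - w) * p_descriptors

with w = 0.7 by default (the 7:3 fingerprint:descriptor trade-off), and a
compound is called hepatotoxic when p is strictly greater than the 0.5
threshold.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._seeds import derive_seed
from .io import LabeledDataset
from .zoo import ZooClassifier

#: the five algorithms selected by the two-tier screen, canonical order
DEFAULT_ALGORITHMS: tuple[str, ...] = ("GDBT", "XGBT", "RF", "LGBT", "CatBT")

DEFAULT_WEIGHT = 0.7
DEFAULT_THRESHOLD = 0.5


def soft_vote(probability_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of member probability vectors."""
    if len(probability_vectors) == 0:
        raise ValueError("soft_vote requires at least one probability vector")
    arrs = [np.asarray(v, dtype=float) for v in probability_vectors]
    n = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != n:
            raise ValueError("probability vectors have mismatched lengths")
    return np.mean(arrs, axis=0)


def fuse_blocks(p_fp: np.ndarray, p_desc: np.ndarray, w: float) -> np.ndarray:
    """Convex fusion ``w * p_fp + (1 - w) * p_desc`` of the two sides."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"fusion weight must lie in [0, 1], got {w}")
    p_fp = np.asarray(p_fp, dtype=float)
    p_desc = np.asarray(p_desc, dtype=float)
    if p_fp.shape != p_desc.shape:
        raise ValueError("fingerprint and descriptor probability vectors differ in length")
    return w * p_fp + (1.0 - w) * p_desc


def classify(probabilities: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Hard labels: 1 iff p is STRICTLY greater than the threshold."""
    p = np.asarray(probabilities, dtype=float)
    return (p > threshold).astype(int)


class DualBlockVotingClassifier(ClassifierMixin, BaseEstimator):
    """Soft-voting ensemble over two feature views with convex fusion.

    Parameters
    ----------
    algorithms : sequence of str
        Member algorithm names (default: the five selected boosters/forest).
    weight : float in [0, 1]
        Weight of the fingerprint side; the descriptor side gets 1 - weight.
    threshold : float in (0, 1)
        Decision threshold; strict "greater than" semantics.
    fingerprint_cols, descriptor_cols : sequence of column names or None
        How to split the input matrix into the two views. With
        ``descriptor_cols=None`` the model degenerates to a single-view
        soft voter over all (or the named fingerprint) columns.
    seed : int
        Pipeline seed; member seeds are derived per (side, algorithm), so
        the fingerprint-side members are bit-identical whether or not a
        descriptor side exists.
    hyperparameters : mapping algorithm -> overrides, optional
    """

    def __init__(
        self,
        algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
        weight: float = DEFAULT_WEIGHT,
        threshold: float = DEFAULT_THRESHOLD,
        fingerprint_cols: Sequence[str] | None = None,
        descriptor_cols: Sequence[str] | None = None,
        seed: int = 0,
        hyperparameters=None,
    ):
        self.algorithms = algorithms
        self.weight = weight
        self.threshold = threshold
        self.fingerprint_cols = fingerprint_cols
        self.descriptor_cols = descriptor_cols
        self.seed = seed
        self.hyperparameters = hyperparameters

    # ------------------------------------------------------------------
    def _split_views(self, X: pd.DataFrame):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        desc = list(self.descriptor_cols) if self.descriptor_cols is not None else []
        if self.fingerprint_cols is not None:
            fp = list(self.fingerprint_cols)
        else:
            fp = [c for c in X.columns if c not in set(desc)]
        missing = [c for c in fp + desc if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from X: {missing[:5]}")
        return X[fp], (X[desc] if desc else None)

    def _member_hp(self, algorithm: str):
        if self.hyperparameters is None:
            return None
        return self.hyperparameters.get(algorithm)

    def fit(self, X, y):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("y contains a single class; both classes are required to fit")
        X_fp, X_desc = self._split_views(X)
        self.classes_ = np.array([0, 1])
        self.fingerprint_members_ = [
            ZooClassifier(
                algorithm=a,
                seed=derive_seed(self.seed, "fp", a),
                hyperparameters=self._member_hp(a),
            ).fit(X_fp, y)
            for a in self.algorithms
        ]
        self.descriptor_members_ = (
            [
                ZooClassifier(
                    algorithm=a,
                    seed=derive_seed(self.seed, "desc", a),
                    hyperparameters=self._member_hp(a),
                ).fit(X_desc, y)
                for a in self.algorithms
            ]
            if X_desc is not None
            else []
        )
        self.n_features_in_ = X_fp.shape[1] + (X_desc.shape[1] if X_desc is not None else 0)
        return self

    def predict_side_proba(self, X) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-side soft-vote P(hepatotoxic) before fusion."""
        if not hasattr(self, "fingerprint_members_"):
            raise RuntimeError("ensemble is not fitted")
        X_fp, X_desc = self._split_views(X)
        p_fp = soft_vote([m.predict_proba(X_fp)[:, 1] for m in self.fingerprint_members_])
        p_desc = (
            soft_vote([m.predict_proba(X_desc)[:, 1] for m in self.descriptor_members_])
            if self.descriptor_members_
            else None
        )
        return p_fp, p_desc

    def predict_proba(self, X) -> np.ndarray:
        p_fp, p_desc = self.predict_side_proba(X)
        p1 = p_fp if p_desc is None else fuse_blocks(p_fp, p_desc, self.weight)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_proba(X)[:, 1], self.threshold)


# ---------------------------------------------------------------------------
# dataset-level convenience wrappers


def fit_ensemble(
    dataset: LabeledDataset,
    fingerprint_block_ids: Sequence[str],
    descriptor_block_id: str | None = "DESCRIPTORS",
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
    weight: float = DEFAULT_WEIGHT,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    hyperparameters=None,
) -> DualBlockVotingClassifier:
    """Fit the dual-block ensemble on named blocks of a dataset."""
    block_ids = list(fingerprint_block_ids) + (
        [descriptor_block_id] if descriptor_block_id else []
    )
    X = dataset.matrix(block_ids)
    desc_cols = (
        [c for c in X.columns if c.startswith(f"{descriptor_block_id}:")]
        if descriptor_block_id
        else None
    )
    model = DualBlockVotingClassifier(
        algorithms=algorithms,
        weight=weight,
        threshold=threshold,
        descriptor_cols=desc_cols,
        seed=seed,
        hyperparameters=hyperparameters,
    )
    model.fit(X, dataset.labels)
    model.fingerprint_block_ids_ = list(fingerprint_block_ids)
    model.descriptor_block_id_ = descriptor_block_id
    return model


def predict_proba_ensemble(model: DualBlockVotingClassifier, dataset: LabeledDataset) -> np.ndarray:
    """P(hepatotoxic) for every compound of an aligned dataset."""
    block_ids = list(model.fingerprint_block_ids_) + (
        [model.descriptor_block_id_] if model.descriptor_block_id_ else []
    )
    return model.predict_proba(dataset.matrix(block_ids))[:, 1]


# ---------------------------------------------------------------------------
# serialization: JSON manifest (retrain-sufficient) + joblib member blobs


def save_model(model: DualBlockVotingClassifier, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "algorithms": list(model.algorithms),
        "weight": model.weight,
        "threshold": model.threshold,
        "seed": model.seed,
        "fingerprint_cols": list(model.fingerprint_cols) if model.fingerprint_cols else None,
        "descriptor_cols": list(model.descriptor_cols) if model.descriptor_cols else None,
        "fingerprint_block_ids": getattr(model, "fingerprint_block_ids_", None),
        "descriptor_block_id": getattr(model, "descriptor_block_id_", None),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(
        {
            "fingerprint_members": model.fingerprint_members_,
            "descriptor_members": model.descriptor_members_,
        },
        directory / "members.joblib",
    )


def load_model(directory: str | Path) -> DualBlockVotingClassifier:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    model = DualBlockVotingClassifier(
        algorithms=manifest["algorithms"],
        weight=manifest["weight"],
        threshold=manifest["threshold"],
        fingerprint_cols=manifest["fingerprint_cols"],
        descriptor_cols=manifest["descriptor_cols"],
        seed=manifest["seed"],
    )
    blobs = joblib.load(directory / "members.joblib")
    model.fingerprint_members_ = blobs["fingerprint_members"]
    model.descriptor_members_ = blobs["descriptor_members"]
    model.classes_ = np.array([0, 1])
    if manifest.get("fingerprint_block_ids"):
        model.fingerprint_block_ids_ = manifest["fingerprint_block_ids"]
        model.descriptor_block_id_ = manifest["descriptor_block_id"]
    return model
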