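"""Repeated stratified cross-validation and the ACC/SE/SP/AUC/MCC metric set.

Conventions: the positive class (label 1) is the hepatotoxicant class, so
sensitivity is recall on hepatotoxicants and specificity recall on
non-hepatotoxicants. AUC is the Mann-Whitney rank statistic (ties credited
0.5), computed with sklearn. A metric whose denominator is zero is reported
as missing (None), never as 0. Per-repeat metrics are computed on the
pooled out-of-fold predictions of that repeat; the aggregate is the mean
and standard deviation across repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._seeds import derive_seed
from .io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred differ in length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    acc: float | None
    se: float | None
    sp: float | None
    auc: float | None
    mcc: float | None
    per_repeat: list["MetricsReport"] = field(default_factory=list)
    aggregate: dict | None = None

    def to_dict(self) -> dict:
        return {
            "counts": vars(self.counts),
            "ACC": self.acc,
            "SE": self.se,
            "SP": self.sp,
            "AUC": self.auc,
            "MCC": self.mcc,
            "aggregate": self.aggregate,
        }

    def to_row(self) -> pd.DataFrame:
        """One-row frame in the conventional Q/SE/SP/AUC percentage layout."""
        pct = lambda v: None if v is None else 100.0 * v
        return pd.DataFrame(
            [
                {
                    "Q (%)": pct(self.acc),
                    "SE (%)": pct(self.se),
                    "SP (%)": pct(self.sp),
                    "AUC (%)": pct(self.auc),
                    "MCC": self.mcc,
                }
            ]
        )


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 1000
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def mcc_from_counts(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient on [-1, 1]; None when undefined."""
    den = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if den == 0:
        return None
    return (c.tp * c.tn - c.fp * c.fn) / den


def compute_metrics(y_true, y_pred, y_prob=None) -> MetricsReport:
    """ACC/SE/SP from the confusion table, AUC from ranks, MCC from counts."""
    y_true = np.asarray(y_true, dtype=int)
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    auc = None
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if y_prob.shape != y_true.shape:
            raise ValueError("y_prob and y_true differ in length")
        if (y_prob < 0).any() or (y_prob > 1).any():
            raise ValueError("y_prob must lie in [0, 1]")
        if 0 < y_true.sum() < y_true.size:
            auc = float(roc_auc_score(y_true, y_prob))
    return MetricsReport(
        counts=counts,
        acc=_safe_div(counts.tp + counts.tn, counts.total),
        se=_safe_div(counts.tp, counts.tp + counts.fn),
        sp=_safe_div(counts.tn, counts.tn + counts.fp),
        auc=auc,
        mcc=mcc_from_counts(counts),
    )


def _aggregate(reports: Sequence[MetricsReport]) -> MetricsReport:
    pooled = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        tn=sum(r.counts.tn for r in reports),
        fp=sum(r.counts.fp for r in reports),
        fn=sum(r.counts.fn for r in reports),
    )
    agg: dict[str, dict] = {}
    for name in ("acc", "se", "sp", "auc", "mcc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        agg[name] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return MetricsReport(
        counts=pooled,
        acc=agg["acc"]["mean"],
        se=agg["se"]["mean"],
        sp=agg["sp"]["mean"],
        auc=agg["auc"]["mean"],
        mcc=agg["mcc"]["mean"],
        per_repeat=list(reports),
        aggregate=agg,
    )


def cross_validate(
    X,
    y,
    estimator,
    cv: CVConfig,
    seed_tags: tuple = (),
) -> MetricsReport:
    """Repeated stratified k-fold CV with pooled out-of-fold predictions.

    Per repeat, the compounds are partitioned into ``cv.folds`` stratified
    folds; each fold is held out once and the estimator (cloned, reseeded
    per repeat x fold when it exposes a ``seed`` parameter) predicts it.
    The repeat's metrics are computed on the pooled held-out predictions.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if cv.stratified and counts.min() < cv.folds:
        raise ValueError(
            f"stratified {cv.folds}-fold CV infeasible: minority class has {counts.min()} members"
        )
    reseedable = "seed" in estimator.get_params()
    reports = []
    for r in range(cv.repeats):
        splitter = StratifiedKFold(
            n_splits=cv.folds,
            shuffle=True,
            random_state=derive_seed(cv.seed, "partition", r),
        )
        oof_pred = np.empty_like(y)
        oof_prob = np.empty(y.shape, dtype=float)
        for k, (tr, te) in enumerate(splitter.split(X, y)):
            est = clone(estimator)
            if reseedable:
                est.set_params(seed=derive_seed(cv.seed, *seed_tags, "rep", r, "fold", k))
            est.fit(X.iloc[tr], y[tr])
            prob = est.predict_proba(X.iloc[te])[:, 1]
            oof_prob[te] = prob
            oof_pred[te] = est.predict(X.iloc[te])
        reports.append(compute_metrics(y, oof_pred, oof_prob))
    return _aggregate(reports)


def holdout_split(
    dataset: LabeledDataset, test_fraction: float = 1.0 / 9.0, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split (default 8:1, e.g. 400/50 on 450)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    idx = np.arange(dataset.n_compounds)
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=dataset.labels,
        random_state=derive_seed(seed, "holdout"),
    )
    return dataset.subset(sorted(tr)), dataset.subset(sorted(te))
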