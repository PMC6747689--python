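"""Two-tier algorithm/fingerprint selection.

Stage one scores every (fingerprint, algorithm) pair by mean CV accuracy,
takes each fingerprint's five best algorithms, and keeps the five
algorithms that appear in most of those per-fingerprint top-5 sets. Stage
two ranks the fingerprints by the mean accuracy of the selected algorithms,
then greedily concatenates them in rank order, keeping the prefix whose
soft-voted CV accuracy peaks; finally a grid search picks the convex weight
between the fingerprint and descriptor probability estimates.

All ties are broken positionally: by grid column order for algorithms and
by row order for fingerprints (earlier wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .ensemble import DualBlockVotingClassifier, classify, fuse_blocks
from .evaluation import CVConfig, compute_metrics, cross_validate
from .io import LabeledDataset
from .zoo import ALGORITHMS, ZooClassifier

DEFAULT_WEIGHT_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding (0.70665 -> 0.7067), for report formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AccuracyGrid:
    """Mean CV accuracy per (fingerprint row, algorithm column)."""

    acc: pd.DataFrame  # index = fingerprints, columns = algorithms
    cv_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.acc.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("grid accuracies must lie in [0, 1]")

    @property
    def fingerprints(self) -> list[str]:
        return list(self.acc.index)

    @property
    def algorithms(self) -> list[str]:
        return list(self.acc.columns)

    def to_csv(self, path: str | Path) -> None:
        self.acc.to_csv(path, index_label="fingerprint")

    @classmethod
    def from_csv(cls, path: str | Path, cv_meta: dict | None = None) -> "AccuracyGrid":
        return cls(acc=pd.read_csv(path, index_col=0), cv_meta=cv_meta or {})


def load_benchmark_grid() -> AccuracyGrid:
    """The published 12x9 cross-validated accuracy grid for the 450-compound
    DILIrank benchmark, shipped with the package."""
    with resources.as_file(
        resources.files("hepavote.data").joinpath("dilirank_grid.csv")
    ) as p:
        return AccuracyGrid.from_csv(p, cv_meta={"source": "published benchmark"})


def load_benchmark_ranking() -> pd.DataFrame:
    """The published per-fingerprint average accuracies (sorted descending)."""
    with resources.as_file(
        resources.files("hepavote.data").joinpath("dilirank_ranking.csv")
    ) as p:
        return pd.read_csv(p)


@dataclass
class SelectionReport:
    top5_sets: dict[str, set[str]]
    algo_counts: dict[str, int]
    selected_algorithms: list[str]
    ranked_fingerprints: list[tuple[str, float]]
    chosen_prefix: int
    chosen_weight: float
    greedy_curve: list[float] = field(default_factory=list)
    weight_curve: dict[float, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "top5_sets": {k: sorted(v) for k, v in self.top5_sets.items()},
            "algo_counts": self.algo_counts,
            "selected_algorithms": self.selected_algorithms,
            "ranked_fingerprints": self.ranked_fingerprints,
            "chosen_prefix": self.chosen_prefix,
            "chosen_weight": self.chosen_weight,
            "greedy_curve": self.greedy_curve,
            "weight_curve": {str(k): v for k, v in self.weight_curve.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stage one: the grid and the algorithm screen


def evaluate_grid(
    dataset: LabeledDataset,
    algorithms: Sequence[str] = ALGORITHMS,
    cv: CVConfig | None = None,
    block_ids: Sequence[str] | None = None,
    hyperparameters: Mapping | None = None,
) -> AccuracyGrid:
    """Mean CV accuracy of every algorithm on every fingerprint block alone."""
    cv = cv or CVConfig()
    if block_ids is None:
        block_ids = [b for b in dataset.blocks if b != "DESCRIPTORS"]
    rows = {}
    for bid in block_ids:
        X = dataset.blocks[bid].to_frame(prefix=True)
        row = {}
        for alg in algorithms:
            est = ZooClassifier(
                algorithm=alg,
                hyperparameters=(hyperparameters or {}).get(alg),
            )
            try:
                report = cross_validate(
                    X, dataset.labels, est, cv, seed_tags=("grid", bid, alg)
                )
            except Exception as exc:
                raise RuntimeError(f"grid cell ({bid}, {alg}) failed: {exc}") from exc
            row[alg] = report.aggregate["acc"]["mean"]
        rows[bid] = row
    acc = pd.DataFrame.from_dict(rows, orient="index").loc[list(block_ids), list(algorithms)]
    return AccuracyGrid(
        acc=acc, cv_meta={"folds": cv.folds, "repeats": cv.repeats, "seed": cv.seed}
    )


def top5_per_fingerprint(grid: AccuracyGrid, row: str, k: int = 5) -> set[str]:
    """The k algorithms with the largest accuracies in one fingerprint row;
    ties broken by column order (earlier column wins)."""
    if row not in grid.acc.index:
        raise KeyError(f"fingerprint {row!r} not in grid")
    vals = grid.acc.loc[row]
    order = sorted(range(len(vals)), key=lambda j: (-vals.iloc[j], j))
    return {grid.algorithms[j] for j in order[:k]}


def count_algorithm_selections(grid: AccuracyGrid, k: int = 5) -> dict[str, int]:
    """How many fingerprint rows include each algorithm in their top-k set."""
    counts = {a: 0 for a in grid.algorithms}
    for fp in grid.fingerprints:
        for a in top5_per_fingerprint(grid, fp, k):
            counts[a] += 1
    return counts


def select_top_algorithms(
    counts: Mapping[str, int],
    k: int = 5,
    order: Sequence[str] | None = None,
) -> list[str]:
    """The k most-selected algorithms, count-descending, ties by column order."""
    order = list(order) if order is not None else [a for a in ALGORITHMS if a in counts]
    if k > len(order):
        raise ValueError(f"k={k} exceeds the {len(order)} available algorithms")
    ranked = sorted(order, key=lambda a: (-counts[a], order.index(a)))
    return ranked[:k]


def rank_fingerprints(
    grid: AccuracyGrid, selected: Sequence[str]
) -> list[tuple[str, float]]:
    """Per fingerprint, the mean accuracy of the selected algorithms.

    Sorted descending on the full-precision mean (row-order ties); the
    reported value is rounded half-up to 4 decimals.
    """
    missing = [a for a in selected if a not in grid.acc.columns]
    if missing:
        raise KeyError(f"algorithms not in grid: {missing}")
    means = grid.acc[list(selected)].mean(axis=1)
    rows = list(grid.fingerprints)
    ordered = sorted(rows, key=lambda f: (-means[f], rows.index(f)))
    return [(f, round_half_up(float(means[f]))) for f in ordered]


# ---------------------------------------------------------------------------
# stage two: fingerprint prefix and fusion weight


def greedy_fingerprint_addition(
    dataset: LabeledDataset,
    ranked: Sequence[str],
    selected_algorithms: Sequence[str],
    cv: CVConfig | None = None,
    repeats: int = 20,
    hyperparameters: Mapping | None = None,
) -> tuple[int, list[float]]:
    """Grow the fingerprint set in rank order; keep the best-accuracy prefix.

    For each prefix size p the selected algorithms are soft-voted on the
    column-wise concatenation of the first p blocks and scored by repeated
    CV; the returned prefix maximizes the mean-accuracy curve (ties favour
    the smaller prefix).
    """
    if not ranked:
        raise ValueError("ranked fingerprint list is empty")
    cv = cv or CVConfig()
    cv = CVConfig(folds=cv.folds, repeats=repeats, stratified=cv.stratified, seed=cv.seed)
    curve = []
    for p in range(1, len(ranked) + 1):
        X = dataset.matrix(list(ranked[:p]))
        est = DualBlockVotingClassifier(
            algorithms=list(selected_algorithms),
            descriptor_cols=None,
            hyperparameters=hyperparameters,
        )
        report = cross_validate(
            X, dataset.labels, est, cv, seed_tags=("greedy", p)
        )
        curve.append(report.aggregate["acc"]["mean"])
    chosen = int(np.argmax(curve)) + 1  # np.argmax takes the first (smallest) maximum
    return chosen, curve


def search_weight(
    dataset: LabeledDataset,
    fp_block_ids: Sequence[str],
    desc_block_id: str,
    selected_algorithms: Sequence[str],
    cv: CVConfig | None = None,
    weight_grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
    threshold: float = 0.5,
    hyperparameters: Mapping | None = None,
) -> tuple[float, dict[float, float]]:
    """CV accuracy of the dual-block ensemble at each fusion weight.

    The members are fitted once per fold; the weight sweep reuses the two
    sides' out-of-fold probabilities. Ties favour the LARGER weight
    (fingerprints over descriptors).
    """
    if not weight_grid:
        raise ValueError("weight grid is empty")
    if any(w < 0 or w > 1 for w in weight_grid):
        raise ValueError("weights must lie in [0, 1]")
    cv = cv or CVConfig()
    X = dataset.matrix(list(fp_block_ids) + [desc_block_id])
    desc_cols = [c for c in X.columns if c.startswith(f"{desc_block_id}:")]
    y = dataset.labels
    from sklearn.model_selection import StratifiedKFold

    acc_per_w = {float(w): [] for w in weight_grid}
    for r in range(cv.repeats):
        splitter = StratifiedKFold(
            n_splits=cv.folds,
            shuffle=True,
            random_state=derive_seed(cv.seed, "partition", r),
        )
        p_fp = np.empty(len(y), dtype=float)
        p_desc = np.empty(len(y), dtype=float)
        for k, (tr, te) in enumerate(splitter.split(X, y)):
            est = DualBlockVotingClassifier(
                algorithms=list(selected_algorithms),
                descriptor_cols=desc_cols,
                seed=derive_seed(cv.seed, "weight", "rep", r, "fold", k),
                hyperparameters=hyperparameters,
            )
            est.fit(X.iloc[tr], y[tr])
            f, d = est.predict_side_proba(X.iloc[te])
            p_fp[te], p_desc[te] = f, d
        for w in acc_per_w:
            pred = classify(fuse_blocks(p_fp, p_desc, w), threshold)
            acc_per_w[w].append(compute_metrics(y, pred).acc)
    curve = {w: float(np.mean(v)) for w, v in acc_per_w.items()}
    best_w = max(curve, key=lambda w: (curve[w], w))  # ties -> larger weight
    return best_w, curve


def run_selection(
    dataset: LabeledDataset,
    cv: CVConfig | None = None,
    k_algorithms: int = 5,
    greedy_repeats: int = 20,
    desc_block_id: str = "DESCRIPTORS",
    weight_grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
    hyperparameters: Mapping | None = None,
) -> tuple[SelectionReport, AccuracyGrid]:
    """The full two-tier pipeline: grid -> algorithms -> ranking -> prefix -> weight."""
    cv = cv or CVConfig()
    grid = evaluate_grid(dataset, cv=cv, hyperparameters=hyperparameters)
    top5 = {fp: top5_per_fingerprint(grid, fp) for fp in grid.fingerprints}
    counts = count_algorithm_selections(grid)
    selected = select_top_algorithms(counts, k=k_algorithms, order=grid.algorithms)
    ranked = rank_fingerprints(grid, selected)
    ranked_ids = [f for f, _ in ranked]
    prefix, curve = greedy_fingerprint_addition(
        dataset, ranked_ids, selected, cv=cv, repeats=greedy_repeats,
        hyperparameters=hyperparameters,
    )
    best_w, wcurve = search_weight(
        dataset, ranked_ids[:prefix], desc_block_id, selected, cv=cv,
        weight_grid=weight_grid, hyperparameters=hyperparameters,
    )
    report = SelectionReport(
        top5_sets=top5,
        algo_counts=counts,
        selected_algorithms=selected,
        ranked_fingerprints=ranked,
        chosen_prefix=prefix,
        chosen_weight=best_w,
        greedy_curve=curve,
        weight_curve=wcurve,
    )
    return report, grid
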