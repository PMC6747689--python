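import numpy as np
import pandas as pd
import pytest

from hepavote.evaluation import CVConfig
from hepavote.selection import (
    AccuracyGrid,
    count_algorithm_selections,
    evaluate_grid,
    greedy_fingerprint_addition,
    load_benchmark_grid,
    rank_fingerprints,
    round_half_up,
    search_weight,
    select_top_algorithms,
    top5_per_fingerprint,
)
from hepavote.synthetic import generate
from hepavote.zoo import ALGORITHMS

from conftest import tiny_config


def _random_grid(rng, n_rows=6, n_cols=9, quantize=True):
    vals = rng.random((n_rows, n_cols))
    if quantize:  # coarse rounding forces ties
        vals = np.round(vals, 1)
    return AccuracyGrid(
        acc=pd.DataFrame(
            vals,
            index=[f"FP{i}" for i in range(n_rows)],
            columns=list(ALGORITHMS)[:n_cols],
        )
    )


class TestTopFive:
    def test_matches_brute_force_with_tie_rule(self):
        """Oracle: stable sort of (accuracy desc, column index asc), take 5."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            grid = _random_grid(rng)
            for fp in grid.fingerprints:
                row = grid.acc.loc[fp].to_numpy()
                oracle = [
                    grid.algorithms[j]
                    for j in sorted(range(len(row)), key=lambda j: (-row[j], j))[:5]
                ]
                assert top5_per_fingerprint(grid, fp) == set(oracle)

    def test_all_equal_row_takes_first_five_columns(self):
        grid = AccuracyGrid(
            acc=pd.DataFrame([[0.7] * 9], index=["X"], columns=list(ALGORITHMS))
        )
        assert top5_per_fingerprint(grid, "X") == set(ALGORITHMS[:5])

    def test_missing_row_is_error(self):
        grid = _random_grid(np.random.default_rng(0))
        with pytest.raises(KeyError):
            top5_per_fingerprint(grid, "nope")


class TestCounts:
    def test_counts_sum_to_five_per_row(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            grid = _random_grid(rng, n_rows=rng.integers(1, 12))
            counts = count_algorithm_selections(grid)
            assert sum(counts.values()) == 5 * len(grid.fingerprints)

    def test_single_row_counts_are_top5_indicator(self):
        rng = np.random.default_rng(1)
        grid = _random_grid(rng, n_rows=1)
        counts = count_algorithm_selections(grid)
        top = top5_per_fingerprint(grid, grid.fingerprints[0])
        assert {a for a, c in counts.items() if c == 1} == top


class TestSelectTopAlgorithms:
    def test_equal_counts_fall_back_to_column_order(self):
        counts = {a: 3 for a in ALGORITHMS}
        assert select_top_algorithms(counts, k=4) == list(ALGORITHMS[:4])

    def test_k_all_sorts_by_count_descending(self):
        counts = {a: i for i, a in enumerate(ALGORITHMS)}
        out = select_top_algorithms(counts, k=len(ALGORITHMS))
        assert out == list(reversed(ALGORITHMS))

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError):
            select_top_algorithms({a: 1 for a in ALGORITHMS}, k=10)


class TestRankFingerprints:
    def test_single_algorithm_ranks_by_its_column(self):
        rng = np.random.default_rng(5)
        grid = _random_grid(rng, quantize=False)
        ranked = rank_fingerprints(grid, ["RF"])
        col = grid.acc["RF"]
        assert [f for f, _ in ranked] == list(col.sort_values(ascending=False, kind="stable").index)

    def test_values_are_non_increasing(self):
        rng = np.random.default_rng(6)
        ranked = rank_fingerprints(_random_grid(rng), ["GDBT", "RF", "CatBT"])
        vals = [v for _, v in ranked]
        assert vals == sorted(vals, reverse=True)

    def test_unknown_algorithm_is_error(self):
        grid = _random_grid(np.random.default_rng(0))
        with pytest.raises(KeyError):
            rank_fingerprints(grid, ["nope"])


def test_round_half_up_breaks_ties_upward():
    assert round_half_up(0.70665) == 0.7067
    assert round_half_up(0.70664) == 0.7066
    assert round_half_up(0.76934) == 0.7693


def test_benchmark_grid_loads_with_expected_shape():
    grid = load_benchmark_grid()
    assert grid.acc.shape == (12, 9)
    assert grid.algorithms == list(ALGORITHMS)
    assert ((grid.acc >= 0) & (grid.acc <= 1)).all().all()


class TestEvaluateGrid:
    def test_shape_and_range_on_two_blocks(self, tiny_dataset, fast_hp):
        grid = evaluate_grid(
            tiny_dataset,
            algorithms=["LR", "RF"],
            cv=CVConfig(folds=2, repeats=1, seed=0),
            block_ids=["ExtendedFP", "AP2DFP"],
            hyperparameters=fast_hp,
        )
        assert grid.acc.shape == (2, 2)
        assert ((grid.acc >= 0) & (grid.acc <= 1)).all().all()

    def test_label_leak_column_scores_near_one(self, fast_hp):
        # plant the label itself as a fingerprint bit: trees should ace it
        ds = generate(tiny_config(seed=21))
        blk = ds.blocks["AP2DFP"]
        blk.values[:, 0] = ds.labels
        grid = evaluate_grid(
            ds,
            algorithms=["RF"],
            cv=CVConfig(folds=5, repeats=1, seed=0),
            block_ids=["AP2DFP"],
            hyperparameters=fast_hp,
        )
        assert grid.acc.loc["AP2DFP", "RF"] > 0.95

    def test_pure_noise_block_scores_near_chance(self, fast_hp):
        cfg = tiny_config(seed=22, n_compounds=200, signal={}, positive_fraction=0.5)
        ds = generate(cfg)
        grid = evaluate_grid(
            ds,
            algorithms=["LR"],
            cv=CVConfig(folds=5, repeats=2, seed=0),
            block_ids=["AP2DFP"],
        )
        assert abs(grid.acc.loc["AP2DFP", "LR"] - 0.5) < 0.12


class TestGreedyAddition:
    def test_single_block_gives_prefix_one(self, tiny_dataset, fast_hp):
        prefix, curve = greedy_fingerprint_addition(
            tiny_dataset,
            ["ExtendedFP"],
            ["RF", "LGBT"],
            cv=CVConfig(folds=3, repeats=1, seed=0),
            repeats=1,
            hyperparameters=fast_hp,
        )
        assert prefix == 1
        assert len(curve) == 1

    def test_signal_prefix_beats_noise_suffix(self, fast_hp):
        """Blocks 1-2 carry all the signal: the accuracy curve rises well
        above the majority rate by prefix 2 and flattens afterwards, so the
        chosen prefix is within noise of the two-block optimum."""
        ds = generate(tiny_config(seed=33, n_compounds=160))
        ranked = ["ExtendedFP", "KRFP", "AP2DFP", "nKRFP"]
        prefix, curve = greedy_fingerprint_addition(
            ds,
            ranked,
            ["RF", "XGBT", "LGBT"],
            cv=CVConfig(folds=4, repeats=1, seed=2),
            repeats=2,
            hyperparameters=fast_hp,
        )
        assert len(curve) == 4
        assert all(0 <= v <= 1 for v in curve)
        majority = max(ds.labels.mean(), 1 - ds.labels.mean())
        assert curve[1] > majority + 0.15  # signal found by prefix 2
        assert max(curve) - curve[1] < 0.03  # noise blocks add nothing real
        assert curve[prefix - 1] == max(curve)

    def test_curve_invariant_to_compound_renaming(self, fast_hp):
        ds = generate(tiny_config(seed=44))
        renamed = generate(tiny_config(seed=44))
        renamed.compound_ids = [f"X-{c}" for c in renamed.compound_ids]
        for blk in renamed.blocks.values():
            blk.compound_ids = list(renamed.compound_ids)
        args = (["ExtendedFP", "AP2DFP"], ["RF", "GDBT"])
        cv = CVConfig(folds=3, repeats=1, seed=7)
        _, c1 = greedy_fingerprint_addition(ds, *args, cv=cv, repeats=1, hyperparameters=fast_hp)
        _, c2 = greedy_fingerprint_addition(renamed, *args, cv=cv, repeats=1, hyperparameters=fast_hp)
        assert c1 == c2

    def test_empty_ranking_is_error(self, tiny_dataset):
        with pytest.raises(ValueError):
            greedy_fingerprint_addition(tiny_dataset, [], ["RF"])


class TestSearchWeight:
    def test_singleton_grid_returns_that_weight(self, tiny_dataset, fast_hp):
        best, curve = search_weight(
            tiny_dataset,
            ["ExtendedFP"],
            "DESCRIPTORS",
            ["RF", "LGBT"],
            cv=CVConfig(folds=3, repeats=1, seed=0),
            weight_grid=[0.5],
            hyperparameters=fast_hp,
        )
        assert best == 0.5
        assert set(curve) == {0.5}

    def test_invalid_weights_are_error(self, tiny_dataset):
        with pytest.raises(ValueError):
            search_weight(
                tiny_dataset, ["ExtendedFP"], "DESCRIPTORS", ["RF"], weight_grid=[1.5]
            )
        with pytest.raises(ValueError):
            search_weight(
                tiny_dataset, ["ExtendedFP"], "DESCRIPTORS", ["RF"], weight_grid=[]
            )
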