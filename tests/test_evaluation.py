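"""Cross-validation protocol, balancing, standardisation and metrics."""

import numpy as np
import pandas as pd
import pytest

from steersense.evaluation import (
    apply_scaler,
    balance_training,
    balanced_accuracy,
    bootstrap_ci,
    confusion_matrix,
    fit_scaler,
    hold_out_test,
    knee_select,
    make_splits,
    metrics_report,
    prepare_splits,
    run_grid,
)

from conftest import make_feature_table


def _steers(n=18, trials=3):
    return [(f"steer{i + 1:02d}", f"trial{i % trials + 1}") for i in range(n)]


class TestHoldOut:
    def test_three_test_steers_spanning_trials(self):
        test, dev = hold_out_test(_steers(), seed=0)
        assert len(test) == 3 and len(dev) == 15
        trial_of = dict(_steers())
        assert len({trial_of[s] for s in test}) == 3

    def test_deterministic_per_seed(self):
        assert hold_out_test(_steers(), seed=5) == hold_out_test(_steers(), seed=5)
        assert hold_out_test(_steers(), seed=5) != hold_out_test(_steers(), seed=6)

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            hold_out_test([], seed=0)


class TestSplits:
    def test_25_splits_with_exact_partition_per_repetition(self):
        _, dev = hold_out_test(_steers(), seed=0)
        splits = make_splits(dev, seed=1)
        assert len(splits) == 25
        for rep in range(1, 6):
            vals = [s.val_steers for s in splits if s.repetition == rep]
            flat = [x for v in vals for x in v]
            assert sorted(flat) == sorted(dev)  # each steer validates exactly once
        for s in splits:
            assert not set(s.train_steers) & set(s.val_steers)
            assert len(s.train_steers) == 12 and len(s.val_steers) == 3

    def test_repetitions_reshuffle_folds(self):
        _, dev = hold_out_test(_steers(), seed=0)
        splits = make_splits(dev, seed=1)
        r1 = {s.val_steers for s in splits if s.repetition == 1}
        r2 = {s.val_steers for s in splits if s.repetition == 2}
        assert r1 != r2

    def test_indivisible_steer_count_rejected(self):
        with pytest.raises(ValueError):
            make_splits([f"s{i}" for i in range(14)], seed=0)


class TestBalancing:
    def _table(self, counts):
        rows = []
        for i, c in enumerate(counts):
            for b in range(c):
                rows.append(
                    {"steer_id": f"s{i}", "trial_id": "t", "block_index": b,
                     "label": "eating", "purity": 1.0, "f": float(b)}
                )
        return pd.DataFrame(rows)

    def test_downsampled_to_minimum_count(self):
        bal = balance_training(self._table([100, 150, 200]), seed=0)
        assert bal.groupby("steer_id").size().tolist() == [100, 100, 100]

    def test_time_order_preserved(self):
        bal = balance_training(self._table([50, 80]), seed=1)
        for _, grp in bal.groupby("steer_id"):
            assert (np.diff(grp["block_index"]) > 0).all()

    def test_equal_counts_unchanged(self):
        t = self._table([40, 40])
        bal = balance_training(t, seed=2)
        assert len(bal) == len(t)

    def test_empty_steer_rejected(self):
        with pytest.raises(ValueError):
            balance_training(self._table([]), seed=0)


class TestScaler:
    def test_closed_form_z_scores(self):
        scaler = fit_scaler(np.array([[1.0], [2.0], [3.0]]))
        z = apply_scaler(scaler, np.array([[1.0], [2.0], [3.0]]))
        assert z.ravel() == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_validation_uses_training_parameters(self):
        train = np.array([[0.0], [10.0]])
        scaler = fit_scaler(train)
        val = apply_scaler(scaler, np.array([[5.0]]))
        assert val[0, 0] == pytest.approx(0.0)  # (5-5)/5, not val's own stats

    def test_constant_column_zeroed_and_flagged(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        scaler = fit_scaler(X)
        assert scaler.constant.tolist() == [False, True]
        assert (apply_scaler(scaler, X)[:, 1] == 0).all()


class TestMetrics:
    def test_perfect_diagonal_gives_ones(self):
        cm = np.diag([10, 20, 30])
        per, macro = balanced_accuracy(cm)
        assert np.allclose(per, 1.0) and macro == 1.0

    def test_binary_formula(self):
        # TP=8, P=10, TN=90, N=100 -> 0.5*(0.8+0.9)=0.85
        cm = np.array([[8, 2], [10, 90]])
        per, _ = balanced_accuracy(cm)
        assert per[0] == pytest.approx(0.85)

    def test_binary_matches_reference_balanced_accuracy(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000)
        p = rng.integers(0, 2, 1000)
        per, _ = balanced_accuracy(confusion_matrix(y, p, 2))
        assert per[1] == pytest.approx(balanced_accuracy_score(y, p))

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 10000)
        p = rng.integers(0, 3, 10000)
        _, macro = balanced_accuracy(confusion_matrix(y, p))
        assert macro == pytest.approx(0.5, abs=0.03)

    def test_report_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = metrics_report(y, y)
        assert rep.macro_balanced_accuracy == 1.0
        assert rep.weighted_precision == 1.0
        assert rep.weighted_recall == 1.0

    def test_precision_is_column_normalised_diagonal(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 500)
        p = rng.integers(0, 3, 500)
        rep = metrics_report(y, p)
        cm = rep.confusion
        for c in range(3):
            assert rep.per_class_precision[c] == pytest.approx(
                cm[c, c] / cm[:, c].sum()
            )

    def test_agrees_with_reference_metrics(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, 1000)
        p = rng.integers(0, 3, 1000)
        rep = metrics_report(y, p)
        assert rep.weighted_precision == pytest.approx(
            precision_score(y, p, average="weighted", zero_division=0)
        )
        assert rep.weighted_recall == pytest.approx(
            recall_score(y, p, average="weighted")
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics_report([], [])


class TestBootstrap:
    def test_constant_values_zero_width(self):
        lo, hi = bootstrap_ci([0.7] * 10, seed=0)
        assert lo == hi == 0.7

    def test_deterministic_per_seed(self):
        v = np.random.default_rng(0).normal(0.8, 0.02, 25)
        assert bootstrap_ci(v, seed=4) == bootstrap_ci(v, seed=4)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(123)
        cover = 0
        reps = 400
        for r in range(reps):
            v = rng.normal(0.8, 0.02, 25)
            lo, hi = bootstrap_ci(v, B=1000, seed=r)
            cover += lo <= 0.8 <= hi
        assert 0.92 <= cover / reps <= 0.98

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.5], seed=0)


class TestKnee:
    def test_knee_prefers_small_near_optimal_count(self):
        assert knee_select({27: 0.81, 7: 0.805, 2: 0.70}, delta=0.01) == 7

    def test_unique_max_with_large_gaps(self):
        assert knee_select({42: 0.9, 27: 0.8, 7: 0.6}, delta=0.01) == 42

    def test_flat_curve_gives_smallest(self):
        assert knee_select({42: 0.8, 7: 0.8, 1: 0.8}) == 1

    def test_manual_override(self):
        assert knee_select({42: 0.9, 7: 0.5}, override=7) == 7


class TestGrid:
    def test_cells_structure_and_25_accuracies(self):
        table = make_feature_table(seed=5)
        splits = make_splits(sorted(table["steer_id"].unique()), seed=0)
        grid, traces = run_grid(
            table,
            [("MI", "LDA"), ("BFE", "LDA"), ("MI", "PLSDA")],
            [5, 3, 1],
            pls_components=[2],
            splits=splits,
            bootstrap_B=500,
        )
        for sel, model in [("MI", "LDA"), ("BFE", "LDA")]:
            arm = grid[(grid.selection == sel) & (grid.model == model)]
            assert sorted(arm["n_features"]) == [1, 3, 5]
            for accs in arm["accuracies"]:
                assert len(accs) == 25
        # PLS-DA cell with components > features marked skipped
        pls = grid[grid.model == "PLSDA"]
        assert bool(pls[pls.n_features == 1]["skipped"].iloc[0])
        assert not bool(pls[pls.n_features == 5]["skipped"].iloc[0])

    def test_label_permutation_null_near_chance(self):
        table = make_feature_table(seed=6)
        rng = np.random.default_rng(0)
        table["label"] = rng.permutation(table["label"].to_numpy())
        splits = make_splits(sorted(table["steer_id"].unique()), seed=0)
        prepared = prepare_splits(table, splits)
        from steersense.evaluation import score_subset_over_splits
        from steersense.models import LDAClassifier

        accs = score_subset_over_splits(
            prepared, np.arange(5), lambda: LDAClassifier()
        )
        assert np.nanmean(accs) == pytest.approx(0.5, abs=0.05)

    def test_train_and_validation_never_share_steers(self):
        table = make_feature_table(seed=7)
        splits = make_splits(sorted(table["steer_id"].unique()), seed=0)
        for ps in prepare_splits(table, splits):
            assert not set(ps.groups_train) & set(ps.groups_val)
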