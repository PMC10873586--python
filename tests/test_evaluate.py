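import numpy as np
import pytest

import cellstack as cs
from cellstack.errors import ClassTooSmallError
from conftest import brute_force_metrics


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = cs.compute_metrics(["A", "A", "B", "B"], ["A", "A", "B", "B"])
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0 and rep.median_f1 == 1.0

    def test_hand_computed_majority_case(self):
        # F1_A = 2*(0.5*1)/(0.5+1) = 2/3, F1_B = 0
        rep = cs.compute_metrics(["A", "A", "B", "B"], ["A", "A", "A", "A"])
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.per_class_f1["A"] == pytest.approx(2 / 3, abs=1e-12)
        assert rep.per_class_f1["B"] == 0.0
        assert rep.macro_f1 == pytest.approx(1 / 3, abs=1e-12)
        assert rep.median_f1 == pytest.approx(1 / 3, abs=1e-12)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            t = int(rng.integers(2, 7))
            classes = [f"C{i}" for i in range(t)]
            true = [classes[i] for i in rng.integers(0, t, size=n)]
            if len(set(true)) < 2:
                true[0], true[1] = classes[0], classes[1]
            pred = [classes[i] for i in rng.integers(0, t, size=n)]
            rep = cs.compute_metrics(true, pred)
            acc, per_class, macro, median = brute_force_metrics(true, pred)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(macro, abs=1e-12)
            assert rep.median_f1 == pytest.approx(median, abs=1e-12)
            for c, v in per_class.items():
                assert rep.per_class_f1[c] == pytest.approx(v, abs=1e-12)
            assert rep.confusion.values.sum() == n

    def test_constant_majority_predictor_accuracy(self):
        true = ["A"] * 7 + ["B"] * 3
        rep = cs.compute_metrics(true, ["A"] * 10)
        assert rep.accuracy == pytest.approx(0.7)

    def test_prediction_only_class_in_confusion_columns(self):
        rep = cs.compute_metrics(["A", "B"], ["A", "C"])
        assert "C" not in rep.per_class_f1
        assert "C" in rep.confusion.columns
        assert rep.confusion.values.sum() == 2

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            cs.compute_metrics(["A"], ["A", "B"])
        with pytest.raises(ValueError, match="empty"):
            cs.compute_metrics([], [])


class TestStratifiedKFoldCV:
    def test_fold_proportions_exact_divisibility(self):
        rng = np.random.default_rng(0)
        labels = ["A"] * 60 + ["B"] * 40
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        y = np.array(labels)
        for _, test_idx in skf.split(np.zeros(100), y):
            assert (y[test_idx] == "A").sum() == 12
            assert (y[test_idx] == "B").sum() == 8

    def test_cv_on_separated_data(self, sim_small, fast_config):
        ds, _, _ = sim_small
        rep = cs.stratified_kfold_cv(ds, fast_config, folds=5, seed=0)
        assert rep.accuracy >= 0.95
        assert rep.repeats == 5 and len(rep.fold_reports) == 5
        assert rep.n_cells == ds.n_cells
        # fold test sets partition all cells
        assert sum(r.n_cells for r in rep.fold_reports) == ds.n_cells

    def test_determinism(self, sim_small, fast_config):
        ds, _, _ = sim_small
        r1 = cs.stratified_kfold_cv(ds, fast_config, folds=3, seed=5)
        r2 = cs.stratified_kfold_cv(ds, fast_config, folds=3, seed=5)
        assert r1.accuracy == r2.accuracy and r1.per_class_f1 == r2.per_class_f1

    def test_small_class_rejected(self, fast_config):
        ds = cs.ExpressionDataset(
            np.ones((5, 3)) + np.eye(5, 3),
            ["g0", "g1", "g2"],
            [f"c{i}" for i in range(5)],
            labels=["A", "A", "A", "B", "B"],
        )
        with pytest.raises(ClassTooSmallError):
            cs.stratified_kfold_cv(ds, fast_config, folds=3, seed=0)


class TestCrossDatasetEval:
    def test_matched_batches_high_accuracy(self, fast_config):
        cfg = cs.SimulationConfig(
            n_types=3, cells_per_type=(60, 60, 60), n_genes=200,
            markers_per_type=10, batch_effect_sd=0.0, seed=21,
        )
        train, test = cs.simulate_pair(cfg, mode="batch-shift")
        rep = cs.cross_dataset_eval(train, test, fast_config, protocol="cross-batch")
        assert rep.accuracy >= 0.9
        assert rep.protocol == "cross-batch"

    def test_test_only_class_scores_zero_f1(self, fast_config):
        cfg = cs.SimulationConfig(
            n_types=3, cells_per_type=(30, 30, 30), n_genes=120,
            markers_per_type=8, seed=11,
        )
        train, test = cs.simulate_pair(cfg, mode="label-subset")
        rep = cs.cross_dataset_eval(train, test, fast_config)
        assert rep.per_class_f1["type3"] == 0.0

    def test_multiple_training_sets_pooled_on_shared_genes(self, fast_config):
        cfg = cs.SimulationConfig(
            n_types=2, cells_per_type=(30, 30), n_genes=100, markers_per_type=6,
            seed=2,
        )
        a, _ = cs.simulate_dataset(cfg)
        b, _ = cs.simulate_dataset(
            cs.SimulationConfig(
                n_types=2, cells_per_type=(30, 30), n_genes=100,
                markers_per_type=6, seed=3,
            )
        )
        b = cs.ExpressionDataset(
            b.matrix, b.gene_ids,
            [f"x_{c}" for c in b.cell_ids], labels=b.labels,
        )
        b_shifted = b.subset_genes(b.gene_ids[10:])  # 90-gene overlap
        rep = cs.cross_dataset_eval([a, b_shifted], a, fast_config, protocol="inter")
        assert rep.accuracy >= 0.9


class TestDownsample:
    def test_exact_target_sizes(self):
        sizes = {"basal": 6009, "ciliated": 1333, "secretory": 4792}
        labels = [c for c, n in sizes.items() for _ in range(n)]
        n = len(labels)
        ds = cs.ExpressionDataset(
            np.ones((n, 2)), ["g0", "g1"], [f"c{i}" for i in range(n)], labels=labels
        )
        out = cs.downsample_per_class(ds, target=1333, seed=0)
        import pandas as pd

        counts = pd.Series(out.labels).value_counts().to_dict()
        assert counts == {"basal": 1333, "ciliated": 1333, "secretory": 1333}

    def test_noop_when_target_exceeds_classes(self, tiny_dense):
        out = cs.downsample_per_class(tiny_dense, target=10, seed=0)
        assert out.cell_ids == tiny_dense.cell_ids

    def test_seed_determinism_and_order_preserved(self):
        labels = ["A"] * 50 + ["B"] * 20
        ds = cs.ExpressionDataset(
            np.ones((70, 2)), ["g0", "g1"], [f"c{i:03d}" for i in range(70)],
            labels=labels,
        )
        a = cs.downsample_per_class(ds, target=10, seed=4)
        b = cs.downsample_per_class(ds, target=10, seed=4)
        assert a.cell_ids == b.cell_ids
        assert a.cell_ids == sorted(a.cell_ids)  # original order kept

    def test_target_validation(self, tiny_dense):
        with pytest.raises(ValueError):
            cs.downsample_per_class(tiny_dense, target=0)


class TestRepeatedDownsampleEval:
    def test_single_repeat_equals_downsample_plus_eval(self, fast_config):
        cfg = cs.SimulationConfig(
            n_types=2, cells_per_type=(40, 20), n_genes=80, markers_per_type=5,
            seed=6,
        )
        train, _ = cs.simulate_dataset(cfg)
        test, _ = cs.simulate_dataset(
            cs.SimulationConfig(
                n_types=2, cells_per_type=(15, 15), n_genes=80,
                markers_per_type=5, seed=8,
            )
        )
        test = cs.ExpressionDataset(
            test.matrix, test.gene_ids, [f"t_{c}" for c in test.cell_ids],
            labels=test.labels,
        )
        rep = cs.repeated_downsample_eval(
            train, test, target=20, repeats=1, model_config=fast_config, seed=9
        )
        manual = cs.cross_dataset_eval(
            cs.downsample_per_class(train, 20, seed=9), test, fast_config, seed=9
        )
        assert rep.accuracy == pytest.approx(manual.accuracy)
        assert rep.macro_f1 == pytest.approx(manual.macro_f1)

    def test_degenerate_target_gives_zero_variance(self, fast_config):
        cfg = cs.SimulationConfig(
            n_types=2, cells_per_type=(20, 20), n_genes=80, markers_per_type=5,
            seed=10,
        )
        train, test = cs.simulate_pair(cfg, mode="batch-shift")
        rep = cs.repeated_downsample_eval(
            train, test, target=1000, repeats=3, model_config=fast_config, seed=0
        )
        accs = [r.accuracy for r in rep.fold_reports]
        # identical samples and fit seed every round -> identical rounds
        assert len(rep.fold_reports) == 3
        assert max(accs) == min(accs)
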