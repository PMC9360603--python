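"""Evaluation protocol: ITR closed forms, fold partitioning, aggregation."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedKFold

from cossvep import EvalReport, compare_modes, itr, kfold_evaluate
from cossvep.evaluate import group_dataset, source_dataset
from cossvep.simulate import SimulationConfig
from cossvep.evaluate import featurize_group
from cossvep.simulate import simulate_group


class TrueLabelPipeline:
    """Cheating oracle with access to the global label table."""

    def __init__(self, X_all, y_all):
        self.table = {X_all[i].tobytes(): y_all[i] for i in range(len(y_all))}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[x.tobytes()] for x in X])


class RandomPipeline:
    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.rng.integers(0, 4, len(X))


class TestItr:
    def test_perfect_accuracy_4_classes_3s_is_40_bits_per_min(self):
        assert itr(1.0, 4, 3.0) == pytest.approx(40.0)

    def test_chance_level_is_zero(self):
        assert itr(0.25, 4, 3.0) == 0.0

    def test_point_nine_accuracy(self):
        assert itr(0.9, 4, 3.0) == pytest.approx(27.45, abs=0.01)

    def test_monotone_above_chance(self):
        values = [itr(p, 4, 3.0) for p in np.linspace(0.25, 1.0, 40)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_shorter_selection_time_scales_rate(self):
        assert itr(1.0, 4, 1.5) == pytest.approx(2 * itr(1.0, 4, 3.0))

    @pytest.mark.parametrize("bad", [(-0.1, 4, 3.0), (0.5, 1, 3.0), (0.5, 4, 0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            itr(*bad)


class TestKFold:
    def make_data(self, n_per_class, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(np.arange(4), n_per_class)
        X = rng.random((len(y), 3, 10))
        return X, y

    def test_oracle_pipeline_scores_one(self):
        X, y = self.make_data(10)
        report = kfold_evaluate(X, y, lambda: TrueLabelPipeline(X, y), k=10, seed=0)
        assert report.mean_accuracy == 1.0
        assert len(report.fold_accuracies) == 10

    def test_stratified_folds_have_one_trial_per_class(self):
        X, y = self.make_data(10)
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test_idx in splitter.split(X, y):
            assert len(test_idx) == 4
            assert sorted(y[test_idx]) == [0, 1, 2, 3]

    def test_partition_covers_every_trial_exactly_once(self):
        X, y = self.make_data(10)
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=3)
        seen = np.concatenate([t for _, t in splitter.split(X, y)])
        assert sorted(seen) == list(range(40))

    def test_random_pipeline_near_chance(self):
        X, y = self.make_data(100, seed=1)  # 400 trials
        report = kfold_evaluate(X, y, lambda: RandomPipeline(seed=2), k=10, seed=1)
        assert report.mean_accuracy == pytest.approx(0.25, abs=0.05)
        assert report.itr_bits_per_min < 1.0

    def test_too_few_trials_per_class_raises(self):
        X, y = self.make_data(5)
        with pytest.raises(ValueError, match="per class"):
            kfold_evaluate(X, y, lambda: RandomPipeline(), k=10)


class TestDatasets:
    def test_group_dataset_shapes(self):
        config = SimulationConfig()
        group = simulate_group(config, 2, trials_per_class=2, seed=0)
        feats = featurize_group(group, window_s=3.0)
        Xs, ys = group_dataset(feats, "single")
        assert Xs.shape == (16, 3, 78) and len(ys) == 16
        Xp, yp = group_dataset(feats, "parallel")
        assert Xp.shape == (8, 6, 78)
        Xa, _ = group_dataset(feats, "average")
        assert Xa.shape == (8, 3, 78)
        Xse, _ = group_dataset(feats, "serial")
        assert Xse.shape == (8, 3, 156)

    def test_source_dataset_fused_size_scales_with_combinations(self):
        config = SimulationConfig()
        X, y = source_dataset(
            "parallel", 2, config, n_source_subjects=3, trials_per_class=2,
            seed=0, window_s=3.0, combinations_per_trial=2,
        )
        assert X.shape == (16, 6, 78)  # 8 trials x 2 combinations
        assert sorted(np.unique(y)) == [0, 1, 2, 3]


def make_report(mode, window, acc, seed=0):
    return EvalReport(
        mode=mode,
        window_s=window,
        fold_accuracies=[acc] * 10,
        mean_accuracy=acc,
        itr_bits_per_min=itr(acc, 4, window),
        n_subjects=2,
        seed=seed,
    )


class TestCompareModes:
    def test_full_grid_aggregation(self):
        reports = [
            make_report(m, w, a)
            for m, a in [("single", 0.8), ("parallel", 0.9)]
            for w in (3.0, 2.0)
        ]
        tables = compare_modes(reports)
        assert tables["accuracy"].shape == (2, 2)
        assert tables["overall"]["parallel"] == pytest.approx(0.9)
        assert tables["overall"]["single"] == pytest.approx(0.8)
        assert list(tables["accuracy"].columns) == [3.0, 2.0]

    def test_single_report_degenerate(self):
        tables = compare_modes([make_report("single", 3.0, 0.7)])
        assert tables["accuracy"].shape == (1, 1)

    def test_identical_accuracies_give_identical_overall(self):
        reports = [make_report(m, w, 0.75) for m in ("single", "average") for w in (3.0, 1.6)]
        tables = compare_modes(reports)
        assert tables["overall"]["single"] == tables["overall"]["average"]

    def test_inconsistent_window_sets_rejected(self):
        reports = [make_report("single", 3.0, 0.8), make_report("parallel", 2.0, 0.9)]
        with pytest.raises(ValueError, match="inconsistent"):
            compare_modes(reports)

    def test_duplicate_cell_rejected(self):
        reports = [make_report("single", 3.0, 0.8), make_report("single", 3.0, 0.9)]
        with pytest.raises(ValueError, match="duplicate"):
            compare_modes(reports)

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            make_report("single", 3.0, 1.2)


def test_accuracy_degrades_with_shorter_windows(fusion_sweep_results):
    """Mean single-person accuracy correlates positively with window length
    (the shorter the analysis window, the harder the classification)."""
    means = fusion_sweep_results.groupby("window_s")["single"].mean()
    rho, _ = spearmanr(means.index.values, means.values)
    assert rho > 0


def test_time_window_sweep_single_cell_produces_one_report():
    """A one-window, one-mode sweep returns a single well-formed report."""
    from cossvep import time_window_sweep
    from cossvep.training import TrainConfig

    config = SimulationConfig(snr_db=10.0)
    group = simulate_group(config, 2, trials_per_class=4, seed=2)
    reports = time_window_sweep(
        group,
        modes=("average",),
        windows=(3.0,),
        seed=2,
        k=4,
        sim_config=config,
        n_source_subjects=2,
        source_trials_per_class=4,
        pretrain_config=TrainConfig.for_pretrain(seed=2, epochs=4),
        finetune_config=TrainConfig.for_finetune(seed=2, epochs=2),
    )
    assert len(reports) == 1
    r = reports[0]
    assert r.mode == "average" and r.window_s == 3.0
    assert len(r.fold_accuracies) == 4
    tables = compare_modes(reports)
    assert tables["accuracy"].shape == (1, 1)
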