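"""Dataset splitting, the tanh/tanh network, the structure sweep, and OVO SVM."""

import numpy as np
import pandas as pd
import pytest

import spicevision as sv


class TestSplitDataset:
    def test_60_20_20_stratified_counts(self):
        labels = np.repeat([1, 2, 3, 4, 5], 18)
        table = sv.FeatureTable(
            features=pd.DataFrame(np.zeros((90, 2)), columns=["a", "b"]),
            labels=labels)
        tr, va, te = sv.split_dataset(table, sv.SplitSpec(seed=0))
        assert (tr.n_samples, va.n_samples, te.n_samples) == (54, 18, 18)
        for part in (tr, va, te):
            counts = np.bincount(part.labels, minlength=6)[1:]
            assert counts.max() - counts.min() <= 1

    def test_all_train(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table,
                                      sv.SplitSpec(fractions=(1.0, 0.0, 0.0)))
        assert tr.n_samples == 100 and va.n_samples == 0 and te.n_samples == 0

    def test_disjoint_exhaustive_and_deterministic(self, blobs_table):
        spec = sv.SplitSpec(seed=5)
        parts1 = sv.split_dataset(blobs_table, spec)
        parts2 = sv.split_dataset(blobs_table, spec)
        for p1, p2 in zip(parts1, parts2):
            pd.testing.assert_frame_equal(p1.features, p2.features)
        assert sum(p.n_samples for p in parts1) == blobs_table.n_samples

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sv.SplitSpec(fractions=(0.5, 0.2, 0.2))


class TestTrainMlp:
    def test_separable_blobs_high_test_ccr_across_seeds(self, blobs_table):
        ccrs = []
        for seed in range(10):
            tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=seed))
            model = sv.train_mlp(tr, va, 13,
                                 sv.MLPConfig(max_epochs=300, seed=seed))
            ccrs.append(float((model.predict(te) == te.labels).mean()))
        assert np.mean(ccrs) >= 0.95

    def test_output_dimensionality_matches_classes(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=0))
        model = sv.train_mlp(tr, va, 4, sv.MLPConfig(max_epochs=20, seed=0))
        assert model.forward(te.features.to_numpy()).shape == (te.n_samples, 5)
        assert model.n_classes == 5

    def test_constant_features_halt_by_patience(self):
        labels = np.repeat([1, 2], 20)
        table = sv.FeatureTable(
            features=pd.DataFrame(np.full((40, 3), 0.7),
                                  columns=["a", "b", "c"]),
            labels=labels)
        tr, va, _ = sv.split_dataset(table, sv.SplitSpec(
            fractions=(0.6, 0.4, 0.0), seed=0))
        cfg = sv.MLPConfig(max_epochs=1000, patience=10, seed=0)
        model = sv.train_mlp(tr, va, 3, cfg)
        assert len(model.log) < cfg.max_epochs  # stopped by patience

    def test_empty_partition_rejected(self, blobs_table):
        empty = blobs_table.take(np.array([], dtype=int))
        with pytest.raises(ValueError):
            sv.train_mlp(empty, None, 3, sv.MLPConfig())

    def test_training_log_records_validation_minimum(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=1))
        model = sv.train_mlp(tr, va, 8, sv.MLPConfig(max_epochs=200, seed=1))
        log_min = model.log["val_mse"].min()
        assert model.best_validation_error == pytest.approx(log_min)
        assert model.log.loc[model.log["val_mse"].idxmin(), "epoch"] \
            == model.best_epoch


class TestSweepStructures:
    def test_sweep_1_to_20_gives_20_records(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=0))
        cfg = sv.MLPConfig(hidden_sizes_to_sweep=tuple(range(1, 21)),
                           max_epochs=15, seed=0)
        sweep = sv.sweep_structures(tr, va, te, cfg)
        assert len(sweep.records) == 20
        assert list(sweep.records["hidden_size"]) == list(range(1, 21))

    def test_singleton_sweep_chooses_that_structure(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=0))
        cfg = sv.MLPConfig(hidden_sizes_to_sweep=(7,), max_epochs=30, seed=0)
        assert sv.sweep_structures(tr, va, te, cfg).chosen_hidden_size == 7

    def test_chosen_structure_attains_max_overall_ccr(self, blobs_table):
        tr, va, te = sv.split_dataset(blobs_table, sv.SplitSpec(seed=2))
        cfg = sv.MLPConfig(hidden_sizes_to_sweep=(1, 5, 13),
                           max_epochs=100, seed=2)
        sweep = sv.sweep_structures(tr, va, te, cfg)
        rec = sweep.records
        chosen_ccr = rec.loc[rec["hidden_size"] == sweep.chosen_hidden_size,
                             "overall_ccr"].iloc[0]
        assert chosen_ccr == rec["overall_ccr"].max()


class TestSvmOvo:
    def test_five_classes_ten_binary_classifiers(self, blobs_table):
        model = sv.train_svm_ovo(blobs_table)
        assert model.n_classifiers == 10

    def test_separable_training_set_fully_correct(self, blobs_table):
        model = sv.train_svm_ovo(blobs_table, sv.SVMConfig(C=1000.0))
        assert (model.predict(blobs_table) == blobs_table.labels).all()

    def test_identical_class_distributions_chance_level(self):
        g = np.random.default_rng(3)
        X = g.standard_normal((400, 3))
        labels = np.r_[np.ones(200, dtype=int), np.full(200, 2, dtype=int)]
        table = sv.FeatureTable(
            features=pd.DataFrame(X, columns=["a", "b", "c"]), labels=labels)
        tr, _, te = sv.split_dataset(table, sv.SplitSpec(
            fractions=(0.8, 0.0, 0.2), seed=3))
        model = sv.train_svm_ovo(tr, sv.SVMConfig(C=1.0))
        ccr = float((model.predict(te) == te.labels).mean())
        assert abs(ccr - 0.5) < 0.2  # binomial noise around chance

    def test_single_class_rejected(self):
        table = sv.FeatureTable(
            features=pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"]),
            labels=np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            sv.train_svm_ovo(table)


class TestScalingInvariance:
    def test_both_classifiers_invariant_to_feature_rescaling(self, blobs_table):
        scaled = sv.FeatureTable(
            features=blobs_table.features * np.array([100.0, 1.0]) + 5.0,
            labels=blobs_table.labels)
        spec = sv.SplitSpec(seed=0)
        for builder in (
            lambda t: sv.train_svm_ovo(
                sv.split_dataset(t, spec)[0], sv.SVMConfig(seed=0)),
            lambda t: sv.train_mlp(*sv.split_dataset(t, spec)[:2], 6,
                                   sv.MLPConfig(max_epochs=50, seed=0)),
        ):
            m1 = builder(blobs_table)
            m2 = builder(scaled)
            p1 = m1.predict(sv.split_dataset(blobs_table, spec)[2])
            p2 = m2.predict(sv.split_dataset(scaled, spec)[2])
            assert np.array_equal(p1, p2)

    def test_label_shuffle_is_chance_level(self, blobs_table):
        g = np.random.default_rng(9)
        shuffled = sv.FeatureTable(features=blobs_table.features,
                                   labels=g.permutation(blobs_table.labels))
        tr, _, te = sv.split_dataset(shuffled, sv.SplitSpec(
            fractions=(0.8, 0.0, 0.2), seed=9))
        model = sv.train_svm_ovo(tr, sv.SVMConfig(C=1.0))
        ccr = float((model.predict(te) == te.labels).mean())
        assert ccr < 0.5  # K=5 chance is 0.2; allow generous binomial slack
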