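import numpy as np
import pytest

from pdmotor.inception import (
    InceptionConfig,
    InceptionModule,
    InceptionTimeClassifier,
    build_network,
    ensemble_predict,
    predict_proba,
    train,
)
from pdmotor.metrics import PredictionSet, balanced_accuracy
from pdmotor.windows import WindowedDataset

COMPACT = dict(depth=2, filter_size=20, n_filters=8, bottleneck_channels=8,
               n_classes=2, n_channels=3)


def _module(c_in=3, **kw):
    cfg = InceptionConfig(**{**COMPACT, **kw})
    return InceptionModule(c_in, cfg, np.random.default_rng(0)), cfg


class TestInceptionModule:
    def test_three_single_filter_branches_give_four_channels(self):
        module, _ = _module(n_filters=1, bottleneck_channels=1)
        out = module.forward(np.random.default_rng(1).normal(size=(2, 3, 50)), False)
        assert out.shape == (2, 4, 50)

    def test_default_filters_give_128_channels(self):
        module, _ = _module(n_filters=32, filter_size=40, bottleneck_channels=32)
        out = module.forward(np.random.default_rng(2).normal(size=(1, 3, 60)), False)
        assert out.shape[1] == 4 * 32 == 128

    @pytest.mark.parametrize("L", [17, 50, 101])
    def test_output_length_equals_input_length(self, L):
        module, _ = _module()
        out = module.forward(np.random.default_rng(3).normal(size=(2, 3, L)), False)
        assert out.shape[2] == L

    def test_halving_count_mode_branch_channels(self):
        module, _ = _module(n_filters=4, filter_size=64,
                            branch_mode="halving_count")
        out = module.forward(np.random.default_rng(4).normal(size=(1, 3, 70)), False)
        assert out.shape[1] == 4 + 1  # one filter per branch + pool branch

    def test_receptive_field_is_local(self):
        """A perturbation far outside the receptive field leaves an output
        position unchanged (single module, eval mode)."""
        module, cfg = _module(filter_size=12)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 3, 120))
        base = module.forward(x, False)
        x2 = x.copy()
        x2[0, :, 110] += 10.0  # far from probe position 10
        out = module.forward(x2, False)
        assert np.allclose(base[0, :, 10], out[0, :, 10])
        assert not np.allclose(base[0, :, 108], out[0, :, 108])


class TestBuildNetwork:
    def test_depth_counts_modules(self):
        net = build_network(InceptionConfig(**{**COMPACT, "depth": 6}))
        assert len(net.modules) == 6

    def test_probability_rows_sum_to_one(self):
        net = build_network(InceptionConfig(**COMPACT))
        probs = net.forward(np.random.default_rng(6).normal(size=(5, 3, 40)))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_parameter_count_increases_with_filters(self):
        counts = [
            build_network(InceptionConfig(**{**COMPACT, "n_filters": nf}))
            .count_parameters()
            for nf in (2, 4, 8)
        ]
        assert counts == sorted(counts) and counts[0] < counts[-1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            InceptionConfig(depth=0)


def _toy_dataset(n=48, L=40, n_classes=2, seed=0):
    """Sinusoid-frequency classes: class k carries a (k+2) Hz tone."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    t = np.arange(L) / 50.0
    acc = np.stack([
        np.vstack([np.sin(2 * np.pi * (k + 2) * 4 * t + rng.uniform(0, 6.28))
                   + 0.1 * rng.normal(size=L) for _ in range(3)])
        for k in y
    ])
    return WindowedDataset(acc, y, np.array([f"P{i % 6}" for i in range(n)], object),
                           np.array(["t"] * n, object), np.zeros(n, int),
                           "bradykinesia", [str(c) for c in range(n_classes)], 50.0)


class TestTraining:
    def test_loss_decreases_over_first_epochs(self):
        ds = _toy_dataset()
        cfg = InceptionConfig(**{**COMPACT, "max_epochs": 6, "seed": 0})
        net = train(build_network(cfg), ds, cfg)
        assert len(net.loss_history) == 6
        assert net.loss_history[4] < net.loss_history[0]
        assert all(np.isfinite(net.loss_history))

    def test_training_is_deterministic(self):
        ds = _toy_dataset()
        cfg = InceptionConfig(**{**COMPACT, "max_epochs": 2, "seed": 3})
        p1 = predict_proba(train(build_network(cfg), ds, cfg), ds)
        p2 = predict_proba(train(build_network(cfg), ds, cfg), ds)
        assert np.array_equal(p1, p2)

    def test_channel_mismatch_rejected(self):
        ds = _toy_dataset()
        cfg = InceptionConfig(**{**COMPACT, "n_channels": 5})
        with pytest.raises(ValueError):
            train(build_network(cfg), ds, cfg)


class TestEnsemble:
    def test_identical_members_equal_single_model(self):
        ds = _toy_dataset(n=12)
        cfg = InceptionConfig(**COMPACT)
        net = build_network(cfg)
        single = predict_proba(net, ds)
        ens = ensemble_predict([net] * 5, ds)
        assert np.allclose(ens.scores, single)

    def test_rows_sum_to_one(self):
        ds = _toy_dataset(n=12)
        cfg = InceptionConfig(**COMPACT)
        nets = [build_network(InceptionConfig(**{**COMPACT, "seed": s}))
                for s in range(3)]
        ens = ensemble_predict(nets, ds)
        assert np.allclose(ens.scores.sum(axis=1), 1.0)

    def test_heterogeneous_class_counts_rejected(self):
        ds = _toy_dataset(n=12)
        a = build_network(InceptionConfig(**COMPACT))
        b = build_network(InceptionConfig(**{**COMPACT, "n_classes": 3}))
        with pytest.raises(ValueError):
            ensemble_predict([a, b], ds)

    def test_ensemble_variance_not_larger_than_single(self):
        """Across seeds, 3-member ensembles vary no more than single nets."""
        ds = _toy_dataset(n=60, seed=1)
        fit, test = ds.subset(np.arange(60) < 40), ds.subset(np.arange(60) >= 40)
        cfg_base = dict(COMPACT, depth=1, n_filters=4, bottleneck_channels=4,
                        max_epochs=8)
        single_bas, ens_bas = [], []
        for rep in range(3):
            cfg = InceptionConfig(**{**cfg_base, "seed": 100 * rep})
            net = train(build_network(cfg), fit, cfg)
            single_bas.append(balanced_accuracy(
                PredictionSet(test.labels, predict_proba(net, test))))
            clf = InceptionTimeClassifier(
                InceptionConfig(**{**cfg_base, "seed": 100 * rep + 7}),
                n_members=3).fit(fit)
            ens_bas.append(balanced_accuracy(clf.predict_set(test)))
        assert np.std(ens_bas) <= np.std(single_bas) + 0.05


class TestRecovery:
    def test_bradykinesia_recovery(self, easy_brady_split):
        """Compact network reaches BA >= 0.85 on the single-factor cohort."""
        fit_set, test_set = easy_brady_split
        cfg = InceptionConfig(**{**COMPACT, "max_epochs": 25, "seed": 0})
        net = train(build_network(cfg), fit_set, cfg)
        pred = PredictionSet(test_set.labels, predict_proba(net, test_set))
        assert balanced_accuracy(pred) >= 0.85

    def test_label_permutation_collapses_to_chance(self, easy_brady_split):
        fit_set, test_set = easy_brady_split
        rng = np.random.default_rng(1)
        permuted = WindowedDataset(
            fit_set.acc, rng.permutation(fit_set.labels), fit_set.patient_ids,
            fit_set.tasks, fit_set.source_offsets, fit_set.symptom,
            list(fit_set.class_names), fit_set.fs_hz,
        )
        cfg = InceptionConfig(**{**COMPACT, "max_epochs": 12, "seed": 0})
        net = train(build_network(cfg), permuted, cfg)
        pred = PredictionSet(test_set.labels, predict_proba(net, test_set))
        # windows cluster by patient x task (labels are drawn per cell), so
        # the chance-level band uses the ~24 independent cells, not windows
        assert abs(balanced_accuracy(pred) - 0.5) < 3 * np.sqrt(0.25 / 24)
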