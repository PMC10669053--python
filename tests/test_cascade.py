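import numpy as np
import pytest

from cardioseg.cascade import (
    PlateauScheduler,
    Split,
    TrainConfig,
    derive_seed,
    fuse_predictions,
    predict_case,
    run_experiment,
    split_dataset,
    train_cascade,
)
from cardioseg.imageio import LabelMap
from cardioseg.phantom import PhantomSpec, generate_dataset


def tiny_cfg(**kwargs):
    defaults = dict(
        learning_rate=1e-3,
        batch_size=4,
        max_epochs=1,
        base_width=2,
        depth=2,
        dropout_rate=0.0,
        seed=0,
        folds=2,
    )
    defaults.update(kwargs)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = PhantomSpec(shape=(8, 32, 32), spacing=(5.0, 3.0, 3.0))
    return generate_dataset(5, spec, seed=3)


class TestSplit:
    def test_60_case_622_split(self):
        cfg = TrainConfig(seed=1)
        split = split_dataset(list(range(60)), cfg)
        assert (len(split.train), len(split.val), len(split.test)) == (36, 12, 12)
        all_ids = set(split.train) | set(split.val) | set(split.test)
        assert all_ids == set(range(60))
        assert not set(split.train) & set(split.test)
        assert not set(split.val) & set(split.test)

    def test_deterministic_per_seed(self):
        cfg = TrainConfig(seed=9)
        a = split_dataset(list(range(20)), cfg)
        b = split_dataset(list(range(20)), cfg)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)
        c = split_dataset(list(range(20)), TrainConfig(seed=10))
        assert (a.train, a.val, a.test) != (c.train, c.val, c.test)

    def test_folds_partition_dev_cases(self):
        cfg = TrainConfig(seed=2)
        split = split_dataset(list(range(30)), cfg)
        dev = set(split.train) | set(split.val)
        seen = []
        for train_k, val_k in split.folds:
            assert not set(train_k) & set(val_k)
            assert set(train_k) | set(val_k) == dev
            seen.extend(val_k)
        assert sorted(seen) == sorted(dev)  # each dev case validates exactly once

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], TrainConfig(folds=5))


class _FakeOpt:
    def __init__(self, lr):
        self.lr = lr


class TestPlateauScheduler:
    def test_flat_sequence_halves_exactly_once_at_epoch_11(self):
        opt = _FakeOpt(1e-4)
        sched = PlateauScheduler(opt, patience=10, factor=0.5)
        halved_at = [
            epoch for epoch in range(1, 12) if sched.step(1.0)
        ]
        assert halved_at == [11]
        assert opt.lr == pytest.approx(5e-5)

    def test_improvement_resets_patience(self):
        opt = _FakeOpt(1.0)
        sched = PlateauScheduler(opt, patience=3, factor=0.5)
        losses = [5.0, 4.0, 4.0, 4.0, 3.0, 3.0, 3.0, 3.0]
        reductions = [sched.step(v) for v in losses]
        assert reductions == [False] * 7 + [True]

    def test_lr_sequence_nonincreasing_with_exact_factor(self):
        opt = _FakeOpt(8.0)
        sched = PlateauScheduler(opt, patience=2, factor=0.5)
        lrs = []
        for v in [1.0] * 9:
            sched.step(v)
            lrs.append(opt.lr)
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        drops = {round(a / b, 6) for a, b in zip(lrs, lrs[1:]) if a != b}
        assert drops == {2.0}


class TestFusion:
    def test_precedence_and_passthrough(self):
        spacing = (5.0, 1.0, 1.0)
        cg = np.zeros((2, 4, 4), dtype=np.int16)
        fg = np.zeros((2, 4, 4), dtype=np.int16)
        cg[0, 0, 0] = 1
        fg[0, 0, 0] = 5  # conflict: coarse label must win
        fg[1, 1, 1] = 7
        fused = fuse_predictions(LabelMap(cg, spacing), LabelMap(fg, spacing))
        assert fused.data[0, 0, 0] == 1
        assert fused.data[1, 1, 1] == 7
        # all-background fg leaves cg untouched and vice versa
        empty = LabelMap(np.zeros_like(cg), spacing)
        np.testing.assert_array_equal(
            fuse_predictions(LabelMap(cg, spacing), empty).data, cg
        )
        np.testing.assert_array_equal(
            fuse_predictions(empty, LabelMap(fg, spacing)).data, fg
        )

    def test_voxel_count_conserved(self):
        spacing = (5.0, 1.0, 1.0)
        rng = np.random.default_rng(0)
        cg = np.where(rng.random((3, 4, 4)) < 0.3, 1, 0).astype(np.int16)
        fg = np.where(rng.random((3, 4, 4)) < 0.3, 8, 0).astype(np.int16)
        fused = fuse_predictions(LabelMap(cg, spacing), LabelMap(fg, spacing))
        assert fused.data.size == cg.size
        assert set(np.unique(fused.data)) <= {0, 1, 8}

    def test_shared_code_rejected(self):
        spacing = (5.0, 1.0, 1.0)
        a = np.full((1, 2, 2), 3, dtype=np.int16)
        with pytest.raises(ValueError, match="mis-remapped|share"):
            fuse_predictions(LabelMap(a, spacing), LabelMap(a.copy(), spacing))


class TestTrainCascade:
    def test_channel_arithmetic_for_size_grouping(self, tiny_dataset):
        model = train_cascade(tiny_dataset, tiny_cfg(max_epochs=0))
        assert model.lsnet.spec.in_channels == 1
        assert model.lsnet.spec.out_classes == 5  # 4 chambers + background
        assert model.ssnet.spec.in_channels == 5  # image + 4 prior channels
        assert model.ssnet.spec.out_classes == 7  # 6 vessels + background

    def test_predict_case_contract(self, tiny_dataset):
        model = train_cascade(tiny_dataset, tiny_cfg(max_epochs=0))
        vol, _ = tiny_dataset[0]
        pred = predict_case(model, vol)
        assert pred.shape == vol.shape
        assert pred.spacing == pytest.approx(vol.spacing)
        assert set(np.unique(pred.data)) <= set(range(0, 11))

    def test_seeded_training_reproducible(self, tiny_dataset):
        cfg = tiny_cfg(max_epochs=2, seed=5)
        m1 = train_cascade(tiny_dataset, cfg)
        m2 = train_cascade(tiny_dataset, cfg)
        assert m1.history["lsnet"]["train_loss"] == m2.history["lsnet"]["train_loss"]
        assert m1.history["ssnet"]["val_loss"] == m2.history["ssnet"]["val_loss"]
        vol, _ = tiny_dataset[0]
        np.testing.assert_array_equal(
            predict_case(m1, vol).data, predict_case(m2, vol).data
        )

    def test_gold_priors_mode(self, tiny_dataset):
        cfg = tiny_cfg(max_epochs=1, prior_source="gold")
        model = train_cascade(tiny_dataset, cfg)
        assert model.ssnet.spec.in_channels == 5

    def test_fingerprint_roundtrip(self, tiny_dataset, tmp_path):
        model = train_cascade(tiny_dataset, tiny_cfg(max_epochs=0))
        model.save(tmp_path)
        from cardioseg.cascade import CascadeModel

        back = CascadeModel.load(tmp_path)
        assert back.grouping.name == model.grouping.name
        assert back.cg_table == model.cg_table
        assert back.fg_table == model.fg_table
        vol, _ = tiny_dataset[0]
        np.testing.assert_array_equal(
            predict_case(back, vol).data, predict_case(model, vol).data
        )

    def test_trained_ssnet_consumes_prior_channels(self, tiny_dataset):
        model = train_cascade(tiny_dataset, tiny_cfg(max_epochs=1))
        vol, _ = tiny_dataset[0]
        from cardioseg.cascade import _normalized

        img = _normalized(vol).astype(np.float32)[0]
        x = np.zeros((1, 5, *img.shape), dtype=np.float32)
        x[0, 0] = img
        with_zero_priors = model.ssnet.forward(x)
        x[0, 1] = 1.0  # claim the whole slice as one chamber
        with_priors = model.ssnet.forward(x)
        assert np.abs(with_priors - with_zero_priors).max() > 1e-6

    def test_nonfinite_loss_aborts_with_diagnostic(self, tiny_dataset):
        cfg = tiny_cfg(max_epochs=3, learning_rate=1e12)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_cascade(tiny_dataset, cfg)


class TestExperimentHarness:
    def test_arms_share_test_cases_and_report_shape(self, tiny_dataset):
        results = run_experiment(tiny_dataset, tiny_cfg(max_epochs=0))
        summary = results["summary"]
        assert set(summary["arm"]) == {"baseline", "two_stage", "cascade"}
        # one row per arm per structure
        assert len(summary) == 3 * 10
        n_test = len(results["split"].test)
        for arm in ("baseline", "two_stage", "cascade"):
            assert len(results["arms"][arm]["per_case"]) == n_test

    def test_grouping_sweep_report_shape(self, tiny_dataset):
        from cardioseg.cascade import grouping_sweep
        from cardioseg.registry import builtin_groupings

        table = grouping_sweep(tiny_dataset, tiny_cfg(max_epochs=0))
        assert list(table["grouping"]) == [g.name for g in builtin_groupings()]
        for acronym in ("LA", "RA", "LV", "RV", "SVC", "IVC", "PA", "PV", "AA", "DA"):
            assert acronym in table.columns


class TestDeriveSeed:
    def test_stable_and_distinct(self):
        assert derive_seed(1, "a") == derive_seed(1, "a")
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert derive_seed(1, "a") != derive_seed(2, "a")
        assert 0 <= derive_seed(123456789, "x") < 2**31
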