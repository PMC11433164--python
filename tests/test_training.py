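"""Split bookkeeping, scale assignment, the optimisation loop, and
full-volume evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxsr.degradation import PairedSample, ScaleFactor, make_pair
from voxsr.errors import ParameterError
from voxsr.models import ArchitectureSpec, build_model
from voxsr.nn import Adam, ReduceLROnPlateau, Tensor, init_xavier_uniform
from voxsr.objectives import LossSpec, training_loss
from voxsr.patching import PatchSpec
from voxsr.training import (
    TrainConfig,
    assign_epoch_scales,
    evaluate,
    predict_volume,
    split_indices,
    split_subjects,
    train,
)
from voxsr.volumes import Volume

from conftest import TINY_UNET


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(581, (406, 105, 70)), (577, (403, 104, 70)), (10, (7, 1, 2))],
    )
    def test_floor_arithmetic(self, n, expected):
        assert split_subjects(n) == expected

    @given(st.integers(min_value=3, max_value=5000))
    @settings(max_examples=200, deadline=None)
    def test_conserves_n(self, n):
        train_n, test_n, val_n = split_subjects(n)
        assert train_n + test_n + val_n == n
        assert min(train_n, test_n, val_n) >= 0

    def test_indices_partition_and_are_deterministic(self):
        a = split_indices(50, seed=4)
        b = split_indices(50, seed=4)
        for xa, xb in zip(a, b):
            np.testing.assert_array_equal(xa, xb)
        allidx = np.concatenate(a)
        assert sorted(allidx) == list(range(50))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            split_subjects(2)


class TestEpochScales:
    def test_singleton_scale_set(self):
        got = assign_epoch_scales(["a", "b"], [3.0], epoch=0, seed=1)
        assert got == {"a": 3.0, "b": 3.0}

    def test_deterministic_per_seed_and_epoch(self):
        ids = [f"v{i}" for i in range(20)]
        a = assign_epoch_scales(ids, (2, 3, 4), 5, 7)
        b = assign_epoch_scales(ids, (2, 3, 4), 5, 7)
        c = assign_epoch_scales(ids, (2, 3, 4), 6, 7)
        assert a == b
        assert a != c

    def test_draws_are_uniform(self):
        ids = [str(i) for i in range(10_000)]
        got = assign_epoch_scales(ids, (2, 2.5, 3, 3.5, 4), 0, 3)
        counts = np.array([
            sum(1 for v in got.values() if v == f) for f in (2, 2.5, 3, 3.5, 4)
        ])
        sd = np.sqrt(10_000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 2000) < 3 * sd)

    def test_empty_scale_set_rejected(self):
        with pytest.raises(ParameterError):
            assign_epoch_scales(["a"], [], 0, 0)


class TestPlateauSchedule:
    def test_constant_metric_reduces_exactly_once_in_four_epochs(self):
        class P:  # minimal parameter stub
            data = np.zeros(1)
            grad = None

        opt = Adam([P()], lr=1e-3)
        sched = ReduceLROnPlateau(opt, patience=3, factor=0.1)
        reductions = [sched.step(1.0) for _ in range(4)]
        assert reductions == [False, False, False, True]
        assert opt.lr == pytest.approx(1e-4)
        # patience counter resets after the reduction
        assert sched.step(1.0) is False


class TestTrainLoop:
    def _tiny_pairs(self, n=2, shape=(24, 24, 24)):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(n):
            hr = Volume(data=rng.random(shape, dtype=np.float32), ident=f"v{i}")
            pairs.append(make_pair(hr, ScaleFactor.isotropic(2)))
        return pairs

    def _tiny_cfg(self, **kw):
        base = dict(
            learning_rate=1e-3, epochs=1, effective_batch=2, micro_batch=1,
            patches_per_volume=2, patch_size=16, val_patches_per_volume=1,
            seed=0, loss=LossSpec(kind="l1"), scale_set=(2,),
        )
        base.update(kw)
        return TrainConfig(**base)

    def _tiny_model(self, seed=0):
        spec = ArchitectureSpec(
            "unet", unet_depth=1, unet_base_width=2, mss_scales=2
        )
        return init_xavier_uniform(build_model(spec), seed)

    def test_single_epoch_records_history_and_checkpoint(self):
        model = self._tiny_model()
        run = train(model, self._tiny_pairs(), self._tiny_cfg())
        assert len(run.history) == 1
        assert set(run.best_state) == {n for n, _ in model.named_parameters()}
        assert run.best_epoch == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ParameterError):
            train(self._tiny_model(), [], self._tiny_cfg())

    def test_training_is_deterministic_given_seed(self):
        runs = []
        for _ in range(2):
            model = self._tiny_model(seed=1)
            run = train(model, self._tiny_pairs(), self._tiny_cfg(epochs=2))
            runs.append((run.history, {n: p.data.copy() for n, p in model.named_parameters()}))
        assert runs[0][0] == runs[1][0]
        for name in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][name], runs[1][1][name])

    def test_loss_decreases_when_memorising_one_volume(self):
        model = self._tiny_model(seed=2)
        pairs = self._tiny_pairs(n=1)
        cfg = self._tiny_cfg(epochs=8, patches_per_volume=4)
        run = train(model, pairs, cfg)
        losses = [h["train_loss"] for h in run.history]
        assert losses[-1] < losses[0]

    def test_gradient_accumulation_equals_mean_batch_gradient(self):
        """Accumulating grads of (loss/N) over N patches must equal the
        analytically averaged per-sample gradient of the mean-reduced loss,
        so one optimiser step sees the same direction however the batch
        was chunked."""
        rng = np.random.default_rng(5)
        patches = [
            (rng.random((1, 16, 16, 16), dtype=np.float32),
             rng.random((1, 16, 16, 16), dtype=np.float32))
            for _ in range(4)
        ]
        loss_fn = training_loss(LossSpec(kind="mse"), "unet")

        # route A: per-sample accumulation of loss/N
        m1 = self._tiny_model(seed=9)
        m1.zero_grad()
        for lr_p, hr_p in patches:
            (loss_fn(m1(Tensor(lr_p)), hr_p) * 0.25).backward()
        acc = {n: p.grad for n, p in m1.named_parameters() if p.grad is not None}

        # route B: average of independently computed per-sample gradients
        m2 = self._tiny_model(seed=9)
        mean_grads = {}
        for lr_p, hr_p in patches:
            m2.zero_grad()
            loss_fn(m2(Tensor(lr_p)), hr_p).backward()
            for n, p in m2.named_parameters():
                if p.grad is not None:  # MSS heads are unused by plain UNet
                    mean_grads[n] = mean_grads.get(n, 0.0) + p.grad / 4.0

        assert set(acc) == set(mean_grads)
        for n in acc:
            np.testing.assert_allclose(acc[n], mean_grads[n], atol=1e-6, err_msg=n)

    def test_divergence_raises_with_epoch(self):
        model = self._tiny_model()
        for p in model.parameters():
            p.data[...] = 1e20  # force overflow to non-finite loss
        from voxsr.errors import DivergenceError
        with np.errstate(all="ignore"), pytest.raises(DivergenceError):
            train(model, self._tiny_pairs(), self._tiny_cfg())


class _IdentityModel:
    """Stand-in model whose prediction is its input."""

    class spec:
        name = "identity"

    def infer(self, x):
        return x


class _OracleModel:
    """Stand-in model that returns the matching ground-truth patch."""

    class spec:
        name = "oracle"

    def __init__(self, hr: Volume):
        self.hr = hr

    def infer(self, x):
        # works with whole-volume patches only
        return Tensor(self.hr.data[None])


class TestEvaluate:
    def test_identity_model_reports_input_similarity(self, pair_f2):
        from voxsr.objectives import ssim
        patch = PatchSpec(size=pair_f2.hr.shape, overlap=(0, 0, 0))
        report = evaluate(_IdentityModel(), [pair_f2], patch)
        assert report.rows[0]["ssim"] == pytest.approx(
            ssim(pair_f2.lr_interp, pair_f2.hr), abs=1e-6
        )

    def test_perfect_oracle_scores_perfectly(self, pair_f2):
        patch = PatchSpec(size=pair_f2.hr.shape, overlap=(0, 0, 0))
        report = evaluate(_OracleModel(pair_f2.hr), [pair_f2], patch)
        row = report.rows[0]
        assert row["ssim"] == pytest.approx(1.0)
        assert row["nrmse"] == pytest.approx(0.0)
        assert row["psnr"] == np.inf

    def test_checkpoint_reload_reproduces_predictions(self, tmp_path, pair_f2):
        from voxsr.models import load_checkpoint, save_checkpoint
        model = init_xavier_uniform(
            build_model(ArchitectureSpec("unet", **TINY_UNET)), 3
        )
        patch = PatchSpec(size=(32, 32, 32), overlap=(8, 8, 8))
        before = predict_volume(model, pair_f2.lr_interp, patch)
        path = str(tmp_path / "m.npz")
        save_checkpoint(model, path)
        loaded, _ = load_checkpoint(path)
        after = predict_volume(loaded, pair_f2.lr_interp, patch)
        np.testing.assert_array_equal(before.data, after.data)
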