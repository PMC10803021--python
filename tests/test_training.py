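"""Training engine: checkpoint retention, scheduling, determinism, evaluation."""

import numpy as np
import pytest

from ldcnet import ModelConfig, SceneConfig, TrainConfig, nn
from ldcnet.config import SceneConfig as _SceneConfig
from ldcnet.decoder import build_model
from ldcnet.nn.optim import AdamW, ReduceLROnPlateau
from ldcnet.synthetic import split_dataset, write_dataset
from ldcnet import training


@pytest.fixture
def tiny_run(tmp_path, tiny_config):
    """A written 32x32 dataset plus matching split, small enough to train."""
    scene = SceneConfig(image_size=32, min_instrument_width=3,
                        max_instrument_width=6, seed=21)
    manifest = write_dataset(8, scene, tmp_path / "data")
    split = split_dataset(8, seed=0)
    return manifest, split


class TestCheckpointSet:
    def test_retains_top_k_of_score_stream(self, tmp_path):
        scores = [0.2, 0.5, 0.1, 0.9, 0.4, 0.8, 0.3, 0.7, 0.6, 0.95]
        ckpts = training.CheckpointSet(top_k=5)
        state = {"w": np.zeros(2, dtype=np.float32)}
        for epoch, s in enumerate(scores):
            ckpts.offer(s, epoch, state, tmp_path)
        retained = sorted(e.val_miou for e in ckpts.entries)
        assert retained == sorted(scores)[-5:]
        # heap property: nothing retained scores below anything dropped
        assert min(retained) >= max(sorted(scores)[:-5])
        for e in ckpts.entries:
            assert (tmp_path / f"epoch_{e.epoch:04d}.npz").exists()

    def test_dropped_files_are_removed(self, tmp_path):
        ckpts = training.CheckpointSet(top_k=2)
        state = {"w": np.zeros(1, dtype=np.float32)}
        for epoch, s in enumerate([0.1, 0.2, 0.3, 0.4]):
            ckpts.offer(s, epoch, state, tmp_path)
        files = sorted(p.name for p in tmp_path.glob("*.npz"))
        assert files == ["epoch_0002.npz", "epoch_0003.npz"]

    def test_at_most_five_from_fifty_validations(self, tmp_path):
        rng = np.random.default_rng(1)
        ckpts = training.CheckpointSet(top_k=5)
        state = {"w": np.zeros(1, dtype=np.float32)}
        for epoch in range(50):  # 100 epochs validated every 2
            ckpts.offer(float(rng.random()), epoch, state, tmp_path)
        assert len(ckpts.entries) == 5
        assert [e.val_miou for e in ckpts.entries] == sorted(
            (e.val_miou for e in ckpts.entries), reverse=True)


class TestScheduler:
    def test_lr_never_increases(self):
        opt = AdamW([nn.Parameter(np.zeros(1, dtype=np.float32))], lr=1e-3)
        sched = ReduceLROnPlateau(opt, mode="max", factor=0.5, patience=2)
        rng = np.random.default_rng(0)
        lrs = [sched.step(float(rng.random())) for _ in range(30)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_reduces_after_patience_exceeded(self):
        opt = AdamW([nn.Parameter(np.zeros(1, dtype=np.float32))], lr=1e-3)
        sched = ReduceLROnPlateau(opt, mode="max", factor=0.5, patience=2)
        sched.step(0.9)
        for _ in range(3):
            sched.step(0.5)
        assert opt.lr == pytest.approx(5e-4)

    def test_respects_min_lr(self):
        opt = AdamW([nn.Parameter(np.zeros(1, dtype=np.float32))], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=0, min_lr=1e-4)
        sched.step(0.9)
        for _ in range(10):
            sched.step(0.1)
        assert opt.lr == pytest.approx(1e-4)


class TestTrain:
    def test_short_run_writes_artifacts(self, tiny_run, tiny_config, tmp_path):
        manifest, split = tiny_run
        tc = TrainConfig(epochs=2, batch_size=4, val_every=1,
                         top_k_checkpoints=2, reader_threads=2, seed=0)
        model, ckpts, log = training.train(tiny_config, tc, manifest, split,
                                           tmp_path / "run")
        assert (tmp_path / "run" / "log.csv").exists()
        assert (tmp_path / "run" / "checkpoints.csv").exists()
        assert 1 <= len(ckpts.entries) <= 2
        assert len(log) == 2
        lrs = [row["lr"] for row in log]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_seeded_runs_are_identical(self, tiny_run, tiny_config, tmp_path):
        manifest, split = tiny_run
        tc = TrainConfig(epochs=1, batch_size=4, val_every=1,
                         top_k_checkpoints=1, reader_threads=1, seed=7)
        _, _, log_a = training.train(tiny_config, tc, manifest, split,
                                     tmp_path / "a")
        _, _, log_b = training.train(tiny_config, tc, manifest, split,
                                     tmp_path / "b")
        assert log_a[-1]["loss"] == log_b[-1]["loss"]

    def test_non_finite_loss_aborts(self, tiny_run, tiny_config, tmp_path):
        manifest, split = tiny_run
        model = build_model(tiny_config)
        next(model.parameters()).data[:] = np.nan
        opt = AdamW(model.parameters())
        images = np.zeros((2, 3, 32, 32), dtype=np.float32)
        masks = np.zeros((2, 32, 32), dtype=np.int64)
        from ldcnet.losses import FocalLossConfig
        with pytest.raises(RuntimeError):
            training.train_step(model, opt, images, masks, FocalLossConfig())

    def test_empty_split_rejected(self, tiny_run, tiny_config, tmp_path):
        manifest, split = tiny_run
        with pytest.raises(ValueError):
            training.load_arrays(manifest, [])


class TestEvaluate:
    def test_single_checkpoint_mean_is_itself(self, tiny_run, tiny_config,
                                              tmp_path):
        manifest, split = tiny_run
        tc = TrainConfig(epochs=1, batch_size=4, val_every=1,
                         top_k_checkpoints=1, reader_threads=1, seed=0)
        _, ckpts, _ = training.train(tiny_config, tc, manifest, split,
                                     tmp_path / "run")
        report = training.evaluate(ckpts, manifest, split.test_indices,
                                   tiny_config)
        assert report["mean"]["miou"] == pytest.approx(
            report["per_checkpoint"][0]["miou"])

    def test_mean_of_stubbed_checkpoint_scores(self, monkeypatch, tiny_run,
                                               tiny_config, tmp_path):
        manifest, split = tiny_run
        ckpts = training.CheckpointSet(top_k=5)
        state = build_model(tiny_config).state_dict()
        mious = [0.9, 0.92, 0.94, 0.96, 0.98]
        for i, s in enumerate(mious):
            ckpts.offer(s, i, state, tmp_path / "ck")
        scores = iter([0.98, 0.96, 0.94, 0.92, 0.9])  # served best-first

        class _Stub:
            def __init__(self, miou):
                self.means = {"precision": miou, "recall": miou, "f1": miou,
                              "miou": miou}

        monkeypatch.setattr(training, "evaluate_split",
                            lambda *a, **k: _Stub(next(scores)))
        report = training.evaluate(ckpts, manifest, split.test_indices,
                                   tiny_config)
        assert report["mean"]["miou"] == pytest.approx(0.94)

    def test_missing_checkpoint_file_raises(self, tiny_run, tiny_config,
                                            tmp_path):
        manifest, split = tiny_run
        ckpts = training.CheckpointSet(top_k=1)
        ckpts.entries.append(training.CheckpointEntry(0.5, 0, "/nonexistent.npz"))
        with pytest.raises(FileNotFoundError):
            training.evaluate(ckpts, manifest, split.test_indices, tiny_config)


class TestPredict:
    def test_zeroed_head_predicts_background(self, tiny_config, rng):
        model = build_model(tiny_config)
        model.head.classifier.weight.data[:] = 0.0
        model.head.classifier.bias.data[:] = 0.0
        labels = model.predict(rng.random((2, 3, 32, 32)).astype(np.float32))
        assert (labels == 0).all()

    def test_prediction_is_deterministic(self, tiny_config, rng):
        model = build_model(tiny_config)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(model.predict(x), model.predict(x))

    def test_state_roundtrip_preserves_predictions(self, tiny_config, rng,
                                                   tmp_path):
        model = build_model(tiny_config, seed=3)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        before = model.predict(x)
        nn.save_state(tmp_path / "ck.npz", model.state_dict())
        other = build_model(tiny_config, seed=99)
        other.load_state_dict(nn.load_state(tmp_path / "ck.npz"))
        assert np.array_equal(before, other.predict(x))
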