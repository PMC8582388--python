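"""Hard-mining mechanics, optimizer schedule, early stopping, orchestration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slideminer as sm
from slideminer.inference import ProbabilityMap
from slideminer.training import MiningState, accumulate, mine_slide, select_top_k

from conftest import make_records


def probmap_of(probs: list[float], size: int = 32) -> ProbabilityMap:
    n = int(np.ceil(np.sqrt(len(probs))))
    tiles = [sm.TileCoord((i % n) * size, (i // n) * size, size, 20) for i in range(len(probs))]
    return ProbabilityMap("s", tiles, np.array(probs), size, size // 2, 20)


class TestSelectTopK:
    def test_descending_selection(self):
        pm = probmap_of([0.9, 0.2, 0.8, 0.5, 0.1])
        top = select_top_k(pm, 4)
        probs = dict(zip(pm.tiles, pm.probabilities))
        assert [probs[t] for t in top] == [0.9, 0.8, 0.5, 0.2]

    def test_fewer_tiles_than_k_returns_all(self):
        pm = probmap_of([0.3, 0.1, 0.2])
        assert len(select_top_k(pm, 4)) == 3

    def test_ties_break_row_major(self):
        pm = probmap_of([0.5] * 9)
        top = select_top_k(pm, 4)
        assert top == pm.tiles[:4]

    def test_empty_map_raises(self):
        pm = ProbabilityMap("s", [], np.array([]), 32, 16, 20)
        with pytest.raises(ValueError):
            select_top_k(pm, 4)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mining_monotonicity(self, seed, k):
        """Mean probability of the selected top-k >= mean of any other k tiles."""
        rng = np.random.default_rng(seed)
        pm = probmap_of(rng.random(20).tolist())
        probs = dict(zip(pm.tiles, pm.probabilities))
        top_mean = np.mean([probs[t] for t in select_top_k(pm, k)])
        random_k = rng.choice(len(pm.tiles), size=k, replace=False)
        assert top_mean >= np.mean(pm.probabilities[random_k]) - 1e-12


class TestAccumulate:
    def test_exact_trigger_flushes(self):
        state = MiningState(N=256)
        state.pending = [("s", None, 1)] * 252
        jobs = accumulate(state, [("s", None, 1)] * 4)
        assert len(jobs) == 1 and len(jobs[0]) == 256
        assert state.pending == [] and state.passes_triggered == 1

    def test_overflow_carries(self):
        state = MiningState(N=256)
        state.pending = [("s", None, 1)] * 254
        jobs = accumulate(state, [("s", None, 0)] * 4)
        assert len(jobs[0]) == 256 and len(state.pending) == 2

    def test_mechanics_of_one_full_pass(self):
        """64 mined slides at k=4 with N=256 trigger exactly one pass of 8 batches."""
        state = MiningState(N=256)
        jobs = []
        for i in range(64):
            jobs += accumulate(state, [(f"s{i}", None, i % 2)] * 4)
        assert state.passes_triggered == 1
        assert len(jobs) == 1 and len(jobs[0]) == 256
        assert len(jobs[0]) // 32 == 8  # batches of 32 per pass

    @given(st.lists(st.integers(1, 10), min_size=1, max_size=60))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_trigger_conservation(self, chunks):
        """Tiles consumed by training passes = N * passes_triggered."""
        state = MiningState(N=64)
        consumed = 0
        for c in chunks:
            for job in accumulate(state, [("s", None, 1)] * c):
                consumed += len(job)
        assert consumed == 64 * state.passes_triggered
        assert len(state.pending) < 64


class TestLearningRateSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 0.001), (1, 0.001), (2, 0.00095), (3, 0.00095), (4, 0.0009025),
         (5, 0.0009025), (6, 0.000857375)],
    )
    def test_step_decay(self, epoch, expected):
        config = sm.TrainingConfig(tile_size=64)
        assert sm.learning_rate_at(epoch, config) == pytest.approx(expected, rel=1e-12)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            sm.learning_rate_at(-1, sm.TrainingConfig(tile_size=64))


class TestEarlyStopper:
    def test_improving_sequence_continues(self):
        stopper = sm.EarlyStopper(patience=10)
        decisions = [stopper.update(v) for v in (1.0, 0.9, 0.8)]
        assert decisions == ["continue"] * 3
        assert stopper.best_epoch == 2

    def test_stops_after_patience_non_improving_epochs(self):
        stopper = sm.EarlyStopper(patience=10)
        assert stopper.update(0.5) == "continue"
        decisions = [stopper.update(0.6) for _ in range(10)]
        assert decisions == ["continue"] * 9 + ["stop"]
        assert stopper.best_epoch == 0

    def test_strictly_decreasing_never_stops(self):
        stopper = sm.EarlyStopper(patience=3)
        assert all(stopper.update(1.0 / (i + 1)) == "continue" for i in range(50))

    def test_tie_keeps_earlier_epoch(self):
        stopper = sm.EarlyStopper(patience=5)
        stopper.update(0.5)
        stopper.update(0.5)
        assert stopper.best_epoch == 0

    def test_nan_is_no_improvement(self):
        stopper = sm.EarlyStopper(patience=2)
        stopper.update(0.5)
        assert stopper.update(float("nan")) == "continue"
        assert stopper.update(float("nan")) == "stop"
        assert stopper.best_epoch == 0


class TestConfig:
    def test_n_must_divide_by_batch(self):
        with pytest.raises(ValueError, match="multiple"):
            sm.TrainingConfig(N=250, batch_size=32)

    def test_reference_defaults(self):
        config = sm.TrainingConfig()
        assert (config.k, config.N, config.batch_size) == (4, 256, 32)
        assert (config.beta1, config.beta2) == (0.9, 0.999)
        assert config.patience == 10


class _ConstantModel(sm.ModelContract):
    name = "constant"

    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, batch):
        return np.full(len(batch), self.p)


class TestMineSlide:
    def test_negative_slide_yields_label_zero_tiles(self, negative_slide):
        config = sm.TrainingConfig(tile_size=64, magnification=20)
        mask = sm.detect_tissue(negative_slide, config.otsu_downsample)
        tiles = sm.enumerate_tiles(mask, 64, 32, 0.1, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        mined = mine_slide(_ConstantModel(0.7), negative_slide, config, tiles)
        assert len(mined) == config.k
        assert all(label == 0 for _, label in mined)

    def test_constant_model_selects_row_major_first_k(self, negative_slide):
        config = sm.TrainingConfig(tile_size=64, magnification=20)
        mask = sm.detect_tissue(negative_slide, config.otsu_downsample)
        tiles = sm.enumerate_tiles(mask, 64, 32, 0.1, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        mined = mine_slide(_ConstantModel(0.5), negative_slide, config, tiles)
        assert [t for t, _ in mined] == tiles[: config.k]

    def test_annotated_slide_restricted(self, positive_slide):
        config = sm.TrainingConfig(tile_size=64, magnification=20)
        mask = sm.detect_tissue(positive_slide, config.otsu_downsample)
        tiles = sm.enumerate_tiles(mask, 64, 32, 0.1, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        mined = mine_slide(sm.build_backbone("tiny-test-cnn", 64, seed=0),
                           positive_slide, config, tiles)
        from slideminer.sampling import points_in_any_polygon

        centers = np.array([[t.x + 32, t.y + 32] for t, _ in mined], float)
        assert points_in_any_polygon(centers, positive_slide.annotations).all()
        assert all(label == 1 for _, label in mined)

    def test_empty_tile_list_skipped_with_warning(self, negative_slide, caplog):
        config = sm.TrainingConfig(tile_size=64, magnification=20)
        with caplog.at_level("WARNING"):
            assert mine_slide(_ConstantModel(0.5), negative_slide, config, []) == []
        assert "skipped" in caplog.text


class TestRunTraining:
    def _tiny_dataset(self):
        spec = sm.SyntheticSpec(slide_width=256, slide_height=256, seed=21)
        train, _ = sm.generate_dataset(spec, 3, 3, seed=1, split="train")
        val, _ = sm.generate_dataset(spec, 2, 2, seed=2, split="val")
        return train, val

    def test_overlapping_manifests_rejected(self):
        train, _ = self._tiny_dataset()
        config = sm.TrainingConfig(tile_size=64, magnification=20, max_epochs=1)
        with pytest.raises(ValueError, match="overlap"):
            sm.run_training(train, train, config)

    def test_random_phase_only_never_mines(self):
        train, val = self._tiny_dataset()
        config = sm.TrainingConfig(tile_size=64, magnification=20, max_epochs=2,
                                   random_phase_epochs=2, seed=3)
        _, history = sm.run_training(train, val, config)
        assert (history["phase"] == "random").all()
        assert (history["passes"] == 0).all()

    def test_history_schema_and_determinism(self):
        train, val = self._tiny_dataset()
        config = sm.TrainingConfig(tile_size=64, magnification=20, max_epochs=2,
                                   N=32, random_phase_epochs=1, seed=3)
        _, h1 = sm.run_training(train, val, config)
        _, h2 = sm.run_training(train, val, config)
        assert list(h1.columns) == ["epoch", "phase", "lr", "train_loss", "val_loss",
                                    "val_auc", "passes"]
        assert h1.equals(h2)

    def test_mining_phase_triggers_passes(self):
        train, val = self._tiny_dataset()
        config = sm.TrainingConfig(tile_size=64, magnification=20, max_epochs=3,
                                   N=32, k=4, random_phase_epochs=1, seed=4)
        _, history = sm.run_training(train, val, config)
        assert history["passes"].iloc[-1] >= 1
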