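"""Shared fixtures: synthetic slide populations and one end-to-end training run."""

from __future__ import annotations

import numpy as np
import pytest

import slideminer as sm


@pytest.fixture(scope="session")
def small_spec() -> sm.SyntheticSpec:
    """Compact slide geometry used across the suite: 320 px slides, x20 scan."""
    return sm.SyntheticSpec(slide_width=320, slide_height=320, seed=11)


@pytest.fixture(scope="session")
def positive_slide(small_spec) -> sm.SlideRecord:
    return sm.generate_slide(small_spec, label=1, seed=1, annotate=True)


@pytest.fixture(scope="session")
def negative_slide(small_spec) -> sm.SlideRecord:
    return sm.generate_slide(small_spec, label=0, seed=7)


def make_records(n_pos: int, n_neg: int) -> list[sm.SlideRecord]:
    """Imageless records for queue/bookkeeping tests."""
    recs = [
        sm.SlideRecord(slide_id=f"p{i}", image_path=None, scan_magnification=20, label=1)
        for i in range(n_pos)
    ]
    recs += [
        sm.SlideRecord(slide_id=f"n{i}", image_path=None, scan_magnification=20, label=0)
        for i in range(n_neg)
    ]
    return recs


@pytest.fixture(scope="session")
def trained_pipeline(small_spec):
    """One full weakly-supervised training run on a 40-slide synthetic dataset.

    12+12 training, 4+4 validation, 4+4 held-out test slides with separable
    lesion texture; tiny-test-cnn backbone at tile size 64, reference
    optimizer schedule (k=4, N=256, batch 32, Adam 0.001 with 0.95/2-epoch
    decay) and early stopping.  Shared by the end-to-end behaviour tests.
    """
    train, _ = sm.generate_dataset(small_spec, 12, 12, seed=1, split="train")
    val, _ = sm.generate_dataset(small_spec, 4, 4, seed=2, split="val")
    test, _ = sm.generate_dataset(small_spec, 4, 4, seed=3, split="test")
    config = sm.TrainingConfig(
        tile_size=64,
        magnification=20,
        random_phase_epochs=1,
        max_epochs=20,
        seed=0,
    )
    model, history = sm.run_training(train, val, config)
    return {
        "model": model,
        "history": history,
        "config": config,
        "train": train,
        "val": val,
        "test": test,
    }
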