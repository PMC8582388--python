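"""Two-phase weakly-supervised training: balanced sampling, then hard mining.

Phase 1 warms the classifier up on randomly sampled, label-balanced tile
batches drawn through the alternating slide queue.  Phase 2 alternates
between frozen-model inference and training: the model scores every
candidate tile of each slide, the k highest-probability tiles are selected
(on a negative slide these are the model's current false positives) and
placed in a training subset; once the subset reaches N tiles a training
pass of N/batch_size batches is triggered.  Tile labels inherit the slide
label throughout — no pixel-level supervision is used.

Defaults follow the reference protocol: k=4, N=256, batch size 32, Adam
with learning rate 0.001 (beta1 0.9, beta2 0.999) decayed by 0.95 every 2
epochs, binary cross-entropy loss, early stopping after 10 epochs without
validation-loss improvement, and the lowest-validation-loss checkpoint as
the final model.  Validation loss is slide-level binary cross entropy on
the max-tile probability, matching the decision rule used at test time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelContract, TinyCNN, apply_partial_finetuning
from .sampling import build_queue, next_balanced_pair, restrict_to_annotations, sample_tiles
from .synthetic import SlideRecord
from .tiling import TileCoord, detect_tissue, enumerate_tiles, extract_tile
from .inference import ProbabilityMap, predict_tiles

__all__ = [
    "TrainingConfig",
    "MiningState",
    "EarlyStopper",
    "select_top_k",
    "mine_slide",
    "accumulate",
    "learning_rate_at",
    "update_early_stopper",
    "run_training",
]

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-7  # probabilities clipped to [PROB_CLIP, 1 - PROB_CLIP] before log loss


@dataclass
class TrainingConfig:
    """Hyper-parameters of the two-phase training procedure."""

    k: int = 4
    N: int = 256
    batch_size: int = 32
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay: float = 0.95
    lr_decay_every: int = 2
    patience: int = 10
    random_phase_epochs: int = 1
    max_epochs: int = 100
    tile_size: int = 512
    magnification: int = 10
    min_tissue_fraction: float = 0.1
    otsu_downsample: int = 32
    backbone: str = "tiny-test-cnn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % self.batch_size:
            raise ValueError(f"N={self.N} must be a multiple of batch_size={self.batch_size}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class MiningState:
    """Accumulator of mined tiles awaiting a training trigger."""

    N: int
    pending: list[tuple[str, TileCoord, int]] = field(default_factory=list)
    passes_triggered: int = 0


@dataclass
class EarlyStopper:
    """Stop when the validation loss has not improved for ``patience`` epochs.

    Improvement means strictly lower loss; ties keep the earlier epoch as
    best.  NaN losses never count as improvement.
    """

    patience: int
    best_loss: float = math.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    _epoch: int = 0

    def update(self, val_loss: float) -> str:
        epoch = self._epoch
        self._epoch += 1
        if math.isnan(val_loss):
            logger.warning("validation loss is NaN at epoch %d; treated as no improvement", epoch)
            improved = False
        else:
            improved = val_loss < self.best_loss
        if improved:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.epochs_since_improvement = 0
            return "continue"
        self.epochs_since_improvement += 1
        return "stop" if self.epochs_since_improvement >= self.patience else "continue"


def update_early_stopper(stopper: EarlyStopper, val_loss: float) -> str:
    return stopper.update(val_loss)


def learning_rate_at(epoch: int, config: TrainingConfig) -> float:
    """Step-decayed learning rate: base * decay^floor(epoch / every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)


def select_top_k(probmap: ProbabilityMap, k: int) -> list[TileCoord]:
    """The k highest-probability tiles (all if fewer), ties row-major first."""
    if len(probmap) == 0:
        raise ValueError(f"slide {probmap.slide_id}: empty probability map")
    order = np.lexsort(
        (
            [t.x for t in probmap.tiles],
            [t.y for t in probmap.tiles],
            -probmap.probabilities,
        )
    )
    return [probmap.tiles[i] for i in order[:k]]


def mine_slide(
    model: ModelContract,
    slide: SlideRecord,
    config: TrainingConfig,
    tiles: list[TileCoord],
    batch_size: int | None = None,
) -> list[tuple[TileCoord, int]]:
    """Frozen-model inference over a slide's candidate tiles, then top-k.

    Candidates of an annotated positive slide are restricted to the
    annotated regions, consistent with the sampling rule.  Every returned
    tile carries the slide label (on negatives: the model's current false
    positives).  A slide with zero candidate tiles is skipped with a
    warning.
    """
    candidates = restrict_to_annotations(slide, tiles) if slide.annotated else tiles
    if not candidates:
        logger.warning("slide %s has no tissue tiles; skipped in mining", slide.slide_id)
        return []
    probs = predict_tiles(model, slide, candidates, batch_size or config.batch_size)
    probmap = ProbabilityMap(
        slide_id=slide.slide_id,
        tiles=candidates,
        probabilities=probs,
        tile_size=config.tile_size,
        stride=config.tile_size // 2,
        magnification=config.magnification,
    )
    return [(t, slide.label) for t in select_top_k(probmap, config.k)]


def accumulate(
    state: MiningState, tiles: list[tuple[str, TileCoord, int]]
) -> list[list[tuple[str, TileCoord, int]]]:
    """Append mined tiles; emit training jobs of exactly N tiles on overflow.

    Each emitted job holds the oldest N pending tiles; the remainder is
    carried over, so total tiles consumed by training equals
    N * passes_triggered.
    """
    state.pending.extend(tiles)
    jobs = []
    while len(state.pending) >= state.N:
        jobs.append(state.pending[: state.N])
        state.pending = state.pending[state.N :]
        state.passes_triggered += 1
    return jobs


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _tile_cache(
    manifest: list[SlideRecord], config: TrainingConfig
) -> dict[str, list[TileCoord]]:
    cache = {}
    for rec in manifest:
        mask = detect_tissue(rec, config.otsu_downsample)
        h, w = rec.load_image().shape[:2]
        cache[rec.slide_id] = enumerate_tiles(
            mask,
            config.tile_size,
            config.tile_size // 2,
            config.min_tissue_fraction,
            magnification=config.magnification,
            scan_magnification=rec.scan_magnification,
            slide_shape=(h, w),
        )
    return cache


def _train_batch(
    model: ModelContract,
    records: dict[str, SlideRecord],
    entries: list[tuple[str, TileCoord, int]],
    rate: float,
) -> float:
    batch = np.stack([extract_tile(records[sid], t) for sid, t, _ in entries])
    labels = np.array([lab for _, _, lab in entries], dtype=float)
    return model.train_step(batch, labels, rate)


def _validate(
    model: ModelContract,
    manifest: list[SlideRecord],
    cache: dict[str, list[TileCoord]],
    config: TrainingConfig,
) -> tuple[float, float]:
    """Slide-level validation: BCE on max-tile probability, plus ROC AUC."""
    from .evaluation import log_loss, roc_auc

    labels, scores = [], []
    for rec in manifest:
        tiles = cache[rec.slide_id]
        if not tiles:
            scores.append(0.0)
        else:
            probs = predict_tiles(model, rec, tiles, config.batch_size)
            scores.append(float(probs.max()))
        labels.append(rec.label)
    loss = log_loss(labels, scores)
    try:
        auc = roc_auc(labels, scores)
    except ValueError:
        logger.warning("validation set is single-class; AUC undefined")
        auc = float("nan")
    return loss, auc


def run_training(
    train_manifest: list[SlideRecord],
    val_manifest: list[SlideRecord],
    config: TrainingConfig,
    model: ModelContract | None = None,
) -> tuple[ModelContract, pd.DataFrame]:
    """Full two-phase training with early stopping and best-checkpoint return.

    Runs ``random_phase_epochs`` of balanced random tile sampling, then
    hard-mining epochs until early stopping (or ``max_epochs``).  The
    returned model is restored to the lowest-validation-loss checkpoint.
    History columns: epoch, phase, lr, train_loss, val_loss, val_auc,
    passes (cumulative mining passes).
    """
    overlap = {r.slide_id for r in train_manifest} & {r.slide_id for r in val_manifest}
    if overlap:
        raise ValueError(f"train and validation manifests overlap: {sorted(overlap)[:5]}")

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    if model is None:
        model = TinyCNN(input_size=config.tile_size, seed=int(seeds[0].generate_state(1)[0]) % 2**31)
        apply_partial_finetuning(model)
        model.beta1, model.beta2 = config.beta1, config.beta2

    records = {r.slide_id: r for r in train_manifest}
    queue = build_queue(train_manifest, seed=int(seeds[1].generate_state(1)[0]) % 2**31)
    sample_rng = np.random.default_rng(seeds[2])
    shuffle_rng = np.random.default_rng(seeds[3])

    train_tiles = _tile_cache(train_manifest, config)
    val_tiles = _tile_cache(val_manifest, config)

    mining = MiningState(N=config.N)
    stopper = EarlyStopper(patience=config.patience)
    history: list[dict] = []
    best_state: dict | None = None
    pairs_per_epoch = len(queue.epoch_sequence) // 2

    for epoch in range(config.max_epochs):
        rate = learning_rate_at(epoch, config)
        phase = "random" if epoch < config.random_phase_epochs else "mining"
        losses: list[float] = []

        if phase == "random":
            half = config.batch_size // 2
            for _ in range(pairs_per_epoch):
                pos, neg = next_balanced_pair(queue)
                entries: list[tuple[str, TileCoord, int]] = []
                for rec in (pos, neg):
                    tiles = train_tiles[rec.slide_id]
                    if not tiles:
                        logger.warning("slide %s has no tissue tiles; skipped", rec.slide_id)
                        break
                    chosen = sample_tiles(rec, half, tiles, sample_rng)
                    entries += [(rec.slide_id, t, rec.label) for t in chosen]
                if len(entries) == config.batch_size:
                    losses.append(_train_batch(model, records, entries, rate))
        else:
            for _ in range(pairs_per_epoch):
                pos, neg = next_balanced_pair(queue)
                for rec in (pos, neg):
                    mined = mine_slide(model, rec, config, train_tiles[rec.slide_id])
                    jobs = accumulate(mining, [(rec.slide_id, t, lab) for t, lab in mined])
                    for job in jobs:
                        job = [job[i] for i in shuffle_rng.permutation(len(job))]
                        for s in range(0, len(job), config.batch_size):
                            losses.append(
                                _train_batch(
                                    model, records, job[s : s + config.batch_size], rate
                                )
                            )

        val_loss, val_auc = _validate(model, val_manifest, val_tiles, config)
        history.append(
            {
                "epoch": epoch,
                "phase": phase,
                "lr": rate,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "val_loss": val_loss,
                "val_auc": val_auc,
                "passes": mining.passes_triggered,
            }
        )
        decision = stopper.update(val_loss)
        if stopper.best_epoch == epoch and isinstance(model, TinyCNN):
            best_state = model.state_dict()
        logger.info(
            "epoch %d [%s] lr=%.5g train=%.4f val=%.4f auc=%s",
            epoch, phase, rate, history[-1]["train_loss"], val_loss, val_auc,
        )
        if decision == "stop":
            break

    if best_state is not None and isinstance(model, TinyCNN):
        model.load_state_dict(best_state)
    return model, pd.DataFrame(history)
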