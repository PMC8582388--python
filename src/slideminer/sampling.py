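"""Balanced slide queue and tile sampling for weakly-supervised training.

The training procedure draws slides from a shuffled queue that alternates
between positive and negative labels, oversampling the minority class so
that every slide is seen at least once per epoch.  From each slide of a
pair, half a batch of tiles is sampled uniformly — restricted to the
loosely annotated regions when the slide carries annotations — so every
training batch is exactly label-balanced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from .synthetic import SlideRecord
from .tiling import TileCoord

__all__ = [
    "QueueState",
    "build_queue",
    "next_balanced_pair",
    "sample_tiles",
    "points_in_any_polygon",
    "restrict_to_annotations",
]


def points_in_any_polygon(points: np.ndarray, polygons: list[np.ndarray]) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test against a polygon list.

    ``points`` is (n, 2) as (x, y); each polygon is an (m, 2) vertex ring.
    Returns a boolean mask, True where the point lies inside at least one
    polygon.
    """
    pts = np.asarray(points, dtype=float)
    inside_any = np.zeros(len(pts), dtype=bool)
    for poly in polygons:
        v = np.asarray(poly, dtype=float)
        x0, y0 = v[:, 0], v[:, 1]
        x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
        inside = np.zeros(len(pts), dtype=bool)
        px, py = pts[:, 0][:, None], pts[:, 1][:, None]
        # edge straddles the horizontal ray through the point
        cond = (y0[None, :] > py) != (y1[None, :] > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0[None, :] + (py - y0[None, :]) / (y1 - y0)[None, :] * (x1 - x0)[None, :]
        crossings = (cond & (px < xint)).sum(axis=1)
        inside = crossings % 2 == 1
        inside_any |= inside
    return inside_any


@dataclass
class QueueState:
    """Label-alternating epoch sequence over a training manifest."""

    positives: list[str]
    negatives: list[str]
    records: dict[str, SlideRecord]
    rng_seed: int
    epoch_index: int = 0
    cursor: int = 0
    epoch_sequence: list[str] = field(default_factory=list)

    def _reshuffle(self) -> None:
        """Build this epoch's alternating sequence with minority oversampling."""
        rng = np.random.default_rng(np.random.SeedSequence([self.rng_seed, self.epoch_index]))
        n_pos, n_neg = len(self.positives), len(self.negatives)
        n = max(n_pos, n_neg)

        def expanded(ids: list[str]) -> list[str]:
            reps = ceil(n / len(ids))
            tiled = (ids * reps)[:n]
            return [tiled[i] for i in rng.permutation(n)]

        pos, neg = expanded(self.positives), expanded(self.negatives)
        seq: list[str] = []
        for p, q in zip(pos, neg):
            seq.extend([p, q])
        self.epoch_sequence = seq
        self.cursor = 0

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rng_seed": self.rng_seed,
                    "epoch_index": self.epoch_index,
                    "cursor": self.cursor,
                    "epoch_sequence": self.epoch_sequence,
                }
            )
        )


def build_queue(manifest: list[SlideRecord], seed: int) -> QueueState:
    """Initialize the alternating queue from a training manifest.

    The minority class is repeated ceil(majority/minority) times then
    truncated to the majority count, so strict (positive, negative)
    alternation exhausts both lists and every slide appears at least once
    per epoch.  A single-class manifest is an error: balanced batches are
    impossible.
    """
    positives = [r.slide_id for r in manifest if r.label == 1]
    negatives = [r.slide_id for r in manifest if r.label == 0]
    if not positives or not negatives:
        raise ValueError(
            f"queue needs both labels: {len(positives)} positive, "
            f"{len(negatives)} negative slides in manifest"
        )
    state = QueueState(
        positives=positives,
        negatives=negatives,
        records={r.slide_id: r for r in manifest},
        rng_seed=seed,
    )
    state._reshuffle()
    return state


def next_balanced_pair(queue: QueueState) -> tuple[SlideRecord, SlideRecord]:
    """Next (positive, negative) slide pair, wrapping to a new epoch when spent."""
    if queue.cursor >= len(queue.epoch_sequence):
        queue.epoch_index += 1
        queue._reshuffle()
    pos_id = queue.epoch_sequence[queue.cursor]
    neg_id = queue.epoch_sequence[queue.cursor + 1]
    queue.cursor += 2
    return queue.records[pos_id], queue.records[neg_id]


def restrict_to_annotations(
    slide: SlideRecord, tiles: list[TileCoord]
) -> list[TileCoord]:
    """Tiles whose center lies inside any annotation polygon of the slide.

    Unannotated slides pass through unchanged.  Centers are computed on the
    level-0 footprint of each tile.  An annotated slide whose polygons
    intersect no tile center is a data problem and raises.
    """
    if not slide.annotated:
        return tiles
    if not tiles:
        return tiles
    factor = slide.scan_magnification // tiles[0].magnification
    half = tiles[0].tile_size * factor / 2.0
    centers = np.array([[t.x + half, t.y + half] for t in tiles], dtype=float)
    keep = points_in_any_polygon(centers, slide.annotations)
    kept = [t for t, k in zip(tiles, keep) if k]
    if not kept:
        raise ValueError(
            f"slide {slide.slide_id}: annotations intersect zero tile centers"
        )
    return kept


def sample_tiles(
    slide: SlideRecord,
    n: int,
    tiles: list[TileCoord],
    rng: np.random.Generator,
) -> list[TileCoord]:
    """Uniformly sample ``n`` tiles from a slide's candidate tiles.

    Annotated slides are restricted to tiles whose centers fall inside the
    annotation polygons; otherwise the whole tissue tile list is the
    candidate set.  Sampling is without replacement when enough candidates
    exist, with replacement otherwise.
    """
    candidates = restrict_to_annotations(slide, tiles)
    if not candidates:
        raise ValueError(f"slide {slide.slide_id}: no candidate tiles to sample")
    replace = n > len(candidates)
    idx = rng.choice(len(candidates), size=n, replace=replace)
    return [candidates[i] for i in idx]
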