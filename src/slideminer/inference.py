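"""Sliding-window slide inference, max-tile aggregation, and heatmaps.

A trained tile classifier is applied to every tissue tile of a slide; the
slide-level probability is the maximum over tile probabilities (a slide is
as suspicious as its most suspicious tile).  Probability maps can be
rendered as heatmaps where overlapping tiles composite by pixel-wise
maximum, matching the slide-level rule, and are also serialized as plain
CSV grids for exact round-tripping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelContract
from .synthetic import SlideRecord
from .tiling import (
    DEFAULT_MIN_TISSUE_FRACTION,
    DEFAULT_OTSU_DOWNSAMPLE,
    TileCoord,
    detect_tissue,
    enumerate_tiles,
    extract_tile,
)

__all__ = [
    "ProbabilityMap",
    "SlidePrediction",
    "predict_tiles",
    "predict_slide",
    "aggregate_slide",
    "render_heatmap",
    "probability_map_to_frame",
    "probability_map_from_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ProbabilityMap:
    """Per-tile positive-class probabilities over a slide's tile grid."""

    slide_id: str
    tiles: list[TileCoord]
    probabilities: np.ndarray
    tile_size: int
    stride: int
    magnification: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.tiles) != len(self.probabilities):
            raise ValueError("one probability per tile required")
        if len(self.probabilities) and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass
class SlidePrediction:
    slide_id: str
    probability: float
    argmax_tile: TileCoord | None
    n_tiles: int
    flags: list[str] = field(default_factory=list)


def predict_tiles(
    model: ModelContract,
    slide: SlideRecord,
    tiles: list[TileCoord],
    batch_size: int = 32,
) -> np.ndarray:
    """Model probabilities for an explicit tile list (batched internally).

    The inference batch size is an implementation detail: outputs are
    identical (to float tolerance) for any batching.
    """
    probs = np.empty(len(tiles), dtype=float)
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start : start + batch_size]
        batch = np.stack([extract_tile(slide, t) for t in chunk])
        probs[start : start + len(chunk)] = model.predict_proba(batch)
    return probs


def predict_slide(
    model: ModelContract,
    slide: SlideRecord,
    tile_size: int,
    magnification: int,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
    otsu_downsample: int = DEFAULT_OTSU_DOWNSAMPLE,
    batch_size: int = 32,
    tiles: list[TileCoord] | None = None,
) -> ProbabilityMap:
    """Sliding-window inference over all tissue tiles of a slide.

    Stride is half the tile size.  A precomputed tile list may be supplied
    to skip tissue detection.  A slide with zero tissue tiles yields an
    empty map (scored 0 downstream, flagged).
    """
    stride = tile_size // 2
    if tiles is None:
        mask = detect_tissue(slide, otsu_downsample)
        h, w = slide.load_image().shape[:2]
        tiles = enumerate_tiles(
            mask,
            tile_size,
            stride,
            min_tissue_fraction,
            magnification=magnification,
            scan_magnification=slide.scan_magnification,
            slide_shape=(h, w),
        )
    probs = predict_tiles(model, slide, tiles, batch_size) if tiles else np.array([])
    return ProbabilityMap(
        slide_id=slide.slide_id,
        tiles=tiles,
        probabilities=probs,
        tile_size=tile_size,
        stride=stride,
        magnification=magnification,
    )


def aggregate_slide(probmap: ProbabilityMap) -> SlidePrediction:
    """Slide probability = max over tiles; the first row-major argmax tile.

    An empty map (no tissue) scores 0 and is flagged ``no-tissue`` rather
    than raising, so evaluation over a manifest never aborts.
    """
    if len(probmap) == 0:
        logger.warning("slide %s has no tissue tiles; scored 0", probmap.slide_id)
        return SlidePrediction(probmap.slide_id, 0.0, None, 0, flags=["no-tissue"])
    order = np.lexsort(
        (
            [t.x for t in probmap.tiles],
            [t.y for t in probmap.tiles],
            -probmap.probabilities,
        )
    )
    best = order[0]
    return SlidePrediction(
        slide_id=probmap.slide_id,
        probability=float(probmap.probabilities[best]),
        argmax_tile=probmap.tiles[best],
        n_tiles=len(probmap),
    )


def probability_map_to_frame(probmap: ProbabilityMap) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slide_id": probmap.slide_id,
            "x": [t.x for t in probmap.tiles],
            "y": [t.y for t in probmap.tiles],
            "tile_size": probmap.tile_size,
            "magnification": probmap.magnification,
            "probability": probmap.probabilities,
        }
    )


def probability_map_from_frame(frame: pd.DataFrame) -> ProbabilityMap:
    if frame.empty:
        raise ValueError("empty probability grid")
    tile_size = int(frame["tile_size"].iloc[0])
    magnification = int(frame["magnification"].iloc[0])
    tiles = [
        TileCoord(int(r.x), int(r.y), tile_size, magnification)
        for r in frame.itertuples(index=False)
    ]
    return ProbabilityMap(
        slide_id=str(frame["slide_id"].iloc[0]),
        tiles=tiles,
        probabilities=frame["probability"].to_numpy(),
        tile_size=tile_size,
        stride=tile_size // 2,
        magnification=magnification,
    )


def render_heatmap(
    probmap: ProbabilityMap,
    slide: SlideRecord,
    downsample: int = 8,
    colormap: str = "inferno",
):
    """Per-pixel probability heatmap at a stated downsample.

    Overlapping tiles composite by pixel-wise maximum, consistent with the
    max-tile slide score.  Returns ``(heat, rgba)`` — the raw float grid
    and its fixed-colormap rendering; callers persist the grid CSV via
    :func:`probability_map_to_frame` for exact testing.
    """
    h0, w0 = slide.load_image().shape[:2]
    h, w = int(np.ceil(h0 / downsample)), int(np.ceil(w0 / downsample))
    heat = np.zeros((h, w), dtype=float)
    factor = slide.scan_magnification // probmap.magnification if len(probmap) else 1
    for tile, p in zip(probmap.tiles, probmap.probabilities):
        size0 = tile.tile_size * factor
        r0, r1 = tile.y // downsample, int(np.ceil((tile.y + size0) / downsample))
        c0, c1 = tile.x // downsample, int(np.ceil((tile.x + size0) / downsample))
        region = heat[r0:r1, c0:c1]
        np.maximum(region, p, out=region)
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    rgba = (cmap(heat) * 255).astype(np.uint8)
    return heat, rgba
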