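"""Otsu tissue detection and sliding-window tile enumeration.

Tissue is found by thresholding a grayscale thumbnail with Otsu's method —
tissue is darker than the near-white slide background — and fixed-size
tiles are then enumerated over the tissue regions on a regular grid whose
stride is, by convention, half the tile size.

Coordinates are 0-based level-0 pixels, x = column, y = row; a tile covers
the half-open square [x, x+S) x [y, y+S) at level 0, where S is the tile
size scaled to level 0 (tile_size * scan_mag / working_mag).  Tiles that
would extend past the slide are dropped, not padded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import downscale_local_mean

from .synthetic import SlideRecord

__all__ = [
    "TissueMask",
    "TileCoord",
    "otsu_threshold",
    "detect_tissue",
    "enumerate_tiles",
    "extract_tile",
    "grayscale",
]

logger = logging.getLogger(__name__)

#: fixed luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])

#: thumbnail downsample at which Otsu runs by default
DEFAULT_OTSU_DOWNSAMPLE = 32

#: default minimum tissue fraction for a tile to be kept
DEFAULT_MIN_TISSUE_FRACTION = 0.1


@dataclass(frozen=True)
class TileCoord:
    """Position of one tile on the level-0 grid.

    ``x``/``y`` are level-0 offsets, multiples of the level-0 stride;
    ``tile_size`` is the side length in pixels at the working
    ``magnification``.
    """

    x: int
    y: int
    tile_size: int
    magnification: int


@dataclass
class TissueMask:
    """Binary tissue grid at ``downsample_factor`` relative to level 0."""

    mask: np.ndarray
    downsample_factor: int
    threshold: float | None = None
    degenerate: bool = False

    @property
    def tissue_area_level0(self) -> float:
        return float(self.mask.sum()) * self.downsample_factor**2


def grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance grayscale (float) of an RGB array; passthrough if single-channel."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 2:
        return arr
    return arr[..., :3] @ _LUMA


def otsu_threshold(histogram: np.ndarray) -> tuple[float, bool]:
    """Gray-level threshold maximizing between-class variance.

    Evaluates all 256 cut points t (class 0 = bins 0..t, class 1 = bins
    t+1..255) and returns the midpoint of the plateau of maximizing cuts,
    so exactly-tied histograms (e.g. two delta masses) threshold midway
    between the modes.  Returns ``(threshold, degenerate)`` where
    ``degenerate`` flags a histogram concentrated in a single bin (no
    separation exists; the bin itself is returned).
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {h.shape}")
    if h.sum() <= 0:
        raise ValueError("histogram has no counts")
    nonzero = np.flatnonzero(h)
    if len(nonzero) == 1:
        return float(nonzero[0]), True

    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(h)
    total = w0[-1]
    mu_cum = np.cumsum(h * levels)
    mu_total = mu_cum[-1]
    w1 = total - w0
    # between-class variance at each cut t (class split after bin t)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)  # cut at 255 leaves class 1 empty
    best = sigma_b.max()
    plateau = np.flatnonzero(np.isclose(sigma_b, best, rtol=0, atol=best * 1e-12))
    t = (plateau[0] + plateau[-1]) / 2.0
    return float(t), False


def detect_tissue(
    slide: SlideRecord,
    downsample_factor: int = DEFAULT_OTSU_DOWNSAMPLE,
    min_object_px: int = 0,
) -> TissueMask:
    """Binary tissue mask from Otsu thresholding on a grayscale thumbnail.

    Pixels darker than the Otsu threshold are tissue (1); a degenerate
    histogram (all-background slide) yields an empty mask.  Small
    connected components below ``min_object_px`` thumbnail pixels are
    optionally removed.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    img = slide.load_image()
    gray = grayscale(img)
    if downsample_factor > 1:
        gray = downscale_local_mean(gray, (downsample_factor, downsample_factor))
        h0, w0 = img.shape[:2]
        gray = gray[
            : int(np.ceil(h0 / downsample_factor)), : int(np.ceil(w0 / downsample_factor))
        ]
    hist, _ = np.histogram(np.clip(gray, 0, 255), bins=256, range=(0, 256))
    thr, degenerate = otsu_threshold(hist)
    if degenerate:
        mask = np.zeros(gray.shape, dtype=bool)
    else:
        mask = gray < thr
    if min_object_px > 0 and mask.any():
        from skimage.morphology import remove_small_objects

        mask = remove_small_objects(mask, min_size=min_object_px)
    return TissueMask(mask=mask, downsample_factor=downsample_factor,
                      threshold=thr, degenerate=degenerate)


def enumerate_tiles(
    mask: TissueMask,
    tile_size: int,
    stride: int | None = None,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
    magnification: int | None = None,
    scan_magnification: int | None = None,
    slide_shape: tuple[int, int] | None = None,
) -> list[TileCoord]:
    """Row-major list of tissue tiles on the stride grid.

    ``tile_size`` and ``stride`` are given at the working magnification
    (stride defaults to half the tile size); both are mapped to level 0
    through scan_magnification / magnification.  A tile is kept iff its
    level-0 footprint's tissue fraction is >= ``min_tissue_fraction`` and
    the footprint lies entirely inside the slide.
    """
    if stride is None:
        stride = tile_size // 2
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if tile_size < stride:
        raise ValueError("tile_size must be >= stride")
    magnification = magnification or scan_magnification or 20
    scan_magnification = scan_magnification or magnification
    if scan_magnification % magnification:
        raise ValueError(
            f"scan magnification {scan_magnification} is not an integer multiple "
            f"of working magnification {magnification}"
        )
    factor = scan_magnification // magnification
    size0 = tile_size * factor  # tile side at level 0
    stride0 = stride * factor

    ds = mask.downsample_factor
    if slide_shape is None:
        slide_shape = (mask.mask.shape[0] * ds, mask.mask.shape[1] * ds)
    h0, w0 = slide_shape
    if size0 > h0 or size0 > w0:
        warnings.warn(f"tile size {size0} exceeds slide bounds {slide_shape}", stacklevel=2)
        return []

    m = mask.mask.astype(np.int64)
    # integral image for O(1) tissue-fraction queries per tile
    integ = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    integ[1:, 1:] = m.cumsum(0).cumsum(1)

    tiles: list[TileCoord] = []
    for y in range(0, h0 - size0 + 1, stride0):
        for x in range(0, w0 - size0 + 1, stride0):
            r0, r1 = y / ds, (y + size0) / ds
            c0, c1 = x / ds, (x + size0) / ds
            ri0, ri1 = int(np.floor(r0)), min(int(np.ceil(r1)), m.shape[0])
            ci0, ci1 = int(np.floor(c0)), min(int(np.ceil(c1)), m.shape[1])
            area = (ri1 - ri0) * (ci1 - ci0)
            if area <= 0:
                continue
            tissue = integ[ri1, ci1] - integ[ri0, ci1] - integ[ri1, ci0] + integ[ri0, ci0]
            if tissue / area >= min_tissue_fraction:
                tiles.append(TileCoord(x=x, y=y, tile_size=tile_size,
                                       magnification=magnification))
    return tiles


def extract_tile(slide: SlideRecord, coord: TileCoord) -> np.ndarray:
    """Pixel content of one tile at its working magnification, float in [0, 1].

    For a working magnification below the scan magnification the level-0
    region of side tile_size * (scan/working) is block-mean downsampled to
    tile_size (deterministic).  Out-of-bounds coordinates are an error; no
    implicit padding.
    """
    img = slide.load_image()
    scan = slide.scan_magnification
    if scan % coord.magnification:
        raise ValueError(
            f"scan magnification {scan} not an integer multiple of {coord.magnification}"
        )
    factor = scan // coord.magnification
    size0 = coord.tile_size * factor
    h0, w0 = img.shape[:2]
    if coord.x < 0 or coord.y < 0 or coord.x + size0 > w0 or coord.y + size0 > h0:
        raise ValueError(
            f"tile at ({coord.x}, {coord.y}) size {size0} out of bounds for "
            f"slide {slide.slide_id} ({w0}x{h0})"
        )
    region = img[coord.y : coord.y + size0, coord.x : coord.x + size0].astype(float)
    if factor > 1:
        region = downscale_local_mean(region, (factor, factor, 1))
    return region / 255.0


def tiles_to_frame(slide_id: str, tiles: list[TileCoord]):
    """Serialize a tile list to a DataFrame (slide_id, x, y, tile_size, magnification)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "x": [t.x for t in tiles],
            "y": [t.y for t in tiles],
            "tile_size": [t.tile_size for t in tiles],
            "magnification": [t.magnification for t in tiles],
        }
    )
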