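"""Synthetic whole-slide generator with planted lesions and loose annotations.

Emulates the statistical structure a weakly-supervised slide classifier is
trained on: near-white background, irregular darker tissue regions, and —
on positive slides — lesion regions of a visually distinct texture planted
inside the tissue.  Benign tissue is smooth, low-contrast correlated noise;
lesions are higher-contrast, higher-frequency texture, so the two are
separable by simple local statistics and learnable by a small CNN.

A configurable fraction of positive slides carries loose polygon
annotations: convex hulls of the lesion components dilated by a stromal
margin, mirroring pathologist annotations that include some adjacent
stroma.  Negative slides get benign-subtype tags (for confusion
breakdowns) drawn from categorical weights.

Everything is deterministic for a fixed (spec, label, seed) triple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

__all__ = ["SyntheticSpec", "SlideRecord", "generate_slide", "generate_dataset", "load_manifest"]

#: default benign subtypes and their manifest weights, fibroadenoma-dominant
#: as in core-needle-biopsy benign caseloads
DEFAULT_SUBTYPE_WEIGHTS = {
    "fibroadenoma": 0.5,
    "mastopathy": 0.3,
    "normal": 0.2,
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic slide population.

    ``lesion_fraction`` is the fraction of tissue area covered by lesion on
    positive slides; ``annotate_fraction`` the fraction of positive slides
    that receive loose polygon annotations; ``annotation_dilation`` the
    stromal margin (pixels) added around each lesion component's convex
    hull; ``annotation_coverage_min`` the minimum fraction of lesion pixels
    the polygons must cover (a generator invariant, checked at build time).
    """

    slide_width: int = 512
    slide_height: int = 512
    n_tissue_blobs: int = 2
    background_intensity: float = 245.0
    tissue_mean: float = 185.0
    tissue_noise_sd: float = 6.0
    tissue_smoothing: float = 6.0
    lesion_mean: float = 150.0
    lesion_noise_sd: float = 35.0
    lesion_smoothing: float = 1.0
    lesion_fraction: float = 0.25
    annotate_fraction: float = 0.5
    annotation_dilation: int = 12
    annotation_coverage_min: float = 0.95
    subtype_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_WEIGHTS)
    )
    scan_magnification: int = 20
    seed: int = 0


@dataclass
class SlideRecord:
    """One slide: image reference, label, and optional weak supervision."""

    slide_id: str
    image_path: Path | None
    scan_magnification: int
    label: int
    subtype: str | None = None
    annotations: list[np.ndarray] | None = None
    ground_truth_lesion_mask: np.ndarray | None = None
    ground_truth_tissue_mask: np.ndarray | None = None
    _image: np.ndarray | None = None

    @property
    def annotated(self) -> bool:
        return bool(self.annotations)

    def load_image(self) -> np.ndarray:
        """Level-0 RGB pixels as uint8 (H, W, 3); cached after first read."""
        if self._image is None:
            if self.image_path is None:
                raise IOError(f"slide {self.slide_id}: no image available")
            try:
                self._image = np.asarray(iio.imread(self.image_path))
            except Exception as exc:  # noqa: BLE001 - annotate with slide_id
                raise IOError(f"slide {self.slide_id}: cannot read {self.image_path}") from exc
        return self._image


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian-correlated field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _tissue_mask(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Irregular tissue blobs via thresholded smooth noise around seed points."""
    h, w = spec.slide_height, spec.slide_width
    field = _smooth_field(rng, (h, w), sigma=min(h, w) / 10)
    # bias the field towards n_tissue_blobs random centers so blobs stay compact
    yy, xx = np.mgrid[0:h, 0:w]
    bias = np.zeros((h, w))
    radius = min(h, w) / (1.8 + spec.n_tissue_blobs * 0.4)
    for _ in range(max(1, spec.n_tissue_blobs)):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / radius**2
        bias = np.maximum(bias, np.exp(-d2))
    mask = (field * 0.35 + bias) > 0.55
    mask = ndimage.binary_closing(mask, iterations=2)
    mask = ndimage.binary_opening(mask, iterations=1)
    if not mask.any():  # degenerate draw: fall back to one central disc
        d2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / radius**2
        mask = d2 < 1.0
    return mask


def _lesion_mask(
    rng: np.random.Generator, tissue: np.ndarray, fraction: float
) -> np.ndarray:
    """Lesion = top-`fraction` quantile of a smooth field, inside tissue only."""
    field = _smooth_field(rng, tissue.shape, sigma=min(tissue.shape) / 14)
    vals = field[tissue]
    cut = np.quantile(vals, 1.0 - fraction)
    lesion = tissue & (field > cut)
    # keep only components of non-trivial size so hulls are well-defined
    labels, n = ndimage.label(lesion)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= 16) + 1
        lesion = np.isin(labels, keep)
    return lesion


def _render(
    rng: np.random.Generator, spec: SyntheticSpec, tissue: np.ndarray, lesion: np.ndarray
) -> np.ndarray:
    h, w = tissue.shape
    img = spec.background_intensity + rng.normal(0.0, 2.0, size=(h, w))
    benign = _smooth_field(rng, (h, w), spec.tissue_smoothing) * spec.tissue_noise_sd
    img[tissue] = spec.tissue_mean + benign[tissue]
    if lesion.any():
        hot = _smooth_field(rng, (h, w), spec.lesion_smoothing) * spec.lesion_noise_sd
        img[lesion] = spec.lesion_mean + hot[lesion]
    img = np.clip(img, 0, 255)
    # faint eosin-like tint keeps the RGB pathway honest without color realism
    rgb = np.stack([img, img * 0.94, img * 0.96], axis=-1)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _loose_annotations(lesion: np.ndarray, dilation: int) -> list[np.ndarray]:
    """Convex hull of each lesion component, buffered by the stromal margin.

    Polygons are simple, clipped to image bounds, in (x, y) level-0 pixel
    coordinates, 0-based.
    """
    h, w = lesion.shape
    bounds = Polygon([(0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)])
    labels, n = ndimage.label(lesion)
    polys: list[np.ndarray] = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        pts = np.column_stack([xs, ys]).astype(float)
        try:
            hull = ConvexHull(pts)
            ring = pts[hull.vertices]
        except QhullError:  # degenerate (collinear) component
            x0, x1 = xs.min(), xs.max()
            y0, y1 = ys.min(), ys.max()
            ring = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
        poly = Polygon(ring).buffer(dilation, quad_segs=4).intersection(bounds)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        polys.append(np.asarray(poly.exterior.coords[:-1], dtype=float))
    return polys


def polygon_coverage(polygons: list[np.ndarray], mask: np.ndarray) -> float:
    """Fraction of mask pixels whose centers fall inside any polygon."""
    if not mask.any():
        return 1.0
    from .sampling import points_in_any_polygon  # local import avoids a cycle

    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    return float(points_in_any_polygon(pts, polygons).mean())


def generate_slide(
    spec: SyntheticSpec,
    label: int,
    seed: int,
    slide_id: str | None = None,
    annotate: bool = False,
    out_dir: Path | None = None,
) -> SlideRecord:
    """Generate one synthetic slide, deterministically for (spec, label, seed).

    Positive slides (label 1) carry lesion texture over ``lesion_fraction``
    of the tissue; negative slides have zero lesion pixels.  If ``annotate``
    is set (positives only), loose polygons covering the lesions are
    attached.  With ``out_dir`` the image and a JSON sidecar are written;
    otherwise the record holds pixels in memory.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    if label == 1 and not (0.0 < spec.lesion_fraction <= 1.0):
        raise ValueError(
            f"lesion_fraction must be in (0, 1] for a positive slide, "
            f"got {spec.lesion_fraction}"
        )
    if min(spec.slide_width, spec.slide_height) < 4 * 32:
        raise ValueError("slide dimensions must fit at least 4 tiles of the smallest tile size")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=[spec.seed, label, seed]))
    tissue = _tissue_mask(rng, spec)
    lesion = (
        _lesion_mask(rng, tissue, spec.lesion_fraction)
        if label == 1
        else np.zeros_like(tissue)
    )
    img = _render(rng, spec, tissue, lesion)

    annotations = None
    if annotate and label == 1 and lesion.any():
        annotations = _loose_annotations(lesion, spec.annotation_dilation)
        cov = polygon_coverage(annotations, lesion)
        if cov < spec.annotation_coverage_min:
            raise AssertionError(
                f"annotation polygons cover {cov:.3f} < {spec.annotation_coverage_min} "
                "of lesion pixels"
            )

    sid = slide_id or f"slide_{label}_{seed:05d}"
    image_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        image_path = out_dir / f"{sid}.png"
        iio.imwrite(image_path, img)

    rec = SlideRecord(
        slide_id=sid,
        image_path=image_path,
        scan_magnification=spec.scan_magnification,
        label=label,
        annotations=annotations,
        ground_truth_lesion_mask=lesion,
        ground_truth_tissue_mask=tissue,
    )
    rec._image = img
    return rec


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def _write_sidecar(rec: SlideRecord) -> None:
    sidecar = {
        "slide_id": rec.slide_id,
        "scan_magnification": rec.scan_magnification,
        "label": rec.label,
        "subtype": rec.subtype,
        "annotations": [p.tolist() for p in rec.annotations] if rec.annotations else [],
    }
    _sidecar_path(rec.image_path).write_text(json.dumps(sidecar))


def generate_dataset(
    spec: SyntheticSpec,
    n_pos: int,
    n_neg: int,
    seed: int,
    out_dir: Path | None = None,
    split: str = "train",
) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Generate a labelled slide collection with a CSV manifest.

    Exactly ``round(annotate_fraction * n_pos)`` positive slides carry
    annotations; negatives get subtypes drawn from ``spec.subtype_weights``.
    When ``out_dir`` is given, images, per-slide JSON sidecars and
    ``manifest.csv`` are written there.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    if n_pos + n_neg == 0:
        raise ValueError("dataset must contain at least one slide")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=[spec.seed, seed, 2]))
    n_annot = int(round(spec.annotate_fraction * n_pos))
    annot_idx = set(rng.choice(n_pos, size=n_annot, replace=False).tolist()) if n_pos else set()

    names = list(spec.subtype_weights)
    weights = np.array([spec.subtype_weights[k] for k in names], dtype=float)
    weights = weights / weights.sum()

    records: list[SlideRecord] = []
    for i in range(n_pos):
        rec = generate_slide(
            spec, 1, seed=seed * 100_003 + i, slide_id=f"{split}_pos_{i:04d}",
            annotate=i in annot_idx, out_dir=out_dir,
        )
        records.append(rec)
    for i in range(n_neg):
        rec = generate_slide(
            spec, 0, seed=seed * 100_003 + n_pos + i,
            slide_id=f"{split}_neg_{i:04d}", out_dir=out_dir,
        )
        rec.subtype = names[rng.choice(len(names), p=weights)]
        records.append(rec)

    manifest = pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "image_path": [str(r.image_path) if r.image_path else "" for r in records],
            "label": [r.label for r in records],
            "subtype": [r.subtype or "" for r in records],
            "split": split,
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for rec in records:
            _write_sidecar(rec)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return records, manifest


def load_manifest(path: str | Path) -> list[SlideRecord]:
    """Read a manifest CSV plus per-slide JSON sidecars back into records."""
    df = pd.read_csv(Path(path), keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        image_path = Path(row.image_path)
        rec = SlideRecord(
            slide_id=row.slide_id,
            image_path=image_path,
            scan_magnification=20,
            label=int(row.label),
            subtype=row.subtype or None,
        )
        sidecar = _sidecar_path(image_path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            rec.scan_magnification = int(meta.get("scan_magnification", 20))
            polys = meta.get("annotations") or []
            rec.annotations = [np.asarray(p, dtype=float) for p in polys] or None
        records.append(rec)
    return records
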