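"""Patch tiling and three-stage quality control for whole-slide rasters.

A slide is tiled into a non-overlapping grid of fixed-size patches
(512 px at 40x; 1024 px at 20x, later downsampled by 2 to 512) and each
patch passes through a filter chain:

1. tissue     -- at least ``min_tissue_fraction`` of the patch must lie on
                 the Otsu tissue mask computed at 1/10 slide resolution;
2. background -- patches dominated by white glass (all RGB channels above
                 ``white_rgb_threshold``) are dropped;
3. saturation -- near-achromatic patches (bubbles, overexposure) are dropped
                 when mean HSV saturation over non-background pixels falls
                 below ``saturation_threshold``;
4. blur       -- out-of-focus patches are dropped when the variance of the
                 3x3 Laplacian of the grayscale patch falls below
                 ``min_laplacian_variance``.

Filters short-circuit: a record carries the first failing stage only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

MAG_20X = "20x"
MAG_40X = "40x"

#: 3x3 Laplacian kernel used for the focus measure.
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0],
                             [1.0, -4.0, 1.0],
                             [0.0, 1.0, 0.0]])

QC_STAGES = ("tissue", "background", "saturation", "blur")


@dataclass
class QCConfig:
    """Thresholds of the quality-control chain.

    ``min_tissue_fraction`` and the white-RGB rule come straight from the
    tiling protocol; the saturation and Laplacian thresholds are tunable
    because no canonical values exist for them.
    """

    min_tissue_fraction: float = 0.10
    white_rgb_threshold: int = 220
    max_background_fraction: float = 0.90
    saturation_threshold: float = 0.07
    min_laplacian_variance: float = 50.0
    patch_side_40x: int = 512
    patch_side_20x_raw: int = 1024
    mask_downsample: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in [0, 1]")
        if not 0.0 <= self.max_background_fraction <= 1.0:
            raise ValueError("max_background_fraction must be in [0, 1]")
        if self.patch_side_40x % 2 or self.patch_side_20x_raw % 2:
            raise ValueError("patch sides must be even")
        if self.min_laplacian_variance < 0:
            raise ValueError("min_laplacian_variance must be >= 0")

    def patch_side(self, magnification: str) -> int:
        if magnification == MAG_40X:
            return self.patch_side_40x
        if magnification == MAG_20X:
            return self.patch_side_20x_raw
        raise ValueError(f"unknown magnification {magnification!r}")


@dataclass
class SlideInfo:
    slide_id: str
    width_px: int
    height_px: int
    native_magnification: str = MAG_40X
    mpp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")


@dataclass
class PatchRecord:
    """One grid cell with its QC measurements.

    Coordinates are 0-based level-0 pixels of the top-left corner; the
    footprint is the half-open square ``[x, x+side_px) x [y, y+side_px)``.
    Measurements of stages that were never reached stay NaN.
    """

    slide_id: str
    x: int
    y: int
    side_px: int
    magnification: str
    tissue_fraction: float = float("nan")
    background_fraction: float = float("nan")
    saturation_stat: float = float("nan")
    blur_score: float = float("nan")
    qc_pass: bool = False
    qc_fail_stage: Optional[str] = None


@dataclass
class TissueMask:
    """Binary tissue raster at ``1/downsample_factor`` of slide resolution."""

    mask: np.ndarray  # 2-D bool
    downsample_factor: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class QCReport:
    slide_id: str
    n_grid: int
    surviving: dict = field(default_factory=dict)  # stage -> count after stage

    def counts(self) -> list:
        """Counts entering/surviving each stage, pipeline order."""
        out = [self.n_grid]
        for stage in QC_STAGES:
            out.append(self.surviving[stage])
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# pixel helpers


def _as_rgb_u8(img: np.ndarray) -> np.ndarray:
    """Coerce a raster to 8-bit RGB; non-8-bit inputs are rescaled (logged)."""
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an RGB raster, got shape {img.shape}")
    img = img[..., :3]
    if img.dtype == np.uint8:
        return img
    logger.info("non-8-bit raster (dtype %s): normalizing to uint8", img.dtype)
    arr = img.astype(np.float64)
    if arr.max() <= 1.0:
        arr = arr * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def _block_mean(gray: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by block averaging; edge blocks are padded by replication."""
    h, w = gray.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        gray = np.pad(gray, ((0, ph), (0, pw)), mode="edge")
    h2, w2 = gray.shape
    return gray.reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))


def grayscale_u8(patch_pixels: np.ndarray) -> np.ndarray:
    """Luminance grayscale on the 0..255 scale (float)."""
    return rgb2gray(_as_rgb_u8(patch_pixels)) * 255.0


# ---------------------------------------------------------------------------
# operations


def compute_tissue_mask(slide_image: np.ndarray, downsample_factor: int = 10) -> TissueMask:
    """Otsu tissue mask on the slide downsampled by ``downsample_factor``.

    Tissue is the *darker* class: H&E-stained tissue absorbs light while the
    glass background is near-white.  A contrast-free (constant) slide has no
    separable foreground and yields an all-background mask.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    img = _as_rgb_u8(slide_image)
    if img.size == 0:
        raise ValueError("empty slide image")
    gray = rgb2gray(img)  # in [0, 1]
    small = _block_mean(gray, downsample_factor) if downsample_factor > 1 else gray
    if np.ptp(small) == 0:
        mask = np.zeros_like(small, dtype=bool)
    else:
        thr = threshold_otsu(small)
        mask = small < thr
    return TissueMask(mask=mask, downsample_factor=downsample_factor)


def generate_grid(slide: SlideInfo, config: QCConfig, magnification: str) -> list:
    """Non-overlapping row-major patch grid; incomplete border tiles dropped."""
    side = config.patch_side(magnification)
    records = []
    for y in range(0, slide.height_px - side + 1, side):
        for x in range(0, slide.width_px - side + 1, side):
            records.append(PatchRecord(slide_id=slide.slide_id, x=x, y=y,
                                       side_px=side, magnification=magnification))
    return records


def tissue_fraction_of(record: PatchRecord, mask: TissueMask) -> float:
    """Fraction of tissue-mask cells overlapping the patch footprint.

    Footprint cells are those whose index range derives from integer
    division of the pixel extent: rows ``y//f .. (y+side-1)//f`` inclusive.
    """
    f = mask.downsample_factor
    r0, r1 = record.y // f, (record.y + record.side_px - 1) // f
    c0, c1 = record.x // f, (record.x + record.side_px - 1) // f
    sub = mask.mask[r0:r1 + 1, c0:c1 + 1]
    if sub.size == 0:
        raise ValueError("tissue mask does not cover the patch footprint")
    return float(sub.mean())


def tissue_filter(record: PatchRecord, mask: TissueMask, config: QCConfig) -> bool:
    """Pass iff tissue occupies at least ``min_tissue_fraction`` (inclusive)."""
    frac = tissue_fraction_of(record, mask)
    record.tissue_fraction = frac
    return frac >= config.min_tissue_fraction


def background_fraction_of(patch_pixels: np.ndarray, config: QCConfig) -> float:
    """Fraction of pixels with all three channels strictly above the white threshold."""
    px = _as_rgb_u8(patch_pixels)
    bg = np.all(px > config.white_rgb_threshold, axis=-1)
    return float(bg.mean())


def background_filter(patch_pixels: np.ndarray, config: QCConfig,
                      record: Optional[PatchRecord] = None) -> bool:
    """Pass iff the white-background fraction does not exceed the cap."""
    frac = background_fraction_of(patch_pixels, config)
    if record is not None:
        record.background_fraction = frac
    return frac <= config.max_background_fraction


def mean_saturation_of(patch_pixels: np.ndarray, config: QCConfig) -> float:
    """Mean HSV saturation over non-background pixels; NaN if all background."""
    px = _as_rgb_u8(patch_pixels)
    sat = rgb2hsv(px)[..., 1]
    fg = ~np.all(px > config.white_rgb_threshold, axis=-1)
    if not fg.any():
        return float("nan")
    return float(sat[fg].mean())


def saturation_filter(patch_pixels: np.ndarray, config: QCConfig,
                      record: Optional[PatchRecord] = None) -> bool:
    """Pass iff mean saturation >= threshold (exclusion is strict ``<``).

    A patch that is entirely background is degenerate and excluded here.
    """
    stat = mean_saturation_of(patch_pixels, config)
    if record is not None:
        record.saturation_stat = stat
    if np.isnan(stat):
        logger.warning("degenerate patch: entirely background at saturation stage")
        return False
    return not (stat < config.saturation_threshold)


def blur_score_of(patch_pixels: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian of the 8-bit-scale grayscale patch."""
    gray = grayscale_u8(patch_pixels)
    lap = ndimage.convolve(gray, LAPLACIAN_KERNEL, mode="reflect")
    return float(lap.var())


def blur_filter(patch_pixels: np.ndarray, config: QCConfig,
                record: Optional[PatchRecord] = None) -> bool:
    """Pass iff the focus measure reaches the sharpness floor (strict ``<`` excludes)."""
    score = blur_score_of(patch_pixels)
    if record is not None:
        record.blur_score = score
    return not (score < config.min_laplacian_variance)


def extract_patch(slide_image: np.ndarray, record: PatchRecord,
                  config: Optional[QCConfig] = None) -> np.ndarray:
    """Crop a patch; 20x crops (1024 px) are area-averaged 2x down to 512.

    Rounding of averaged values is round-half-to-even, keeping constants exact.
    """
    config = config or QCConfig()
    img = _as_rgb_u8(slide_image)
    h, w = img.shape[:2]
    x, y, side = record.x, record.y, record.side_px
    if x < 0 or y < 0 or x + side > w or y + side > h:
        raise IndexError(
            f"patch ({x},{y}) side {side} exceeds slide bounds {w}x{h}")
    crop = img[y:y + side, x:x + side]
    if record.magnification == MAG_20X:
        a = crop.astype(np.float64)
        a = a.reshape(side // 2, 2, side // 2, 2, 3).mean(axis=(1, 3))
        crop = np.clip(np.round(a), 0, 255).astype(np.uint8)
    return crop


def run_qc_pipeline(slide_image: np.ndarray, slide_id: str,
                    config: Optional[QCConfig] = None,
                    magnification: str = MAG_40X):
    """Tile a slide and run the filter chain; returns (records, report).

    All grid records are returned (with ``qc_pass``/``qc_fail_stage`` set);
    stages run in order tissue -> background -> saturation -> blur and a
    failed record keeps only the measurements of stages it reached.
    """
    config = config or QCConfig()
    img = _as_rgb_u8(slide_image)
    h, w = img.shape[:2]
    slide = SlideInfo(slide_id=slide_id, width_px=w, height_px=h,
                      native_magnification=magnification)
    records = generate_grid(slide, config, magnification)
    mask = compute_tissue_mask(img, config.mask_downsample)

    surviving = {s: 0 for s in QC_STAGES}
    for rec in records:
        if not tissue_filter(rec, mask, config):
            rec.qc_fail_stage = "tissue"
            continue
        surviving["tissue"] += 1
        pixels = extract_patch(img, rec, config)
        if not background_filter(pixels, config, rec):
            rec.qc_fail_stage = "background"
            continue
        surviving["background"] += 1
        if not saturation_filter(pixels, config, rec):
            rec.qc_fail_stage = "saturation"
            continue
        surviving["saturation"] += 1
        if not blur_filter(pixels, config, rec):
            rec.qc_fail_stage = "blur"
            continue
        surviving["blur"] += 1
        rec.qc_pass = True

    report = QCReport(slide_id=slide_id, n_grid=len(records), surviving=surviving)
    logger.info("QC %s: %s", slide_id, " -> ".join(str(c) for c in report.counts()))
    return records, report


# ---------------------------------------------------------------------------
# manifest I/O

MANIFEST_COLUMNS = ["slide_id", "x", "y", "side_px", "magnification",
                    "tissue_fraction", "background_fraction", "saturation_stat",
                    "blur_score", "qc_pass", "qc_fail_stage"]


def records_to_manifest(records: Sequence[PatchRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=MANIFEST_COLUMNS)


def manifest_to_records(df: pd.DataFrame) -> list:
    recs = []
    for row in df.itertuples(index=False):
        stage = row.qc_fail_stage
        if isinstance(stage, float) and np.isnan(stage):
            stage = None
        recs.append(PatchRecord(
            slide_id=str(row.slide_id), x=int(row.x), y=int(row.y),
            side_px=int(row.side_px), magnification=str(row.magnification),
            tissue_fraction=float(row.tissue_fraction),
            background_fraction=float(row.background_fraction),
            saturation_stat=float(row.saturation_stat),
            blur_score=float(row.blur_score),
            qc_pass=bool(row.qc_pass), qc_fail_stage=stage))
    return recs
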