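"""End-to-end inference: image -> superpixel patches -> labels -> count.

``segment_image`` classifies every superpixel's patch with the trained model
and paints the patch label over the superpixel's pixels, producing the
binary ear mask.  ``median_filter_binary`` applies the 3x3 median to the
mask (burr removal); ``median_denoise`` and ``impulse_denoise`` apply the
same filter to a noisy input image before segmentation (the conditional
form touches only saturated pixels and is the effective remedy for
salt-and-pepper corruption).  ``count_regions`` labels connected
components (8-connectivity by
default, matching regionprops-style counting), drops regions below a
minimum area and reports per-region statistics; the component count is the
ear count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .model import EarCountModel, predict_patch_labels
from .superpixel import extract_patches, slic_segment

__all__ = [
    "PipelineConfig",
    "Region",
    "SegmentationResult",
    "segment_image",
    "median_filter_binary",
    "median_denoise",
    "impulse_denoise",
    "count_regions",
    "run_pipeline",
]

logger = logging.getLogger("earcount")


@dataclass(frozen=True)
class PipelineConfig:
    """Post-processing knobs of the inference pipeline."""

    median_window: int = 3
    connectivity: int = 8
    min_area: int = 0

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass
class Region:
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class SegmentationResult:
    mask: np.ndarray
    count: int
    regions: list[Region] = field(default_factory=list)


def segment_image(image: np.ndarray, model: EarCountModel,
                  slic_config=None) -> np.ndarray:
    """Classify superpixel patches and paint labels into a full-image mask."""
    spmap = slic_segment(image, slic_config or model.slic_config)
    patchset = extract_patches(image, spmap, model.feature_config.patch_size)
    labels = predict_patch_labels(model, patchset)
    return labels[spmap.labels].astype(bool)


def median_filter_binary(mask: np.ndarray, window: int = 3) -> np.ndarray:
    """Square median filter on a binary mask with reflected borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    if window == 1:
        return np.asarray(mask).astype(bool).copy()
    out = ndimage.median_filter(np.asarray(mask).astype(np.uint8),
                                size=window, mode="reflect")
    return out.astype(bool)


def median_denoise(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-channel median filter of an RGB image (impulse-noise removal)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    out = np.stack(
        [ndimage.median_filter(image[:, :, c], size=window, mode="reflect")
         for c in range(image.shape[2])],
        axis=2,
    )
    return out.astype(image.dtype)


def impulse_denoise(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Conditional median for impulse noise: only saturated pixels change.

    Pixels at 0 or 255 (the values salt-and-pepper noise writes) are
    replaced by the median of their window; all other pixels pass through
    untouched, so images free of impulses are (almost) unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    filtered = median_denoise(image, window)
    out = image.copy()
    hit = (image == 0) | (image == 255)
    out[hit] = filtered[hit]
    return out


def count_regions(mask: np.ndarray, connectivity: int = 8,
                  min_area: int = 0) -> SegmentationResult:
    """Connected-component count and per-region stats, largest first."""
    mask = np.asarray(mask).astype(bool)
    conn = 2 if connectivity == 8 else 1
    labeled = measure.label(mask, connectivity=conn)
    regions = [
        Region(area=int(r.area),
               centroid=(float(r.centroid[0]), float(r.centroid[1])),
               bbox=tuple(int(v) for v in r.bbox))
        for r in measure.regionprops(labeled)
        if r.area >= max(min_area, 1)
    ]
    regions.sort(key=lambda r: (-r.area, r.bbox))
    return SegmentationResult(mask=mask, count=len(regions), regions=regions)


def run_pipeline(image: np.ndarray, model: EarCountModel,
                 config: PipelineConfig = PipelineConfig()) -> SegmentationResult:
    """segment -> median filter -> count, with per-stage timing logs."""
    stages = (
        ("segment", lambda img: segment_image(img, model)),
        ("median_filter", lambda m: median_filter_binary(m, config.median_window)),
        ("count", lambda m: count_regions(m, config.connectivity, config.min_area)),
    )
    value = image
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            value = fn(value)
        except Exception as exc:
            raise type(exc)(f"pipeline stage {name!r}: {exc}") from exc
        logger.info("stage %s finished in %.3f s", name, time.perf_counter() - t0)
    return value
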