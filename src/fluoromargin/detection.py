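"""Image and margin classification against the per-patient threshold.

An image is positive when, after 3x3 median smoothing, it contains a
connected suprathreshold region of at least ``min_area_px`` pixels
(8-connectivity).  The area rule guards against isolated noise speckle;
the threshold comparison is strict (a pixel exactly at threshold is below).
A margin surface covered by several fields of view is positive if any
field is positive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .imageops import label_components, median_smooth
from .synthetic import MarginImage


@dataclass(frozen=True)
class DetectionConfig:
    min_area_px: int = 9
    smoothing_px: int = 3

    def validate(self) -> None:
        if self.min_area_px < 1:
            raise ConfigurationError("min_area_px must be >= 1")
        if self.smoothing_px < 1 or self.smoothing_px % 2 == 0:
            raise ConfigurationError("smoothing_px must be a positive odd integer")


@dataclass
class DetectionResult:
    margin_id: str
    field_index: int
    positive: bool
    highlight_mask: np.ndarray
    max_normalized_signal: float
    suprathreshold_area_px: int


def classify_image(
    image: MarginImage,
    threshold: float,
    config: DetectionConfig = DetectionConfig(),
    baseline: Optional[float] = None,
    smoothed: Optional[np.ndarray] = None,
) -> DetectionResult:
    """Classify one field of view against an absolute threshold (AFU).

    ``baseline`` (AFU) is used to report the peak signal in normalized
    units; when absent the threshold itself is used as the scale.
    ``smoothed`` lets callers reuse a precomputed median-smoothed array.
    """
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    config.validate()
    if smoothed is None:
        smoothed = median_smooth(
            image.pixels, image.circular_mask, size=config.smoothing_px
        )
    above = image.circular_mask & (smoothed > threshold)
    labels, n_components = label_components(above)
    highlight = np.zeros_like(above)
    if n_components:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= config.min_area_px)
        keep = keep[keep != 0]
        if keep.size:
            highlight = np.isin(labels, keep)
    area = int(highlight.sum())
    scale = baseline if baseline is not None else threshold
    return DetectionResult(
        margin_id=image.margin_id,
        field_index=image.field_index,
        positive=bool(area > 0),
        highlight_mask=highlight,
        max_normalized_signal=float(np.nanmax(smoothed) / scale),
        suprathreshold_area_px=area,
    )


def aggregate_margin(results: Sequence[DetectionResult]) -> str:
    """Margin reading: positive iff any field of view is positive."""
    if len(results) == 0:
        raise InputError("aggregate_margin requires at least one result")
    margin_ids = {r.margin_id for r in results}
    if len(margin_ids) > 1:
        raise InputError(f"mixed margin_ids in aggregation: {sorted(margin_ids)}")
    return "positive" if any(r.positive for r in results) else "negative"


def render_overlay(image: MarginImage, result: DetectionResult) -> np.ndarray:
    """Grayscale rendering with suprathreshold regions colored pure red.

    Red pixels correspond exactly to the retained highlight mask; pixels
    outside the circular field are black.
    """
    if result.margin_id != image.margin_id or result.field_index != image.field_index:
        raise InputError("detection result does not belong to this image")
    if result.highlight_mask.shape != image.pixels.shape:
        raise InputError("highlight mask shape does not match image")
    mask = image.circular_mask
    vmax = float(np.nanmax(image.pixels))
    if not np.isfinite(vmax) or vmax <= 0:
        vmax = 1.0
    gray = np.zeros(image.pixels.shape, dtype=float)
    gray[mask] = np.clip(image.pixels[mask] / vmax, 0.0, 1.0)
    # Reserve 254 for grayscale so pure red (255, 0, 0) is unambiguous.
    base = np.round(gray * 254.0).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[result.highlight_mask] = (255, 0, 0)
    return rgb
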