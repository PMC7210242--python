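"""Shared low-level raster helpers.

All field-of-view images are square arrays holding arbitrary fluorescence
units (AFU) inside an inscribed circular field; pixels outside the field are
invalid and carried as NaN so they never enter summary statistics.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi


@lru_cache(maxsize=8)
def circular_field_mask(size_px: int) -> np.ndarray:
    """Boolean mask of the circular field inscribed in a ``size_px`` square."""
    c = (size_px - 1) / 2.0
    radius = (size_px - 1) / 2.0
    rr, cc = np.ogrid[:size_px, :size_px]
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    mask.setflags(write=False)
    return mask


def in_field_values(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return pixels[mask]


def field_mean(pixels: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean(pixels[mask]))


def median_smooth(pixels: np.ndarray, mask: np.ndarray, size: int = 3) -> np.ndarray:
    """3x3 (by default) median filter restricted to the circular field.

    Out-of-field pixels are filled with the in-field median before filtering
    so rim pixels are not dragged toward zero, then restored to NaN.
    """
    med = float(np.median(pixels[mask]))
    filled = np.where(mask, pixels, med)
    smoothed = ndi.median_filter(filled, size=size, mode="nearest")
    smoothed[~mask] = np.nan
    return smoothed


def smoothed_peak(pixels: np.ndarray, mask: np.ndarray, size: int = 3) -> float:
    """Maximum in-field value after median smoothing."""
    return float(np.nanmax(median_smooth(pixels, mask, size=size)))


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling of a boolean mask."""
    structure = np.ones((3, 3), dtype=int)
    return ndi.label(mask, structure=structure)
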