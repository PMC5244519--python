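"""Responsive-cortex masking and V1-normalized per-area amplitudes.

The magnitude map is duplicated, smoothed with a 5x5 Gaussian kernel,
thresholded into a responsive-cortex mask — and the mask is then applied
to the ORIGINAL (unfiltered) magnitude map; the filtered copy exists only
to build the mask.  Per-area means over (area intersect mask) are then
normalized to the V1 mean within each animal, which cancels global gain
differences between animals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import AreaLabelMap

__all__ = ["ThresholdRule", "ResponseTable", "responsive_mask", "region_means",
           "normalize_to_v1", "gaussian_kernel_2d"]

logger = logging.getLogger(__name__)


def gaussian_kernel_2d(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Odd-sized truncated Gaussian kernel, normalized to unit sum.

    A stated "kernel size 5 x 5" fixes the support, not the width; sigma
    defaults to 1 px.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


@dataclass(frozen=True)
class ThresholdRule:
    """How the responsive-cortex threshold is chosen.

    ``mode="fraction_of_p99"`` (default): threshold = value x the 99th
    percentile of the filtered map — scale-free and robust to outlier
    pixels, applied per animal.  ``mode="absolute"``: threshold = value
    in the magnitude map's own units.
    """

    mode: str = "fraction_of_p99"
    value: float = 0.25

    def resolve(self, filtered: np.ndarray) -> float:
        if self.mode == "absolute":
            return self.value
        if self.mode == "fraction_of_p99":
            return self.value * float(np.percentile(filtered, 99.0))
        raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass
class ResponseTable:
    """Per-animal, per-area response amplitudes."""

    animal_id: str
    raw_mean: dict[str, float]
    n_pixels: dict[str, int]
    threshold_used: float
    normalized: dict[str, float] = field(default_factory=dict)
    missing_areas: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {"animal_id": self.animal_id,
                     "mask_threshold": self.threshold_used}
        for area, v in self.raw_mean.items():
            row[f"raw_{area}"] = v
        for area, v in self.normalized.items():
            row[f"norm_{area}"] = v
        for area, v in self.n_pixels.items():
            row[f"n_px_{area}"] = v
        return row


def responsive_mask(mag: np.ndarray, kernel_px: int = 5,
                    sigma: float = 1.0,
                    rule: ThresholdRule | None = None) -> np.ndarray:
    """Threshold the Gaussian-filtered magnitude map into a binary mask.

    Raises if the mask comes out empty, naming the threshold used.
    """
    rule = rule or ThresholdRule()
    kernel = gaussian_kernel_2d(kernel_px, sigma)
    filtered = ndimage.convolve(np.asarray(mag, dtype=float), kernel, mode="nearest")
    threshold = rule.resolve(filtered)
    mask = filtered >= threshold
    if not mask.any():
        raise ValueError(
            f"responsive mask is empty at threshold {threshold:.6g} "
            f"(rule {rule.mode}={rule.value})")
    return mask


def region_means(mag: np.ndarray, mask: np.ndarray, labels: AreaLabelMap,
                 animal_id: str = "animal",
                 threshold_used: float = float("nan"),
                 erode_px: int = 0) -> ResponseTable:
    """Mean of the ORIGINAL magnitude map over each (area intersect mask).

    ``erode_px`` optionally shrinks each area label by that many pixels
    before averaging, excluding partial-volume boundary pixels (an area
    that erosion would empty is kept un-eroded).  Areas whose intersection
    with the mask is empty are reported missing (with a warning) rather
    than silently zero.
    """
    mag = np.asarray(mag, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mag.shape != mask.shape or mag.shape != labels.labels.shape:
        raise ValueError(
            f"shape mismatch: mag {mag.shape}, mask {mask.shape}, "
            f"labels {labels.labels.shape}")
    raw: dict[str, float] = {}
    n_px: dict[str, int] = {}
    missing: list[str] = []
    for name in labels.area_names():
        area_mask = labels.mask_of(name)
        if erode_px > 0:
            eroded = ndimage.binary_erosion(area_mask, iterations=erode_px)
            if eroded.any():
                area_mask = eroded
        sel = area_mask & mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"area {name} has no responsive pixels; excluded",
                          stacklevel=2)
            missing.append(name)
            continue
        raw[name] = float(mag[sel].mean())
        n_px[name] = n
    return ResponseTable(animal_id=animal_id, raw_mean=raw, n_pixels=n_px,
                         threshold_used=threshold_used, missing_areas=missing)


def normalize_to_v1(table: ResponseTable) -> ResponseTable:
    """Divide every area's raw mean by the animal's V1 mean (V1 -> 1)."""
    if "V1" not in table.raw_mean:
        raise ValueError(f"animal {table.animal_id}: V1 missing, cannot normalize")
    v1 = table.raw_mean["V1"]
    if v1 <= 0:
        raise ValueError(f"animal {table.animal_id}: V1 mean is {v1}, "
                         "cannot normalize")
    table.normalized = {area: v / v1 for area, v in table.raw_mean.items()}
    return table
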