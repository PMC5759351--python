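"""Pollen-viability statistics: MPV, APV, PSI, and rating categories.

Viability is estimated as the fraction of dark-stained (viable) grains:

* ``MPV_img``  — manual viability per image: dark-blue grains / all
  grains × 100, counted by eye.
* ``APV_img``  — automatic viability per image: green-channel count /
  red-channel count × 100.
* ``APV``      — sample-level automatic viability: a count-weighted
  ratio, Σ green / Σ red × 100 over all the sample's images. This is
  deliberately not the mean of per-image APVs; images with more grains
  carry more weight.
* ``PSI_img``  — pollen size index: percentage of grains whose area
  exceeds a calibration threshold (118 px² by default, the mean area of
  the smallest viable grain across a calibration image set). Implemented
  for completeness; size distributions of viable and non-viable grains
  overlap too much across cultivars for PSI to be a reliable proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .errors import UndefinedViabilityError

logger = logging.getLogger(__name__)

__all__ = [
    "Rating",
    "PsiConfig",
    "ViabilityResult",
    "apv_image",
    "mpv_image",
    "apv_sample",
    "psi_image",
    "psi_threshold_from_calibration",
    "rate_viability",
]


class Rating(str, Enum):
    """Categorical viability rating derived from APV (%)."""

    VERY_LOW = "very_low"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


@dataclass(frozen=True)
class PsiConfig:
    """Pollen-size-index calibration: grains strictly over the threshold count."""

    area_threshold: float = 118.0

    def __post_init__(self) -> None:
        if self.area_threshold <= 0:
            raise ValueError("PSI area threshold must be > 0")


@dataclass(frozen=True)
class ViabilityResult:
    """Viability percentages and rating at image or sample scope."""

    scope: str  # "image" | "sample"
    apv: float
    rating: Rating
    mpv: Optional[float] = None
    psi: Optional[float] = None


def apv_image(green_count: int, red_count: int) -> float:
    """Automatic viability per image: 100 · green_count / red_count.

    A value above 100% indicates a segmentation fault (more viable than
    total grains); it is reported uncapped with a warning rather than
    silently clamped.
    """
    if green_count < 0 or red_count < 0:
        raise ValueError("counts must be non-negative")
    if red_count == 0:
        raise UndefinedViabilityError(
            "APV undefined: red-channel (total) count is zero"
        )
    value = 100.0 * green_count / red_count
    if value > 100.0:
        logger.warning(
            "APV %.2f%% exceeds 100%% (green %d > red %d): check segmentation",
            value, green_count, red_count,
        )
    return value


def mpv_image(dark_blue: int, all_grains: int) -> float:
    """Manual viability per image: 100 · dark-blue grains / all grains."""
    if dark_blue < 0 or all_grains < 0:
        raise ValueError("counts must be non-negative")
    if all_grains == 0:
        raise UndefinedViabilityError("MPV undefined: no grains counted")
    if dark_blue > all_grains:
        raise ValueError("dark-blue count cannot exceed the total grain count")
    return 100.0 * dark_blue / all_grains


def apv_sample(per_image_counts: Sequence[tuple[int, int]]) -> float:
    """Sample-level APV: 100 · Σ green / Σ red over the sample's images.

    This count-weighted ratio differs from the mean of per-image APVs
    whenever images contribute unequal grain numbers.
    """
    if len(per_image_counts) == 0:
        raise UndefinedViabilityError("sample APV undefined: no images")
    sum_green = sum(g for g, _ in per_image_counts)
    sum_red = sum(r for _, r in per_image_counts)
    if sum_red == 0:
        raise UndefinedViabilityError("sample APV undefined: total red count is zero")
    return 100.0 * sum_green / sum_red


def psi_image(areas: Sequence[float], cfg: PsiConfig = PsiConfig()) -> float:
    """Pollen size index: % of grains with area strictly over the threshold."""
    if len(areas) == 0:
        raise UndefinedViabilityError("PSI undefined: no grain areas supplied")
    over = sum(1 for a in areas if a > cfg.area_threshold)
    return 100.0 * over / len(areas)


def psi_threshold_from_calibration(
    smallest_viable_area_per_image: Sequence[float],
) -> float:
    """Mean of the smallest viable-grain area found in each calibration image."""
    if len(smallest_viable_area_per_image) == 0:
        raise UndefinedViabilityError("PSI calibration needs at least one image")
    vals = list(smallest_viable_area_per_image)
    return sum(vals) / len(vals)


def rate_viability(apv: float) -> Rating:
    """Map an APV percentage to its categorical rating.

    Bins: very high (APV > 90), high (75 < APV ≤ 90), medium
    (50 < APV ≤ 75), low (25 ≤ APV ≤ 50), very low (APV < 25). Boundary
    membership is assigned to the lower category except that exactly 25
    rates as low; any consistent rule reproduces the published labels
    since no reference value sits exactly on a boundary.
    """
    if not 0 <= apv <= 100:
        raise ValueError(f"APV out of range [0, 100]: {apv}")
    if apv > 90:
        return Rating.VERY_HIGH
    if apv > 75:
        return Rating.HIGH
    if apv > 50:
        return Rating.MEDIUM
    if apv >= 25:
        return Rating.LOW
    return Rating.VERY_LOW


def viability_result_for_sample(
    per_image_counts: Sequence[tuple[int, int]],
) -> ViabilityResult:
    """Convenience wrapper: sample APV plus its rating."""
    apv = apv_sample(per_image_counts)
    return ViabilityResult(scope="sample", apv=apv, rating=rate_viability(min(apv, 100.0)))
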