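"""Synthetic Alexander-stain micrographs with exact ground truth.

Scenes emulate bright-field images of stained pollen: elliptical grains
on a light background, with viable grains rendered dark purple (dark in
both the red and green channels), non-viable grains pale turquoise (dark
in red, near-background in green), plus optional small "balloon"
artifacts that are dark only in the green channel — mimicking released
protoplasm blobs that the green-channel area floor is designed to
reject. A configurable fraction of grains is placed overlapping a
neighbor to exercise watershed splitting.

What is deliberately not modelled: optics (no blur/vignetting beyond
additive Gaussian noise), stain chemistry, pollen apertures or texture,
and debris other than the green-channel balloons. Grains are exact
ellipses, so real-image failure modes such as out-of-focus halos or
clumps of more than a few grains are not represented.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from math import ceil, cos, pi, sin, sqrt
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from PIL import Image
from skimage.draw import ellipse as draw_ellipse

from .errors import PlacementError

__all__ = [
    "SyntheticSceneSpec",
    "GrainTruth",
    "GroundTruth",
    "generate_scene",
    "generate_batch",
]

#: Minimum clearance (px) between non-touching grain boundaries, chosen to
#: exceed twice the default morphological dilation so solidification never
#: fuses grains that were generated as separate.
_SEPARATION_GAP = 6.0

_MAX_TRIES = 1000


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate the acquisition conditions of the real micrographs:
    1024×768 rasters averaging ~130 grains per image, grain areas inside
    the 60–800 px² counting window with overlapping viable/non-viable
    size distributions (non-viable slightly smaller), and mild additive
    noise. The default palette guarantees the channel-contrast margins
    that make automatic thresholding reliable: grains sit ≥ 40 intensity
    units below background in the red channel, viable grains ≥ 40 below
    in the green channel, while non-viable grains stay within 20 units
    of background green.
    """

    image_size: tuple[int, int] = (768, 1024)  # (H, W)
    n_viable: int = 90
    n_nonviable: int = 40
    radius_range_viable: tuple[float, float] = (8.0, 14.0)
    radius_range_nonviable: tuple[float, float] = (6.5, 12.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    touching_fraction: float = 0.0
    n_artifacts: int = 3
    viable_color: tuple[int, int, int] = (70, 60, 120)
    nonviable_color: tuple[int, int, int] = (90, 225, 230)
    background_color: tuple[int, int, int] = (235, 235, 235)
    artifact_color: tuple[int, int, int] = (235, 120, 235)
    noise_sd: float = 5.0
    jpeg_quality: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_viable < 0 or self.n_nonviable < 0 or self.n_artifacts < 0:
            raise ValueError("counts must be non-negative")
        for lo, hi in (self.radius_range_viable, self.radius_range_nonviable):
            if not 0 < lo <= hi:
                raise ValueError("radius ranges must be positive and ordered")
        lo, hi = self.eccentricity_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("eccentricity range must lie in [0, 1)")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._validate_palette()

    def _validate_palette(self) -> None:
        """Channel-contrast margins the segmentation invariants rely on."""
        bg_r, bg_g = self.background_color[0], self.background_color[1]
        if bg_r - self.viable_color[0] < 40 or bg_g - self.viable_color[1] < 40:
            raise ValueError(
                "viable color must be >= 40 units below background in red and green"
            )
        if bg_r - self.nonviable_color[0] < 40:
            raise ValueError("non-viable color must be >= 40 units below background in red")
        if abs(bg_g - self.nonviable_color[1]) > 20:
            raise ValueError(
                "non-viable color must stay within 20 units of background in green"
            )
        if self.n_artifacts:
            if abs(bg_r - self.artifact_color[0]) > 10:
                raise ValueError("artifact color must match background in the red channel")
            if bg_g - self.artifact_color[1] < 40:
                raise ValueError("artifact color must be >= 40 units below background green")


@dataclass(frozen=True)
class GrainTruth:
    """Geometry and identity of one generated grain."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (major, minor) semi-axes, px
    angle: float  # major-axis rotation, radians
    viable: bool
    area_px: int  # rasterized pixel count of the grain's own ellipse


@dataclass(frozen=True)
class GroundTruth:
    """Truth table for one scene."""

    grains: tuple[GrainTruth, ...]
    true_total: int
    true_viable: int
    true_viability: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.true_total > 0:
            expected = 100.0 * self.true_viable / self.true_total
            object.__setattr__(self, "true_viability", expected)


def _directional_radius(a: float, b: float, angle: float, theta: float) -> float:
    """Radius of an ellipse (semi-axes a, b, rotated by ``angle``) along ``theta``."""
    phi = theta - angle
    return a * b / sqrt((b * cos(phi)) ** 2 + (a * sin(phi)) ** 2)


def _sample_geometry(
    rng: np.random.Generator, spec: SyntheticSceneSpec, viable: bool
) -> tuple[float, float, float]:
    lo, hi = spec.radius_range_viable if viable else spec.radius_range_nonviable
    r = rng.uniform(lo, hi)
    e = rng.uniform(*spec.eccentricity_range)
    # Preserve area π·r²: a·b = r² with axis ratio b/a = sqrt(1 − e²).
    ratio = sqrt(1.0 - e * e)
    a = r / ratio**0.5
    b = r * ratio**0.5
    angle = rng.uniform(0.0, pi)
    return a, b, angle


def _place_grains(
    rng: np.random.Generator, spec: SyntheticSceneSpec
) -> list[tuple[float, float, float, float, float, bool]]:
    """Place grains, returning (cy, cx, a, b, angle, viable) per grain.

    Non-touching grains keep at least ``_SEPARATION_GAP`` px between their
    bounding circles; grains flagged as touching are attached to a random
    already-placed grain with a boundary overlap of 10–30% of the smaller
    equivalent radius. Placement uses rejection sampling with bounded
    retries and fails loudly rather than silently under-filling.
    """
    h, w = spec.image_size
    total = spec.n_viable + spec.n_nonviable
    flags = np.array([True] * spec.n_viable + [False] * spec.n_nonviable)
    rng.shuffle(flags)
    n_touch = int(round(spec.touching_fraction * total))
    touch_idx: set[int] = set()
    if n_touch and total > 1:
        touch_idx = set(rng.choice(np.arange(1, total), size=min(n_touch, total - 1),
                                   replace=False).tolist())

    placed: list[tuple[float, float, float, float, float, bool]] = []
    for i in range(total):
        viable = bool(flags[i])
        a, b, angle = _sample_geometry(rng, spec, viable)
        margin = ceil(a) + 4
        if margin * 2 >= min(h, w):
            raise PlacementError("grain radius too large for the canvas")
        ok = False
        for _ in range(_MAX_TRIES):
            if i in touch_idx and placed:
                j = int(rng.integers(len(placed)))
                py, px, pa, pb, pangle, _ = placed[j]
                theta = rng.uniform(0.0, 2 * pi)
                r_self = sqrt(a * b)
                r_other = sqrt(pa * pb)
                overlap = rng.uniform(0.1, 0.3) * min(r_self, r_other)
                d = (
                    _directional_radius(pa, pb, pangle, theta)
                    + _directional_radius(a, b, angle, theta + pi)
                    - overlap
                )
                cy, cx = py + d * sin(theta), px + d * cos(theta)
                if not (margin <= cy < h - margin and margin <= cx < w - margin):
                    continue
                partner = j
            else:
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                partner = None
            crowded = False
            for k, (qy, qx, qa, qb, _, _) in enumerate(placed):
                if partner is not None and k == partner:
                    continue
                if (cy - qy) ** 2 + (cx - qx) ** 2 < (a + qa + _SEPARATION_GAP) ** 2:
                    crowded = True
                    break
            if not crowded:
                placed.append((cy, cx, a, b, angle, viable))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place grain {i + 1}/{total} after {_MAX_TRIES} tries; "
                "canvas too crowded"
            )
    return placed


def generate_scene(spec: SyntheticSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a given spec (seed included).

    Returns the H×W×3 uint8 image and its :class:`GroundTruth`. When
    ``jpeg_quality`` is set the image is round-tripped through an
    in-memory JPEG encode to emulate the acquisition file format.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color

    placed = _place_grains(rng, spec)
    grains: list[GrainTruth] = []
    # Paint non-viable grains first so that in mixed touching pairs the
    # viable grain keeps its full dark-green footprint.
    for pass_viable in (False, True):
        color = spec.viable_color if pass_viable else spec.nonviable_color
        for cy, cx, a, b, angle, viable in placed:
            if viable != pass_viable:
                continue
            # skimage rotates row/col axes clockwise; sign is irrelevant
            # here because orientation angles are sampled uniformly.
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
            img[rr, cc] = color
            grains.append(
                GrainTruth(
                    center=(cy, cx),
                    axes=(a, b),
                    angle=angle,
                    viable=viable,
                    area_px=int(len(rr)),
                )
            )

    # Artifacts are free-standing: they keep clear of grains and of each
    # other so counting accuracy can be attributed purely to the filters.
    artifact_centers: list[tuple[float, float, float]] = []
    for i in range(spec.n_artifacts):
        area = rng.uniform(40.0, 99.0)
        r = sqrt(area / pi)
        m = ceil(r) + 2
        for _ in range(_MAX_TRIES):
            cy = rng.uniform(m, h - m)
            cx = rng.uniform(m, w - m)
            near_grain = any(
                (cy - gy) ** 2 + (cx - gx) ** 2 < (ga + r + _SEPARATION_GAP) ** 2
                for gy, gx, ga, _, _, _ in placed
            )
            near_artifact = any(
                (cy - ay) ** 2 + (cx - ax) ** 2 < (ar + r + _SEPARATION_GAP) ** 2
                for ay, ax, ar in artifact_centers
            )
            if not near_grain and not near_artifact:
                break
        else:
            raise PlacementError(
                f"could not place artifact {i + 1}/{spec.n_artifacts} "
                f"after {_MAX_TRIES} tries"
            )
        artifact_centers.append((cy, cx, r))
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(h, w))
        # Rasterization can overshoot the analytic area by a perimeter's
        # worth of pixels; shrink until the blob stays safely inside the
        # 40-99 px² artifact regime regardless of subpixel placement.
        while len(rr) > 96 and r > 1.0:
            r -= 0.05
            rr, cc = draw_ellipse(cy, cx, r, r, shape=(h, w))
        img[rr, cc] = spec.artifact_color

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if spec.jpeg_quality is not None:
        buf = _stdio.BytesIO()
        Image.fromarray(img).save(buf, format="JPEG", quality=spec.jpeg_quality)
        buf.seek(0)
        img = np.asarray(Image.open(buf).convert("RGB"))

    n_viable = sum(g.viable for g in grains)
    truth = GroundTruth(
        grains=tuple(grains),
        true_total=len(grains),
        true_viable=n_viable,
    )
    return img, truth


def generate_batch(
    template: SyntheticSceneSpec,
    n_images: int,
    out_dir: str | Path,
    viability_range: tuple[float, float] = (10.0, 99.0),
    seed: int = 0,
    image_format: str = "png",
    total_range: Optional[tuple[int, int]] = None,
) -> list[tuple[Path, GroundTruth]]:
    """Generate a directory of scenes plus a ``truth.tsv`` table.

    Each image's true viability is drawn uniformly from
    ``viability_range`` and realised by splitting the image's total
    grain count into viable/non-viable accordingly. The total is the
    template's grain count unless ``total_range`` is given, in which
    case it is drawn uniformly per image (real acquisitions vary widely
    in grains per field of view). Deterministic for a given ``seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if image_format not in ("png", "jpg"):
        raise ValueError(f"unsupported image format: {image_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    results: list[tuple[Path, GroundTruth]] = []
    truth_lines = ["image_id\ttrue_total\ttrue_viable\ttrue_viability"]
    for i in range(n_images):
        v = master.uniform(*viability_range)
        child_seed = int(master.integers(0, 2**31 - 1))
        if total_range is not None:
            total = int(master.integers(total_range[0], total_range[1] + 1))
        else:
            total = template.n_viable + template.n_nonviable
        n_viable = int(round(v * total / 100.0))
        spec = replace(
            template,
            n_viable=n_viable,
            n_nonviable=total - n_viable,
            seed=child_seed,
            jpeg_quality=template.jpeg_quality if image_format == "jpg" else None,
        )
        img, truth = generate_scene(spec)
        path = out_dir / f"img_{i:04d}.{image_format}"
        if image_format == "jpg":
            Image.fromarray(img).save(path, quality=spec.jpeg_quality or 95)
            img = np.asarray(Image.open(path).convert("RGB"))
        else:
            iio.imwrite(path, img)
        truth_lines.append(
            f"{path.name}\t{truth.true_total}\t{truth.true_viable}\t"
            f"{truth.true_viability:.4f}"
        )
        results.append((path, truth))
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    return results
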