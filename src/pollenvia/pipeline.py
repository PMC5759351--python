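"""Batch pipeline: process a directory of micrographs end to end.

For each image: split RGB channels, segment the red and green channels,
apply the per-channel particle filters, record the counts, and
optionally write the two annotated overlays. Images are then grouped
into samples (one image per sample unless a mapping is supplied) and
sample-level APV plus its rating are computed from the count sums.
Individual image failures are logged and skipped so a long batch never
dies on one bad file.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from . import io as pio
from .channels import select_counting_channels
from .errors import ConfigError
from .particles import (
    GREEN_FILTER,
    RED_FILTER,
    CountResult,
    FilterConfig,
    apply_filters,
    kept_and_discarded_masks,
    measure_particles,
)
from .segment import SegmentationConfig, segment_channel_with_threshold
from .viability import Rating, apv_sample, rate_viability

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SampleSummary", "run_pipeline", "load_config", "process_image"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a batch run; defaults are the published
    counting parameters (red 60–800 px², green 100–800 px², circularity
    0.40–1.00, isodata threshold, watershed on)."""

    input_dir: Path = Path(".")
    output_dir: Path = Path("pollenvia_out")
    red_filter: FilterConfig = RED_FILTER
    green_filter: FilterConfig = GREEN_FILTER
    seg: SegmentationConfig = SegmentationConfig()
    sample_map: Optional[Mapping[str, str]] = None
    emit_annotated: bool = True
    table_format: str = "tsv"
    log_level: str = "INFO"


@dataclass(frozen=True)
class SampleSummary:
    """Sample-level aggregation: count sums, APV and its rating."""

    sample_id: str
    n_images: int
    sum_red: int
    sum_green: int
    apv: float
    rating: Rating


def process_image(
    img: pio.RgbImage,
    seg: SegmentationConfig = SegmentationConfig(),
    red_filter: FilterConfig = RED_FILTER,
    green_filter: FilterConfig = GREEN_FILTER,
    annotated_dir: Optional[Path] = None,
) -> tuple[CountResult, CountResult]:
    """Run the counting pipeline on one image; returns (red, green) results."""
    red, green = select_counting_channels(img)
    results = []
    for ch, f in ((red, red_filter), (green, green_filter)):
        lm, t = segment_channel_with_threshold(ch, seg)
        particles = apply_filters(measure_particles(lm), f)
        n_counted = sum(p.passed_filter for p in particles)
        logger.info(
            "%s [%s]: threshold=%d detected=%d counted=%d",
            img.source_id, ch.channel_name, t, len(particles), n_counted,
        )
        results.append(
            CountResult(
                image_id=img.source_id,
                channel=ch.channel_name,
                n_detected=len(particles),
                n_counted=n_counted,
                particles=tuple(particles),
            )
        )
        if annotated_dir is not None:
            kept, discarded = kept_and_discarded_masks(lm, particles)
            stem = Path(img.source_id).stem or "image"
            pio.write_annotated_image(
                kept, discarded, annotated_dir / f"{stem}_{ch.channel_name}.png"
            )
    return results[0], results[1]


def run_pipeline(cfg: RunConfig) -> tuple[list[pio.CountTableRow], list[SampleSummary]]:
    """Process every image under ``cfg.input_dir``.

    Writes ``counts.tsv`` (or .csv) and ``samples.tsv`` into
    ``cfg.output_dir`` plus, when enabled, two annotated overlays per
    image. Returns the count rows and sample summaries. A failed image
    is logged and skipped; an empty input directory is an error.
    """
    paths = pio.discover_batch(cfg.input_dir)
    if not paths:
        raise FileNotFoundError(f"no input images found in {cfg.input_dir}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotated_dir = None
    if cfg.emit_annotated:
        annotated_dir = out / "annotated"
        annotated_dir.mkdir(exist_ok=True)

    rows: list[pio.CountTableRow] = []
    n_failed = 0
    for path in paths:
        try:
            img = pio.read_rgb_image(path)
            red_res, green_res = process_image(
                img, cfg.seg, cfg.red_filter, cfg.green_filter, annotated_dir
            )
        except Exception:
            n_failed += 1
            logger.exception("skipping image that failed to process: %s", path)
            continue
        rows.append(
            pio.CountTableRow(
                image_id=path.name,
                red_count=red_res.n_counted,
                green_count=green_res.n_counted,
            )
        )
    if n_failed:
        logger.warning("%d of %d images failed and were skipped", n_failed, len(paths))

    ext = "tsv" if cfg.table_format == "tsv" else "csv"
    pio.write_count_table(rows, out / f"counts.{ext}", format=cfg.table_format)

    summaries = summarize_samples(rows, cfg.sample_map)
    write_sample_table(summaries, out / f"samples.{ext}", cfg.table_format)
    return rows, summaries


def summarize_samples(
    rows: list[pio.CountTableRow],
    sample_map: Optional[Mapping[str, str]] = None,
) -> list[SampleSummary]:
    """Group image counts into samples and compute sample-level APV.

    Default grouping is one sample per image. Images whose red sum is
    zero get no summary (viability undefined) and are logged.
    """
    groups: dict[str, list[pio.CountTableRow]] = {}
    for row in rows:
        sid = sample_map.get(row.image_id, row.image_id) if sample_map else row.image_id
        groups.setdefault(sid, []).append(row)
    summaries = []
    for sid in sorted(groups):
        members = groups[sid]
        sum_red = sum(r.red_count for r in members)
        sum_green = sum(r.green_count for r in members)
        if sum_red == 0:
            logger.warning("sample %s has zero total count; APV undefined", sid)
            continue
        apv = apv_sample([(r.green_count, r.red_count) for r in members])
        summaries.append(
            SampleSummary(
                sample_id=sid,
                n_images=len(members),
                sum_red=sum_red,
                sum_green=sum_green,
                apv=apv,
                rating=rate_viability(min(apv, 100.0)),
            )
        )
    return summaries


def write_sample_table(
    summaries: list[SampleSummary], path: Path, table_format: str = "tsv"
) -> None:
    delim = "\t" if table_format == "tsv" else ","
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["sample_id", "n_images", "sum_red", "sum_green", "apv", "rating"])
        for s in summaries:
            writer.writerow(
                [s.sample_id, s.n_images, s.sum_red, s.sum_green,
                 f"{s.apv:.4f}", s.rating.value]
            )


# ---------------------------------------------------------------------------
# Plain-text configuration files: one `key = value` per line, # comments.

_BOOL_KEYS = {"watershed", "exclude_edges", "emit_annotated"}
_INT_KEYS = {"fixed_threshold", "morph_iterations", "maxima_merge_radius", "connectivity"}
_FLOAT_KEYS = {
    "red_area_min", "red_area_max", "green_area_min", "green_area_max",
    "circ_min", "circ_max",
}
_STR_KEYS = {
    "input_dir", "output_dir", "threshold_method", "structuring_element",
    "table_format", "log_level",
}
KNOWN_KEYS = _BOOL_KEYS | _INT_KEYS | _FLOAT_KEYS | _STR_KEYS


def _parse_value(key: str, raw: str, lineno: int):
    try:
        if key in _BOOL_KEYS:
            if raw.lower() in ("true", "yes", "on", "1"):
                return True
            if raw.lower() in ("false", "no", "off", "0"):
                return False
            raise ValueError(raw)
        if key in _INT_KEYS:
            return int(raw)
        if key in _FLOAT_KEYS:
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(
            f"malformed value for key '{key}' on line {lineno}: {raw!r}"
        ) from exc


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a key = value text file.

    Unset keys keep the published defaults; unknown keys and malformed
    values raise :class:`ConfigError` naming the key and line. The full
    effective configuration is echoed to the log.
    """
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"expected 'key = value' on line {lineno}: {line!r}")
        key, _, raw = stripped.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key '{key}' on line {lineno}")
        values[key] = _parse_value(key, raw, lineno)

    seg_kwargs = {}
    if "threshold_method" in values:
        seg_kwargs["threshold_method"] = values["threshold_method"]
    if "fixed_threshold" in values:
        seg_kwargs["fixed_threshold"] = values["fixed_threshold"]
        seg_kwargs.setdefault("threshold_method", "fixed")
    for src, dst in (
        ("morph_iterations", "morph_iterations"),
        ("structuring_element", "structuring_element"),
        ("watershed", "watershed_enabled"),
        ("maxima_merge_radius", "maxima_merge_radius"),
        ("connectivity", "connectivity"),
        ("exclude_edges", "exclude_edges"),
    ):
        if src in values:
            seg_kwargs[dst] = values[src]
    try:
        seg = SegmentationConfig(**seg_kwargs)
        red = FilterConfig(
            area_min=values.get("red_area_min", RED_FILTER.area_min),
            area_max=values.get("red_area_max", RED_FILTER.area_max),
            circ_min=values.get("circ_min", RED_FILTER.circ_min),
            circ_max=values.get("circ_max", RED_FILTER.circ_max),
        )
        green = FilterConfig(
            area_min=values.get("green_area_min", GREEN_FILTER.area_min),
            area_max=values.get("green_area_max", GREEN_FILTER.area_max),
            circ_min=values.get("circ_min", GREEN_FILTER.circ_min),
            circ_max=values.get("circ_max", GREEN_FILTER.circ_max),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    cfg = RunConfig(
        input_dir=Path(str(values.get("input_dir", "."))),
        output_dir=Path(str(values.get("output_dir", "pollenvia_out"))),
        red_filter=red,
        green_filter=green,
        seg=seg,
        emit_annotated=bool(values.get("emit_annotated", True)),
        table_format=str(values.get("table_format", "tsv")),
        log_level=str(values.get("log_level", "INFO")),
    )
    logger.info("effective configuration: %s", cfg)
    return cfg
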