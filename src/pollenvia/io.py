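"""Reading micrographs, discovering batch inputs, and writing pipeline outputs.

The pipeline produces two artefacts per run: a plain-text counts table
(one row per image, with the red-channel and green-channel grain counts)
and, per input image, two annotated overlays in which counted grains are
painted cyan and discarded structures black on a white background.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ImageDecodeError

logger = logging.getLogger(__name__)

#: File suffixes treated as images during batch discovery.
DEFAULT_EXTENSIONS = (".jpg", ".jpeg", ".png", ".tif", ".tiff")

#: Overlay palette: counted grains, discarded structures, background.
CYAN = (0, 255, 255)
BLACK = (0, 0, 0)
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB micrograph plus the identifier of its source file."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 intensities, got {px.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class CountTableRow:
    """Per-image grain counts: total (red channel) and viable (green)."""

    image_id: str
    red_count: int
    green_count: int

    def __post_init__(self) -> None:
        if self.red_count < 0 or self.green_count < 0:
            raise ValueError("counts must be non-negative")


def read_rgb_image(path: str | Path) -> RgbImage:
    """Read a color micrograph from ``path`` as an :class:`RgbImage`.

    Grayscale sources are promoted to three identical channels with a
    logged warning; an alpha channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ImageDecodeError(f"cannot decode image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        logger.warning("grayscale input %s promoted to 3 identical channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageDecodeError(f"unsupported image layout {arr.shape}: {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return RgbImage(pixels=arr, source_id=path.name)


def discover_batch(
    directory: str | Path, extensions: Sequence[str] = DEFAULT_EXTENSIONS
) -> list[Path]:
    """List image files in ``directory`` in lexicographic order.

    Non-image files are skipped; the ordering is deterministic so batch
    tables are reproducible across runs and filesystems.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    suffixes = {e.lower() for e in extensions}
    return sorted(
        p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in suffixes
    )


def write_count_table(
    rows: Iterable[CountTableRow], path: str | Path, format: str = "tsv"
) -> None:
    """Write per-image counts as a delimited text table with a header."""
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown table format: {format!r}")
    delim = "\t" if format == "tsv" else ","
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["image_id", "red_count", "green_count"])
        for row in rows:
            writer.writerow([row.image_id, row.red_count, row.green_count])


def read_count_table(path: str | Path, format: str = "tsv") -> list[CountTableRow]:
    """Parse a table written by :func:`write_count_table`."""
    delim = "\t" if format == "tsv" else ","
    rows: list[CountTableRow] = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        if header != ["image_id", "red_count", "green_count"]:
            raise ValueError(f"unexpected count-table header: {header}")
        for rec in reader:
            rows.append(CountTableRow(rec[0], int(rec[1]), int(rec[2])))
    return rows


def render_annotated(kept: np.ndarray, discarded: np.ndarray) -> np.ndarray:
    """Render the overlay: kept particles cyan, discarded black, rest white.

    ``kept`` is a labeled mask (0 = background) or boolean mask; ``discarded``
    is a boolean mask of rejected foreground. Kept pixels win where the two
    overlap, so a particle is never painted half-and-half.
    """
    kept = np.asarray(kept)
    discarded = np.asarray(discarded, dtype=bool)
    if kept.shape != discarded.shape:
        raise ValueError(
            f"mask dimensions differ: kept {kept.shape} vs discarded {discarded.shape}"
        )
    out = np.full(kept.shape + (3,), 255, dtype=np.uint8)
    out[discarded] = BLACK
    out[kept > 0] = CYAN
    return out


def write_annotated_image(
    kept: np.ndarray, discarded: np.ndarray, path: str | Path
) -> None:
    """Write the cyan/black/white overlay for one channel to ``path``."""
    iio.imwrite(Path(path), render_annotated(kept, discarded))
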