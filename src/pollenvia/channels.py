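"""RGB channel separation.

After Alexander's modified staining, the three dyes project very
differently onto the primary color channels: malachite green (pollen-wall
cellulose, present in every grain) darkens the red channel, while acid
fuchsin (protoplasm, present only in viable grains) darkens the green
channel. The red channel therefore carries total-grain information and
the green channel viable-grain information; the blue channel (dominated
by the orange G counterstain) is discarded. No color-space transform is
applied — channels are the raw planes of the RGB raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RgbImage


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel grayscale plane extracted from an RGB micrograph."""

    pixels: np.ndarray
    channel_name: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError(f"expected H×W pixels, got shape {self.pixels.shape}")
        if self.channel_name not in ("red", "green", "blue"):
            raise ValueError(f"unknown channel name: {self.channel_name!r}")


def split_channels(img: RgbImage) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split an RGB image into its red, green and blue grayscale planes."""
    names = ("red", "green", "blue")
    return tuple(
        ChannelImage(np.ascontiguousarray(img.pixels[:, :, i]), names[i], img.source_id)
        for i in range(3)
    )


def select_counting_channels(img: RgbImage) -> tuple[ChannelImage, ChannelImage]:
    """Return the (red, green) channel pair used for counting.

    Red drives total-grain counting, green viable-grain counting; blue is
    dropped.
    """
    red, green, _ = split_channels(img)
    return red, green


def recombine(red: ChannelImage, green: ChannelImage, blue: ChannelImage) -> RgbImage:
    """Stack three channel planes back into an RGB image (split inverse)."""
    px = np.stack([red.pixels, green.pixels, blue.pixels], axis=-1)
    return RgbImage(pixels=px.astype(np.uint8), source_id=red.source_id)


def rescale_linear(ch: ChannelImage, low: int, high: int) -> ChannelImage:
    """Optional linear contrast hook mapping [low, high] onto [0, 255].

    Off by default in the pipeline: contrast and saturation are assumed
    to have been set at acquisition time.
    """
    if not 0 <= low < high <= 255:
        raise ValueError("need 0 <= low < high <= 255")
    px = (ch.pixels.astype(np.float64) - low) * (255.0 / (high - low))
    px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return ChannelImage(px, ch.channel_name, ch.source_id)
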