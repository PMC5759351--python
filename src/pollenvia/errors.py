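"""Exception hierarchy for the pollenvia package."""


class PollenviaError(Exception):
    """Base class for all package-specific errors."""


class ImageDecodeError(PollenviaError):
    """An input file could not be decoded as an image."""


class DegenerateHistogramError(PollenviaError):
    """Automatic thresholding is undefined, e.g. on a constant image."""


class UndefinedViabilityError(PollenviaError):
    """A viability ratio has a zero denominator (no grains counted)."""


class PlacementError(PollenviaError):
    """Synthetic-scene generation could not place all requested grains."""


class ConfigError(PollenviaError):
    """A run-configuration file contains an unknown key or a bad value."""
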