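"""Packaged reference data.

The package ships a small table of published sample-level APV values
(mean ± SD across inflorescences) with their categorical viability
ratings for 111 grapevine accessions surveyed in a germplasm
collection. It serves as a fixture for checking that the rating bins
reproduce the published labels; the means are stored as printed and are
not recomputed here.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .viability import Rating

__all__ = ["load_reference_apv"]

_RATING_FROM_LABEL = {
    "Very low": Rating.VERY_LOW,
    "Low": Rating.LOW,
    "Medium": Rating.MEDIUM,
    "High": Rating.HIGH,
    "Very high": Rating.VERY_HIGH,
}


def load_reference_apv() -> pd.DataFrame:
    """Load the packaged APV reference table.

    Columns: plot_code, cultivar, main_use, skin_color, apv_mean,
    apv_sd, rating (printed label) and rating_enum (:class:`Rating`).
    """
    path = files("pollenvia.data").joinpath("icvv_apv_2015.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["rating_enum"] = df["rating"].map(_RATING_FROM_LABEL)
    if df["rating_enum"].isna().any():
        raise ValueError("reference table contains an unknown rating label")
    return df
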