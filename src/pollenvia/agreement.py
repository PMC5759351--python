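"""Method-agreement statistics: OLS regression, Bland–Altman, Welch t-test.

These are the validation statistics used to compare automatic counts
against a manual (or ground-truth) reference: an ordinary least-squares
fit of automatic on manual counts with its R², Bland–Altman limits of
agreement on the paired differences, and a two-sample t-test on
viability percentages. The Welch (unequal-variance) t-test is the
default; the pooled-variance variant is available via ``equal_var``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedCounts",
    "AgreementReport",
    "linear_fit",
    "bland_altman",
    "compare_viability_means",
    "agreement_report",
    "write_agreement_report",
    "plot_agreement",
]

#: Limits-of-agreement multiplier (standard Bland–Altman 95% interval).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedCounts:
    """One image's manual and automatic counts of the same quantity."""

    image_id: str
    manual: float
    automatic: float

    def __post_init__(self) -> None:
        if self.manual < 0 or self.automatic < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AgreementReport:
    """Regression and Bland–Altman summary for one paired comparison."""

    slope: float
    intercept: float
    r_squared: float
    mean_difference: float
    loa_low: float
    loa_high: float
    n: int


def _to_arrays(pairs: Sequence[PairedCounts]) -> tuple[np.ndarray, np.ndarray]:
    manual = np.array([p.manual for p in pairs], dtype=np.float64)
    automatic = np.array([p.automatic for p in pairs], dtype=np.float64)
    return manual, automatic


def linear_fit(pairs: Sequence[PairedCounts]) -> tuple[float, float, float]:
    """OLS of automatic on manual counts: (slope, intercept, R²)."""
    if len(pairs) < 3:
        raise ValueError("linear fit needs at least 3 pairs")
    manual, automatic = _to_arrays(pairs)
    if np.var(manual) == 0:
        raise ValueError("manual counts have zero variance; fit is degenerate")
    res = stats.linregress(manual, automatic)
    ss_res = float(np.sum((automatic - (res.slope * manual + res.intercept)) ** 2))
    ss_tot = float(np.sum((automatic - automatic.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(res.slope), float(res.intercept), r_squared


def bland_altman(pairs: Sequence[PairedCounts]) -> tuple[float, float, float]:
    """Bland–Altman agreement: (mean difference, LoA low, LoA high).

    Differences are automatic − manual; limits of agreement are
    mean ± 1.96 × sample SD (n−1 denominator).
    """
    if len(pairs) < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    manual, automatic = _to_arrays(pairs)
    d = automatic - manual
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_d, mean_d - LOA_MULTIPLIER * sd, mean_d + LOA_MULTIPLIER * sd


def compare_viability_means(
    mpv_values: Sequence[float],
    apv_values: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test on viability percentages.

    Welch's unequal-variance test by default; set ``equal_var=True`` for
    the pooled-variance (Student) variant.
    """
    a = np.asarray(mpv_values, dtype=np.float64)
    b = np.asarray(apv_values, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups are constant; t statistic is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def agreement_report(pairs: Sequence[PairedCounts]) -> AgreementReport:
    """Full agreement summary: OLS fit plus Bland–Altman limits."""
    slope, intercept, r2 = linear_fit(pairs)
    mean_d, lo, hi = bland_altman(pairs)
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mean_difference=mean_d,
        loa_low=lo,
        loa_high=hi,
        n=len(pairs),
    )


def write_agreement_report(
    reports: dict[str, AgreementReport], path: str | Path
) -> None:
    """Write one or more named agreement reports as a TSV table."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["comparison", "n", "slope", "intercept", "r_squared",
             "mean_difference", "loa_low", "loa_high"]
        )
        for name, rep in reports.items():
            writer.writerow(
                [name, rep.n, f"{rep.slope:.6f}", f"{rep.intercept:.6f}",
                 f"{rep.r_squared:.6f}", f"{rep.mean_difference:.6f}",
                 f"{rep.loa_low:.6f}", f"{rep.loa_high:.6f}"]
            )


def plot_agreement(
    pairs: Sequence[PairedCounts], report: AgreementReport, path: str | Path,
    title: str = "",
) -> None:
    """Scatter + Bland–Altman panel figure saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manual, automatic = _to_arrays(pairs)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(manual, automatic, s=12, alpha=0.7)
    grid = np.linspace(manual.min(), manual.max(), 50)
    ax1.plot(grid, report.slope * grid + report.intercept, "r-", label="fit")
    ax1.plot(grid, grid, "b-", lw=0.8, label="identity")
    ax1.set_xlabel("manual count")
    ax1.set_ylabel("automatic count")
    ax1.legend(frameon=False)
    ax1.set_title(f"R² = {report.r_squared:.3f}")

    mean_pair = (manual + automatic) / 2.0
    ax2.scatter(mean_pair, automatic - manual, s=12, alpha=0.7)
    ax2.axhline(report.mean_difference, color="r")
    ax2.axhline(report.loa_low, color="k")
    ax2.axhline(report.loa_high, color="k")
    ax2.set_xlabel("mean of methods")
    ax2.set_ylabel("automatic − manual")
    ax2.set_title("Bland–Altman")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
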