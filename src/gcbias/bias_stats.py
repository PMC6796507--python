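"""GC binning, the C_GC curve, the overall bias statistic and its regression.

Windows are binned by GC content at 0.5% resolution: a window with GC
``g`` percent joins the bin [label, label + width) with
label = floor(g / width) * width.  C_i is the unweighted mean relative
coverage of the windows in bin i.  The single-number summary of
GC-content-associated bias is

    B = sum_i n_i (C_i - Cbar)^2 / (n_T * N)        (mean_squared variant)

where Cbar is the genome-wide mean relative coverage, fixed at exactly 1 by
construction of relative coverage; n_i is the bin's window count, n_T the
total retained windows and N the number of non-empty bins.  The ``root``
variant is the square root of the same quantity; both order genomes and
library preparations identically (a monotone transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome_io import WindowRecord

C_BAR = 1.0  # mean relative coverage across the genome, by construction

_VARIANTS = ("mean_squared", "root")


@dataclass
class GCBinTable:
    """Windows aggregated by GC bin.

    gc_label holds the lower edge of each 0.5%-wide interval; only non-empty
    bins are stored, in increasing GC order.
    """

    gc_label: np.ndarray  # percent, lower bin edges
    n: np.ndarray  # window count per bin
    c: np.ndarray  # mean window relative coverage per bin (C_i)
    bin_width: float = 0.5

    def __post_init__(self) -> None:
        self.gc_label = np.asarray(self.gc_label, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.gc_label.size == self.n.size == self.c.size):
            raise ValueError("bin table columns must have equal length")
        if self.gc_label.size == 0:
            raise ValueError("bin table is empty")
        if (self.n < 1).any():
            raise ValueError("stored bins must be non-empty (n_i >= 1)")
        if (np.diff(self.gc_label) <= 0).any():
            raise ValueError("gc_label must be strictly increasing")

    @property
    def n_total(self) -> int:
        """n_T: total number of retained windows."""
        return int(self.n.sum())

    @property
    def n_bins(self) -> int:
        """N: number of analysed (non-empty) bins."""
        return int(self.gc_label.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gc_label": self.gc_label,
                "n_windows": self.n,
                "mean_relative_coverage": self.c,
            }
        )


@dataclass(frozen=True)
class BiasResult:
    """The overall GC-content-associated bias B with its provenance."""

    B: float
    variant: str
    mean_gc: float
    n_total: int
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "variant": self.variant,
            "mean_gc": self.mean_gc,
            "n_T": self.n_total,
            "N": self.n_bins,
        }


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of overall bias on genome mean GC."""

    slope: float
    intercept: float
    p_value_slope: float
    r_squared: float
    ci95_slope: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value_slope,
            "r2": self.r_squared,
            "ci95": list(self.ci95_slope),
        }


def bin_by_gc(
    windows: Sequence[WindowRecord], bin_width: float = 0.5
) -> GCBinTable:
    """Group windows into GC bins of ``bin_width`` percent and average coverage.

    Every window must have relative_coverage filled.  Empty bins are not
    stored.
    """
    if not windows:
        raise ValueError("no windows to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    gc = np.array([w.gc_percent for w in windows], dtype=float)
    rel = np.array(
        [
            math.nan if w.relative_coverage is None else w.relative_coverage
            for w in windows
        ],
        dtype=float,
    )
    if np.isnan(rel).any():
        raise ValueError("windows with unfilled relative_coverage")
    if np.isnan(gc).any():
        raise ValueError("windows with undefined GC content")
    # tiny epsilon guards against values like 30.499999999 from N-containing
    # windows landing one bin low; exact multiples of bin_width are unaffected
    labels = np.floor(gc / bin_width + 1e-9) * bin_width
    labels = np.round(labels, 10)
    order = np.argsort(labels, kind="stable")
    uniq, start_idx, counts = np.unique(
        labels[order], return_index=True, return_counts=True
    )
    sums = np.add.reduceat(rel[order], start_idx)
    return GCBinTable(
        gc_label=uniq, n=counts, c=sums / counts, bin_width=bin_width
    )


def cgc_curve(
    bins: GCBinTable, min_bin_fraction: float = 0.005
) -> pd.DataFrame:
    """The C_GC curve for display: (gc_label, C_i), rarest bins dropped.

    Bins holding fewer than ``min_bin_fraction`` of all windows are omitted,
    mirroring how extreme-GC bins are excluded from coverage-vs-GC figures.
    This is purely a reporting filter and is never applied to the bias
    statistic.
    """
    frac = bins.n / bins.n_total
    keep = frac >= min_bin_fraction
    return pd.DataFrame(
        {
            "gc_label": bins.gc_label[keep],
            "n_windows": bins.n[keep],
            "cgc": bins.c[keep],
            "bin_fraction": frac[keep],
        }
    )


def overall_bias(
    bins: GCBinTable,
    variant: str = "mean_squared",
    mean_gc: float = math.nan,
) -> BiasResult:
    """The overall GC-content-associated bias B of one genome/library.

    mean_squared: B = sum_i n_i (C_i - 1)^2 / (n_T N) over all stored bins.
    root: the square root of the mean_squared value.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {_VARIANTS}")
    ms = float(
        np.sum(bins.n * (bins.c - C_BAR) ** 2) / (bins.n_total * bins.n_bins)
    )
    b = math.sqrt(ms) if variant == "root" else ms
    return BiasResult(
        B=b,
        variant=variant,
        mean_gc=float(mean_gc),
        n_total=bins.n_total,
        n_bins=bins.n_bins,
    )


def bias_gc_regression(
    points: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS regression of overall bias B on genome mean GC (percent).

    Returns the slope (bias units per GC percent) with its classical
    two-sided t-test p-value and 95% confidence interval.
    """
    if len(points) < 3:
        raise ValueError("at least 3 (mean_gc, B) points are required")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: mean_gc identical across points")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value_slope=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
    )
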