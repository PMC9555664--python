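"""Breakpoint cross-correlation between the two species' annual series.

The Pearson correlation at lag 0 between paired annual means is computed
separately for the years strictly before a breakpoint (landfill closure)
and for the breakpoint year onward, summarizing the change in coupling
between the two species across the regime shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError


@dataclass(frozen=True)
class SplitCorrelation:
    breakpoint_year: int
    cc_before: float
    cc_after: float
    n_before: int
    n_after: int

    def report(self) -> dict:
        return {
            "breakpoint_year": int(self.breakpoint_year),
            "cc_before": float(self.cc_before),
            "n_before": int(self.n_before),
            "cc_after": float(self.cc_after),
            "n_after": int(self.n_after),
        }


def pearson_cc(a, b, method: str = "pearson") -> float:
    """Correlation at lag 0 between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-d and of equal length")
    if len(a) < 3:
        raise InsufficientDataError(f"need at least 3 paired values, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def split_cc(series_a, series_b, breakpoint_year: int,
             method: str = "pearson") -> SplitCorrelation:
    """Before/after correlations around a breakpoint year.

    The breakpoint year itself belongs to the "after" segment.  Accepts
    :class:`~eggsync.morphometrics.AnnualSeries` objects or (years, values)
    pairs with identical year axes.
    """
    years = np.asarray(series_a.years, dtype=int)
    if not np.array_equal(years, np.asarray(series_b.years, dtype=int)):
        raise ValueError("the two series cover different year ranges")
    a = np.asarray(series_a.mean_volume_cm3, dtype=float)
    b = np.asarray(series_b.mean_volume_cm3, dtype=float)

    before = years < breakpoint_year
    after = ~before
    for name, mask in (("before", before), ("after", after)):
        if mask.sum() < 3:
            raise InsufficientDataError(
                f"{name}-breakpoint segment has only {int(mask.sum())} year(s); need >= 3"
            )
    return SplitCorrelation(
        breakpoint_year=int(breakpoint_year),
        cc_before=pearson_cc(a[before], b[before], method),
        cc_after=pearson_cc(a[after], b[after], method),
        n_before=int(before.sum()),
        n_after=int(after.sum()),
    )
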