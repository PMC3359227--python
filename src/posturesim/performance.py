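"""Per-shift statistical performance of a sampling strategy.

For one shift, strategy and posture variable, every candidate window yields
an estimate y of the true full-shift value M.  Performance is summarised by

* bias              B      = mu_y - M   (mu_y = mean of the window estimates)
* precision         s_y    = SD of the window estimates (n-1 denominator)
* dispersion limits D_2.5  = P_2.5  - M,   D_97.5 = P_97.5 - M

where P_2.5 / P_97.5 are the empirical 2.5th/97.5th percentiles of the
window-estimate distribution: 95% of single-window estimates fall between
M + D_2.5 and M + D_97.5, so the D limits combine bias and imprecision in
one empirical measure.  With a single window (window = whole shift) the
spread statistics are undefined and reported as NaN.

Across a population of shifts the per-shift values are compared as
empirical cumulative distribution curves, and their medians/means feed a
bias-correction lookup table per (strategy, variable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import DEFAULT_SECTORS
from .recording import ShiftRecording
from .windows import (
    SamplingStrategy,
    WindowExceedsShiftError,
    enumerate_windows,
    window_matrix,
)

__all__ = [
    "CORE_VARIABLES",
    "ECDFCurve",
    "PerformanceRecord",
    "ecdf_across_shifts",
    "median_bias_table",
    "performance_record",
    "population_performance",
    "true_value",
    "window_values",
]

logger = logging.getLogger(__name__)

#: The four posture variables of the canonical study design.
CORE_VARIABLES: tuple[str, ...] = ("p10", "p50", "p90", "range_10_90")

_QUANTILES = {"p10": 0.10, "p50": 0.50, "p90": 0.90}


def _evaluate(
    mat: np.ndarray, variable: str, sectors: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    """Variable value for each row of a (n, samples) angle matrix."""
    if variable in _QUANTILES:
        return np.quantile(mat, _QUANTILES[variable], axis=1)
    if variable == "range_10_90":
        p10, p90 = np.quantile(mat, [0.10, 0.90], axis=1)
        return p90 - p10
    if variable == "mean_angle":
        return mat.mean(axis=1)
    if variable.startswith("sector_"):
        name = variable[len("sector_") :]
        if name not in sectors:
            raise ValueError(f"unknown sector {name!r}; defined sectors: {sorted(sectors)}")
        lo, hi = sectors[name]
        mask = (mat >= lo) & (mat < hi)
        if hi == 180.0:
            mask |= mat == 180.0
        return mask.mean(axis=1)
    raise ValueError(
        f"unknown variable {variable!r}; expected p10/p50/p90/range_10_90/"
        f"mean_angle or sector_<name>"
    )


def window_values(
    shift: ShiftRecording,
    strategy: SamplingStrategy,
    variable: str,
    sectors: Mapping[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """The chosen variable evaluated on every window, in start order."""
    return _evaluate(window_matrix(shift, strategy), variable, sectors or DEFAULT_SECTORS)


def true_value(
    shift: ShiftRecording,
    variable: str,
    sectors: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """The full-shift ('true') value M of the chosen variable."""
    return float(
        _evaluate(shift.angles[np.newaxis, :], variable, sectors or DEFAULT_SECTORS)[0]
    )


@dataclass(frozen=True)
class PerformanceRecord:
    """Performance of one (shift, strategy, variable) cell."""

    subject_id: str
    shift_id: str
    strategy: SamplingStrategy
    variable: str
    M: float
    n_windows: int
    mu_y: float
    s_y: float
    B: float
    P2_5: float
    P97_5: float
    D2_5: float
    D97_5: float


def performance_record(
    shift: ShiftRecording,
    strategy: SamplingStrategy,
    variable: str,
    sectors: Mapping[str, tuple[float, float]] | None = None,
) -> PerformanceRecord:
    """Compute all performance statistics for one shift x strategy x variable."""
    y = window_values(shift, strategy, variable, sectors)
    m = true_value(shift, variable, sectors)
    n = y.size
    mu = float(y.mean())
    if n > 1:
        s = float(y.std(ddof=1))
        p_lo, p_hi = (float(v) for v in np.quantile(y, [0.025, 0.975]))
    else:
        s = p_lo = p_hi = math.nan
    return PerformanceRecord(
        subject_id=shift.subject_id,
        shift_id=shift.shift_id,
        strategy=strategy,
        variable=variable,
        M=m,
        n_windows=int(n),
        mu_y=mu,
        s_y=s,
        B=mu - m,
        P2_5=p_lo,
        P97_5=p_hi,
        D2_5=p_lo - m,
        D97_5=p_hi - m,
    )


def population_performance(
    shifts: Iterable[ShiftRecording],
    strategies: Sequence[SamplingStrategy],
    variables: Sequence[str] = CORE_VARIABLES,
    *,
    sectors: Mapping[str, tuple[float, float]] | None = None,
    policy: str = "skip",
) -> list[PerformanceRecord]:
    """Records for every shift x strategy x variable cell.

    ``policy="skip"`` drops (with a logged warning) cells whose window is
    longer than the shift — the analog of excluding too-short shifts;
    ``policy="strict"`` raises instead.
    """
    if policy not in ("skip", "strict"):
        raise ValueError(f"policy must be 'skip' or 'strict', got {policy!r}")
    records: list[PerformanceRecord] = []
    for shift in shifts:
        for strategy in strategies:
            try:
                enumerate_windows(shift, strategy)
            except WindowExceedsShiftError:
                if policy == "strict":
                    raise
                logger.warning(
                    "skipping shift %s/%s (%d min) for %d-min windows",
                    shift.subject_id,
                    shift.shift_id,
                    shift.duration_min,
                    strategy.window_duration_min,
                )
                continue
            mat = window_matrix(shift, strategy)
            full = shift.angles[np.newaxis, :]
            secs = sectors or DEFAULT_SECTORS
            for variable in variables:
                y = _evaluate(mat, variable, secs)
                m = float(_evaluate(full, variable, secs)[0])
                n = y.size
                mu = float(y.mean())
                if n > 1:
                    s = float(y.std(ddof=1))
                    p_lo, p_hi = (float(v) for v in np.quantile(y, [0.025, 0.975]))
                else:
                    s = p_lo = p_hi = math.nan
                records.append(
                    PerformanceRecord(
                        shift.subject_id,
                        shift.shift_id,
                        strategy,
                        variable,
                        M=m,
                        n_windows=int(n),
                        mu_y=mu,
                        s_y=s,
                        B=mu - m,
                        P2_5=p_lo,
                        P97_5=p_hi,
                        D2_5=p_lo - m,
                        D97_5=p_hi - m,
                    )
                )
    return records


def records_to_frame(records: Iterable[PerformanceRecord]) -> pd.DataFrame:
    """Long-format table, one row per shift x strategy x variable."""
    rows = [
        {
            "subject_id": r.subject_id,
            "shift_id": r.shift_id,
            "window_duration_min": r.strategy.window_duration_min,
            "step_min": r.strategy.step_min,
            "variable": r.variable,
            "M": r.M,
            "n_windows": r.n_windows,
            "mu_y": r.mu_y,
            "s_y": r.s_y,
            "B": r.B,
            "P2_5": r.P2_5,
            "P97_5": r.P97_5,
            "D2_5": r.D2_5,
            "D97_5": r.D97_5,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ECDFCurve:
    """Empirical CDF of a per-shift statistic: step heights i/n."""

    values: np.ndarray
    probabilities: np.ndarray

    def median(self) -> float:
        """Median under the package-wide quantile convention."""
        return float(np.quantile(self.values, 0.5))


def ecdf_across_shifts(
    records: Sequence[PerformanceRecord], statistic: str
) -> ECDFCurve:
    """ECDF of one statistic (B, s_y, D2_5, D97_5, mu_y or M) across shifts."""
    if statistic not in ("B", "s_y", "D2_5", "D97_5", "M", "mu_y"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(records) == 0:
        raise ValueError("ecdf_across_shifts requires at least one record")
    values = np.sort(np.asarray([getattr(r, statistic) for r in records], dtype=float))
    n = values.size
    return ECDFCurve(values=values, probabilities=np.arange(1, n + 1) / n)


def median_bias_table(records: Iterable[PerformanceRecord]) -> pd.DataFrame:
    """Median and mean per-shift bias per (window duration, variable).

    Subtracting the tabulated median bias from a single-window estimate is
    the simple correction usable when true full-shift values are not
    available for calibration.
    """
    frame = records_to_frame(records)
    if frame.empty:
        return pd.DataFrame(
            columns=["window_duration_min", "variable", "median_bias", "mean_bias", "n_shifts"]
        )
    out = (
        frame.groupby(["window_duration_min", "variable"], sort=True)["B"]
        .agg(median_bias="median", mean_bias="mean", n_shifts="size")
        .reset_index()
    )
    return out
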