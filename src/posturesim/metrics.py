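"""Posture exposure summary variables.

The standard amplitude-distribution description of a postural exposure
(Jonsson's convention) uses the 10th percentile for 'static'/neutral
exposure, the 50th for average exposure, the 90th for 'peak' exposure, and
the 10th-90th percentile range as an amplitude-of-variation measure.  Time
proportions in named angle sectors (e.g. neutral < 20°, elevated > 60°)
are the usual alternative.

All quantiles in this package use one convention: linear interpolation
between order statistics at rank ``1 + q * (n - 1)`` (numpy's default
``"linear"`` method), applied identically to posture percentiles and to
the dispersion-limit percentiles of sample estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_SECTORS",
    "ExposureSummary",
    "percentile",
    "sector_proportion",
    "summarize",
]

#: Default angle sectors (degrees), a partition of [0, 180]: neutral and
#: elevated thresholds at 20° and 60° as commonly used for the upper arm.
DEFAULT_SECTORS: dict[str, tuple[float, float]] = {
    "neutral": (0.0, 20.0),
    "intermediate": (20.0, 60.0),
    "elevated": (60.0, 180.0),
}


@dataclass(frozen=True)
class ExposureSummary:
    """The posture variables of one angle sequence (shift or window)."""

    p10: float
    p50: float
    p90: float
    range_10_90: float
    mean_angle: float
    sector_proportions: Mapping[str, float]


def _as_angles(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("angles must be a non-empty 1-D sequence")
    return a


def percentile(angles, q: float) -> float:
    """q-quantile (q in [0, 1]) under the package's interpolation convention.

    Linear interpolation between order statistics at rank ``1 + q*(n-1)``.
    """
    a = _as_angles(angles)
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(a, q))


def sector_proportion(angles, lower: float, upper: float) -> float:
    """Fraction of samples with angle in ``[lower, upper)`` degrees.

    The half-open convention lets adjacent sectors tile [0°, 180°] without
    double counting; as the single exception, ``upper == 180`` is treated
    as closed so the top sector of a partition captures angles clamped to
    the physical maximum.
    """
    a = _as_angles(angles)
    if not lower < upper:
        raise ValueError(f"sector bounds must satisfy lower < upper, got [{lower}, {upper})")
    mask = (a >= lower) & (a < upper)
    if upper == 180.0:
        mask |= a == 180.0
    return float(mask.mean())


def summarize(
    angles, sectors: Mapping[str, tuple[float, float]] | None = None
) -> ExposureSummary:
    """Full exposure summary: p10/p50/p90, their range, mean, sector times."""
    a = _as_angles(angles)
    if sectors is None:
        sectors = DEFAULT_SECTORS
    p10, p50, p90 = (float(v) for v in np.quantile(a, [0.10, 0.50, 0.90]))
    props = {name: sector_proportion(a, lo, hi) for name, (lo, hi) in sectors.items()}
    return ExposureSummary(
        p10=p10,
        p50=p50,
        p90=p90,
        range_10_90=p90 - p10,
        mean_angle=float(a.mean()),
        sector_proportions=props,
    )
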