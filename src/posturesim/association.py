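"""Rank correlations between true exposure and sampling error.

Across the shifts of a population, the true full-shift value M of a
posture variable is correlated (Spearman) with the per-shift bias B and
with the per-shift estimate SD s_y, for each sampling strategy.  A
positive M-vs-B correlation means higher-exposure shifts incur larger
positive bias, i.e. the sampling error is exposure-dependent — the
situation in which a single overall bias correction is only approximate.

Confidence intervals use the Fisher z transform: arctanh(rho) +/-
z_{1-alpha/2}/sqrt(n-3), back-transformed with tanh.  Ties get average
ranks; no tie correction is applied to the denominator (with continuous
exposure values ties are improbable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .performance import PerformanceRecord

__all__ = [
    "CorrelationResult",
    "correlation_table",
    "correlations_to_frame",
    "fisher_ci",
    "spearman_rho",
]

logger = logging.getLogger(__name__)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D arrays, got {x.shape} vs {y.shape}")
    if x.size < 4:
        raise ValueError(f"need at least 4 pairs, got {x.size}")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("rank correlation undefined: one input is constant")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return max(-1.0, min(1.0, rho))


def fisher_ci(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"|rho| must be < 1 for a Fisher interval, got {rho}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z = math.atanh(rho)
    half_width = stats.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half_width), math.tanh(z + half_width)


@dataclass(frozen=True)
class CorrelationResult:
    """One cell of the correlation table."""

    window_duration_min: int
    variable: str
    pairing: str  # "M_vs_B" or "M_vs_sy"
    rho: float
    n: int
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


_PAIRINGS = {"M_vs_B": "B", "M_vs_sy": "s_y"}


def correlation_table(
    records: Iterable[PerformanceRecord],
    *,
    pairings: Sequence[str] = ("M_vs_B", "M_vs_sy"),
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """M-vs-B and M-vs-s_y Spearman correlations per strategy x variable.

    One result per (pairing, window duration, variable) cell present in the
    records; cells whose correlation is undefined (constant input, or fewer
    than 4 shifts with finite values) are logged and omitted.
    """
    for p in pairings:
        if p not in _PAIRINGS:
            raise ValueError(f"unknown pairing {p!r}; expected one of {sorted(_PAIRINGS)}")
    by_cell: dict[tuple[int, str], list[PerformanceRecord]] = {}
    for r in records:
        by_cell.setdefault((r.strategy.window_duration_min, r.variable), []).append(r)

    results: list[CorrelationResult] = []
    for (duration, variable), cell in sorted(by_cell.items()):
        m = np.asarray([r.M for r in cell], dtype=float)
        for pairing in pairings:
            y = np.asarray([getattr(r, _PAIRINGS[pairing]) for r in cell], dtype=float)
            ok = np.isfinite(m) & np.isfinite(y)
            try:
                rho = spearman_rho(m[ok], y[ok])
                ci_low, ci_high = fisher_ci(rho, int(ok.sum()), alpha)
            except ValueError as exc:
                logger.warning(
                    "correlation undefined for %s, %d min, %s: %s",
                    pairing,
                    duration,
                    variable,
                    exc,
                )
                continue
            results.append(
                CorrelationResult(
                    window_duration_min=duration,
                    variable=variable,
                    pairing=pairing,
                    rho=rho,
                    n=int(ok.sum()),
                    ci_low=ci_low,
                    ci_high=ci_high,
                    alpha=alpha,
                )
            )
    return results


def correlations_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Correlation table as a tidy frame (one row per cell)."""
    return pd.DataFrame(
        [
            {
                "pairing": r.pairing,
                "variable": r.variable,
                "window_duration_min": r.window_duration_min,
                "rho": r.rho,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": r.n,
                "significant": r.significant,
            }
            for r in results
        ]
    )
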