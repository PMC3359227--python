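"""Exhaustive consecutive sampling windows across a shift.

A sampling strategy is a window duration in whole minutes plus a step
between candidate start minutes.  The canonical strategies slide a 5, 10,
20, 40, 60, 120 or 240 min window across the shift at one-minute steps, so
a 480-min shift yields 471 ten-minute windows: minutes #1-10, #2-11, ...,
#471-480.  Minute indexing is 1-based and windows include both end
minutes; only whole windows entirely inside the shift are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .metrics import ExposureSummary, summarize
from .recording import ShiftRecording

__all__ = [
    "CANONICAL_DURATIONS",
    "SamplingStrategy",
    "WindowEstimate",
    "WindowExceedsShiftError",
    "canonical_strategies",
    "enumerate_windows",
    "sample_estimates",
    "window_matrix",
]

#: The seven window durations (minutes) of the canonical study design.
CANONICAL_DURATIONS: tuple[int, ...] = (5, 10, 20, 40, 60, 120, 240)


class WindowExceedsShiftError(ValueError):
    """Requested window duration exceeds the shift's recorded duration."""


@dataclass(frozen=True)
class SamplingStrategy:
    """Consecutive sampling of ``window_duration_min`` minutes, candidate
    start minutes every ``step_min`` minutes (1 = exhaustive sliding)."""

    window_duration_min: int
    step_min: int = 1

    def __post_init__(self) -> None:
        if int(self.window_duration_min) != self.window_duration_min or self.window_duration_min < 1:
            raise ValueError(
                f"window_duration_min must be a positive integer, got {self.window_duration_min}"
            )
        if int(self.step_min) != self.step_min or self.step_min < 1:
            raise ValueError(f"step_min must be a positive integer, got {self.step_min}")


def canonical_strategies(step_min: int = 1) -> list[SamplingStrategy]:
    return [SamplingStrategy(d, step_min) for d in CANONICAL_DURATIONS]


@dataclass(frozen=True)
class WindowEstimate:
    """Exposure summary of one sampling window (1-based start minute)."""

    start_minute: int
    strategy: SamplingStrategy
    summary: ExposureSummary


def enumerate_windows(shift: ShiftRecording, strategy: SamplingStrategy) -> np.ndarray:
    """1-based start minutes of every whole window inside the shift.

    With step 1 there are exactly ``duration_min - window_duration_min + 1``
    starts.  Raises :class:`WindowExceedsShiftError` if the window is longer
    than the shift (the analog of excluding too-short shifts).
    """
    w = strategy.window_duration_min
    if w > shift.duration_min:
        raise WindowExceedsShiftError(
            f"window of {w} min exceeds shift {shift.subject_id}/{shift.shift_id} "
            f"of {shift.duration_min} min"
        )
    return np.arange(1, shift.duration_min - w + 2, strategy.step_min)


def window_matrix(shift: ShiftRecording, strategy: SamplingStrategy) -> np.ndarray:
    """All window sample vectors as a read-only (n_windows, w*rate) view."""
    starts = enumerate_windows(shift, strategy)
    w_samples = strategy.window_duration_min * shift.sample_rate
    view = sliding_window_view(shift.angles, w_samples)
    return view[(starts - 1) * shift.sample_rate]


def sample_estimates(
    shift: ShiftRecording,
    strategy: SamplingStrategy,
    sectors: Mapping[str, tuple[float, float]] | None = None,
) -> list[WindowEstimate]:
    """Exposure summary of every window, in start-minute order."""
    starts = enumerate_windows(shift, strategy)
    mat = window_matrix(shift, strategy)
    return [
        WindowEstimate(int(start), strategy, summarize(row, sectors))
        for start, row in zip(starts, mat)
    ]
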