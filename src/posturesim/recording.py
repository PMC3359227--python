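"""Full-shift posture recordings.

A :class:`ShiftRecording` is the unit of analysis everywhere in this
package: one work shift's upper-arm elevation angle time series (degrees,
0° = arm hanging vertically), tagged with subject and shift identity and a
sampling rate in samples per minute.  Recordings always span whole minutes
so that minute-aligned sampling windows tile them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ShiftRecording"]


@dataclass(frozen=True)
class ShiftRecording:
    """One shift's arm-elevation time series.

    Parameters
    ----------
    subject_id, shift_id
        Opaque labels identifying the worker and the measured shift.
    sample_rate
        Samples per minute (positive integer).
    angles
        Elevation angles in degrees, all within [0, 180].  The length must
        be a whole number of minutes, i.e. a multiple of ``sample_rate``.
    """

    subject_id: str
    shift_id: str
    sample_rate: int
    angles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if int(self.sample_rate) != self.sample_rate or self.sample_rate < 1:
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate}")
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if angles.size % self.sample_rate != 0:
            raise ValueError(
                f"recording length {angles.size} is not a whole number of minutes "
                f"at {self.sample_rate} samples/min"
            )
        if np.any(angles < 0.0) or np.any(angles > 180.0):
            bad = int(np.flatnonzero((angles < 0.0) | (angles > 180.0))[0])
            raise ValueError(
                f"angle out of physical range [0, 180] at sample {bad}: {angles[bad]!r}"
            )
        angles.setflags(write=False)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_min(self) -> int:
        """Recording duration in whole minutes."""
        return self.angles.size // self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.angles.size

    def minute_slice(self, first_minute: int, last_minute: int) -> np.ndarray:
        """Samples of the inclusive 1-based minute span ``first..last``."""
        if not (1 <= first_minute <= last_minute <= self.duration_min):
            raise ValueError(
                f"minute span {first_minute}..{last_minute} outside shift of "
                f"{self.duration_min} min"
            )
        r = self.sample_rate
        return self.angles[(first_minute - 1) * r : last_minute * r]
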