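"""Synthetic full-shift arm-elevation generators.

Occupational arm-elevation recordings (e.g. from hairdressers) are far from
white noise: extended periods of elevated work with a customer alternate
with long near-neutral idle periods.  The generator here emulates that
structure with a two-state alternating-renewal process:

* the shift switches between an *elevated* regime and a *neutral* regime;
* dwell times in each regime are drawn from an exponential (default) or
  lognormal distribution with configurable means (minutes);
* within a regime, angles are Gaussian around the regime mean, and all
  angles are clamped to the physical range [0°, 180°].

Between-subject and between-shift variation in overall exposure level is
introduced through a per-shift exposure offset (degrees).  The offset is
applied as a proportional rescaling of both regime means and SDs, scaled so
that the shift's mean elevation moves by approximately the offset: busier
or more demanding shifts have both higher angles *and* a wider
elevated/neutral separation, which is what makes sampling bias
exposure-dependent (see docs/methods.md).

An iid generator is also provided: serially independent samples from a
uniform or truncated-normal law.  Iid series obey classical sampling theory
(e.g. the square-root-of-duration precision law) and therefore serve as the
analytic oracle against which the autocorrelated regime-switching series
are contrasted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .recording import ShiftRecording

__all__ = [
    "ShiftGenParams",
    "PopulationConfig",
    "generate_shift",
    "generate_iid_shift",
    "generate_population",
]


@dataclass(frozen=True)
class ShiftGenParams:
    """Parameters of the two-state regime-switching shift generator.

    Defaults are chosen to resemble full-shift hairdresser exposure:
    roughly equal time in elevated (customer) and neutral (idle) regimes
    with dwell times long relative to short sampling windows, elevated
    angles around 45° and neutral angles around 12°, giving full-shift
    10th/50th/90th percentiles in the single-digit/low-20s/mid-50s degree
    range typical of service work.
    """

    duration_min: int = 480
    sample_rate: int = 1
    elevated_dwell_mean: float = 12.0  # minutes with a customer
    neutral_dwell_mean: float = 12.0  # idle minutes between customers
    elevated_angle_mean: float = 45.0
    elevated_angle_sd: float = 15.0
    neutral_angle_mean: float = 12.0
    neutral_angle_sd: float = 8.0
    subject_offset: float = 0.0  # degrees; shift-level exposure level offset
    seed: int = 0
    dwell_distribution: str = "exponential"  # or "lognormal"
    dwell_cv: float = 1.0  # coefficient of variation, lognormal dwells only

    def __post_init__(self) -> None:
        if int(self.duration_min) != self.duration_min or self.duration_min < 1:
            raise ValueError(f"duration_min must be a positive integer, got {self.duration_min}")
        if int(self.sample_rate) != self.sample_rate or self.sample_rate < 1:
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate}")
        for name in ("elevated_dwell_mean", "neutral_dwell_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("elevated_angle_sd", "neutral_angle_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dwell_distribution not in ("exponential", "lognormal"):
            raise ValueError(
                f"dwell_distribution must be 'exponential' or 'lognormal', "
                f"got {self.dwell_distribution!r}"
            )
        if self.dwell_cv <= 0:
            raise ValueError(f"dwell_cv must be > 0, got {self.dwell_cv}")

    @property
    def baseline_mean_angle(self) -> float:
        """Dwell-weighted mean of the regime means (degrees), offset ignored."""
        total = self.elevated_dwell_mean + self.neutral_dwell_mean
        return (
            self.elevated_dwell_mean * self.elevated_angle_mean
            + self.neutral_dwell_mean * self.neutral_angle_mean
        ) / total

    @property
    def exposure_scale(self) -> float:
        """Multiplicative exposure factor implied by ``subject_offset``.

        1 + offset / baseline mean angle, floored at 0.05 so extreme
        negative offsets degrade gracefully instead of inverting angles.
        """
        base = self.baseline_mean_angle
        if base <= 0:
            return 1.0
        return max(0.05, 1.0 + self.subject_offset / base)


@dataclass(frozen=True)
class PopulationConfig:
    """A population of subjects, each contributing several shifts.

    ``composition`` lists ``(n_subjects, shifts_per_subject)`` blocks; the
    default reproduces the 73-shift / 20-subject layout of a full-week
    occupational measurement campaign (14 subjects with 4 shifts, 5 with 3,
    1 with 2).  Per-subject and per-shift exposure offsets are drawn from
    centred normals with the configured SDs and added before the base
    generator's own offset.
    """

    composition: Sequence[tuple[int, int]] = ((14, 4), (5, 3), (1, 2))
    duration_range: tuple[int, int] = (300, 595)
    between_subject_sd: float = 6.0
    between_shift_sd: float = 3.0
    base: ShiftGenParams = field(default_factory=ShiftGenParams)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "composition", tuple((int(a), int(b)) for a, b in self.composition)
        )
        object.__setattr__(self, "duration_range", tuple(self.duration_range))
        for n_subj, n_shifts in self.composition:
            if n_subj < 1 or n_shifts < 1:
                raise ValueError(f"composition entries must be positive, got {(n_subj, n_shifts)}")
        lo, hi = self.duration_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid duration_range {self.duration_range}")
        if self.between_subject_sd < 0 or self.between_shift_sd < 0:
            raise ValueError("between-subject/between-shift SDs must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(n for n, _ in self.composition)

    @property
    def n_shifts(self) -> int:
        return sum(n * s for n, s in self.composition)


def _dwell_sampler(params: ShiftGenParams, rng: np.random.Generator):
    if params.dwell_distribution == "exponential":
        return lambda mean: rng.exponential(mean)
    # lognormal with the requested mean and coefficient of variation
    sigma2 = math.log(1.0 + params.dwell_cv**2)
    sigma = math.sqrt(sigma2)

    def draw(mean: float) -> float:
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, sigma)

    return draw


def generate_shift(
    params: ShiftGenParams,
    *,
    subject_id: str = "S01",
    shift_id: str = "D1",
    return_states: bool = False,
):
    """Simulate one full shift of the alternating-renewal posture process.

    Returns a :class:`ShiftRecording` of exactly
    ``duration_min * sample_rate`` samples; with ``return_states=True``,
    additionally returns the boolean elevated-state indicator per sample.
    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.duration_min * params.sample_rate
    f = params.exposure_scale
    means = (params.neutral_angle_mean * f, params.elevated_angle_mean * f)
    sds = (params.neutral_angle_sd * f, params.elevated_angle_sd * f)
    dwell_means = (params.neutral_dwell_mean, params.elevated_dwell_mean)
    draw_dwell = _dwell_sampler(params, rng)

    # stationary start-state probability of the elevated regime
    p_elev = params.elevated_dwell_mean / (params.elevated_dwell_mean + params.neutral_dwell_mean)
    state = int(rng.random() < p_elev)

    angles = np.empty(n)
    states = np.empty(n, dtype=bool)
    pos = 0
    while pos < n:
        dwell_min = draw_dwell(dwell_means[state])
        seg = max(1, round(dwell_min * params.sample_rate))
        seg = min(seg, n - pos)
        if sds[state] > 0:
            angles[pos : pos + seg] = rng.normal(means[state], sds[state], seg)
        else:
            angles[pos : pos + seg] = means[state]
        states[pos : pos + seg] = bool(state)
        pos += seg
        state = 1 - state

    np.clip(angles, 0.0, 180.0, out=angles)
    rec = ShiftRecording(subject_id, shift_id, params.sample_rate, angles)
    if return_states:
        return rec, states
    return rec


_IID_DISTRIBUTIONS = ("uniform", "truncated_normal")


def generate_iid_shift(
    distribution: str,
    duration_min: int,
    sample_rate: int = 1,
    seed: int = 0,
    *,
    low: float = 0.0,
    high: float = 90.0,
    mean: float = 30.0,
    sd: float = 15.0,
    subject_id: str = "S01",
    shift_id: str = "D1",
) -> ShiftRecording:
    """Simulate a shift of serially independent angles.

    ``distribution`` is ``"uniform"`` on ``[low, high]`` or
    ``"truncated_normal"`` with the given ``mean``/``sd`` truncated to
    [0°, 180°] by rejection.  Deterministic per ``seed``.
    """
    if distribution not in _IID_DISTRIBUTIONS:
        raise ValueError(
            f"unsupported distribution {distribution!r}; expected one of {_IID_DISTRIBUTIONS}"
        )
    if duration_min < 1 or sample_rate < 1:
        raise ValueError("duration_min and sample_rate must be positive integers")
    rng = np.random.default_rng(seed)
    n = duration_min * sample_rate
    if distribution == "uniform":
        if not (0.0 <= low <= high <= 180.0):
            raise ValueError(f"uniform support [{low}, {high}] must lie within [0, 180]")
        angles = rng.uniform(low, high, n) if high > low else np.full(n, low)
    else:
        if sd < 0:
            raise ValueError(f"sd must be >= 0, got {sd}")
        angles = rng.normal(mean, sd, n)
        bad = (angles < 0.0) | (angles > 180.0)
        while np.any(bad):
            angles[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (angles < 0.0) | (angles > 180.0)
    return ShiftRecording(subject_id, shift_id, sample_rate, angles)


def _entity_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed: master seed + stable entity index."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def generate_population(config: PopulationConfig) -> list[ShiftRecording]:
    """Generate one recording per (subject, shift) slot of the composition.

    Subject offsets are drawn once per subject and shift offsets once per
    shift (normal, SDs from the config); durations are uniform integers on
    the configured range.  Entity index 0 seeds the population-level draws
    and shift slot *i* (in composition order) is seeded from entity index
    ``i + 1``, so any single shift can be regenerated in isolation.
    """
    pop_rng = np.random.default_rng(_entity_seed(config.seed, 0))
    lo, hi = config.duration_range

    recordings: list[ShiftRecording] = []
    shift_index = 0
    subject_index = 0
    for n_subj, shifts_per_subject in config.composition:
        for _ in range(n_subj):
            subject_index += 1
            subject_id = f"S{subject_index:02d}"
            subject_offset = pop_rng.normal(0.0, config.between_subject_sd)
            for day in range(1, shifts_per_subject + 1):
                shift_offset = pop_rng.normal(0.0, config.between_shift_sd)
                duration = int(pop_rng.integers(lo, hi + 1))
                params = replace(
                    config.base,
                    duration_min=duration,
                    subject_offset=config.base.subject_offset + subject_offset + shift_offset,
                    seed=_entity_seed(config.seed, shift_index + 1),
                )
                recordings.append(
                    generate_shift(params, subject_id=subject_id, shift_id=f"D{day}")
                )
                shift_index += 1
    return recordings
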