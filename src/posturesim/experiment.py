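"""End-to-end experiment driver.

Chains the generator, window sampler, performance statistics and
correlation analysis into one reproducible run: a population of recordings
(synthetic, or loaded from CSV) is filtered on a minimum shift duration,
every shift is resampled exhaustively under every strategy, and the result
bundle — performance table, ECDF curves, correlation table, median-bias
table, run log — is written as plain CSV/JSON.  All randomness derives
from a single master seed; identical configs reproduce identical CSVs.

Recording CSV schema (one row per sample)::

    subject_id, shift_id, minute_index, sample_index_within_minute, angle_deg

with ``minute_index`` and ``sample_index_within_minute`` 1-based and
contiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import DEFAULT_SECTORS
from .performance import (
    ecdf_across_shifts,
    median_bias_table,
    population_performance,
    records_to_frame,
)
from .association import correlation_table, correlations_to_frame
from .recording import ShiftRecording
from .simulate import PopulationConfig, ShiftGenParams, generate_population
from .windows import CANONICAL_DURATIONS, SamplingStrategy

__all__ = [
    "ExperimentConfig",
    "read_recordings",
    "run_experiment",
    "write_recordings",
]

logger = logging.getLogger(__name__)

_RECORDING_COLUMNS = [
    "subject_id",
    "shift_id",
    "minute_index",
    "sample_index_within_minute",
    "angle_deg",
]

_ECDF_STATISTICS = ("B", "s_y", "D2_5", "D97_5", "M")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one full simulated-sampling experiment."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    input_csv: str | None = None  # overrides the synthetic population if set
    strategy_durations: Sequence[int] = CANONICAL_DURATIONS
    step_min: int = 1
    variables: Sequence[str] = ("p10", "p50", "p90", "range_10_90")
    sectors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SECTORS)
    )
    min_duration_min: int = 300
    policy: str = "skip"  # or "strict"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(d) != d or d < 1 for d in self.strategy_durations):
            raise ValueError(
                f"strategy durations must be positive integers: {self.strategy_durations}"
            )
        object.__setattr__(
            self, "strategy_durations", tuple(int(d) for d in self.strategy_durations)
        )
        object.__setattr__(self, "variables", tuple(str(v) for v in self.variables))
        object.__setattr__(
            self,
            "sectors",
            {str(k): (float(v[0]), float(v[1])) for k, v in self.sectors.items()},
        )
        if self.policy not in ("skip", "strict"):
            raise ValueError(f"policy must be 'skip' or 'strict', got {self.policy!r}")
        if self.policy == "strict" and self.min_duration_min < max(self.strategy_durations):
            raise ValueError(
                "under the strict policy min_duration_min must cover the longest window "
                f"({max(self.strategy_durations)} min), got {self.min_duration_min}"
            )

    @property
    def strategies(self) -> list[SamplingStrategy]:
        return [SamplingStrategy(int(d), self.step_min) for d in self.strategy_durations]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["composition"] = [list(c) for c in self.population.composition]
        d["strategy_durations"] = [int(x) for x in self.strategy_durations]
        d["variables"] = list(self.variables)
        d["sectors"] = {k: list(v) for k, v in self.sectors.items()}
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        raw = dict(raw)
        if "population" in raw:
            pop = dict(raw["population"])
            if "base" in pop:
                pop["base"] = ShiftGenParams(**pop["base"])
            if "composition" in pop:
                pop["composition"] = [tuple(c) for c in pop["composition"]]
            if "duration_range" in pop:
                pop["duration_range"] = tuple(pop["duration_range"])
            raw["population"] = PopulationConfig(**pop)
        if "sectors" in raw:
            raw["sectors"] = {k: tuple(v) for k, v in raw["sectors"].items()}
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def write_recordings(recordings: Iterable[ShiftRecording], path: str | Path) -> None:
    """Write recordings to the documented long-format CSV schema."""
    frames = []
    for rec in recordings:
        r = rec.sample_rate
        n = rec.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "shift_id": rec.shift_id,
                    "minute_index": np.arange(n) // r + 1,
                    "sample_index_within_minute": np.arange(n) % r + 1,
                    "angle_deg": rec.angles,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class RecordingParseError(ValueError):
    """Recording CSV violates the documented schema."""


def read_recordings(path: str | Path) -> list[ShiftRecording]:
    """Read and validate a recording CSV; robust to shuffled row order."""
    frame = pd.read_csv(path)
    missing = [c for c in _RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing columns {missing}")
    angles = pd.to_numeric(frame["angle_deg"], errors="coerce")
    bad = frame.index[angles.isna()]
    if len(bad):
        raise RecordingParseError(f"{path}: non-numeric angle_deg at data row {bad[0]}")
    out_of_range = frame.index[(angles < 0) | (angles > 180)]
    if len(out_of_range):
        row = out_of_range[0]
        raise RecordingParseError(
            f"{path}: angle {angles[row]} outside [0, 180] at data row {row}"
        )
    frame = frame.assign(angle_deg=angles)

    recordings = []
    for (subject_id, shift_id), grp in frame.groupby(
        ["subject_id", "shift_id"], sort=True
    ):
        grp = grp.sort_values(["minute_index", "sample_index_within_minute"])
        rate = int(grp["sample_index_within_minute"].max())
        minutes = grp["minute_index"].to_numpy()
        within = grp["sample_index_within_minute"].to_numpy()
        n_min = int(minutes.max())
        expected_minutes = np.repeat(np.arange(1, n_min + 1), rate)
        expected_within = np.tile(np.arange(1, rate + 1), n_min)
        if (
            len(grp) != n_min * rate
            or not np.array_equal(minutes, expected_minutes)
            or not np.array_equal(within, expected_within)
        ):
            raise RecordingParseError(
                f"{path}: shift {subject_id}/{shift_id} has gaps or duplicates "
                f"in minute/sample indexing"
            )
        recordings.append(
            ShiftRecording(
                str(subject_id), str(shift_id), rate, grp["angle_deg"].to_numpy()
            )
        )
    return recordings


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full study and write the result bundle to ``out_dir``.

    Returns a mapping from artifact name to written path.  Outputs:
    ``population.csv`` (synthetic runs only), ``performance.csv``,
    ``ecdf_<statistic>.csv`` for B, s_y, D2_5, D97_5 and M,
    ``correlations.csv``, ``median_bias.csv`` and ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.input_csv is not None:
        shifts = read_recordings(config.input_csv)
        source = str(config.input_csv)
    else:
        pop = dataclasses.replace(config.population, seed=config.seed)
        shifts = generate_population(pop)
        source = "synthetic"
        paths["population"] = out / "population.csv"
        write_recordings(shifts, paths["population"])

    n_before = len(shifts)
    shifts = [s for s in shifts if s.duration_min >= config.min_duration_min]
    n_after = len(shifts)
    if n_after < n_before:
        logger.info(
            "duration filter (%d min): %d of %d shifts retained",
            config.min_duration_min,
            n_after,
            n_before,
        )
    if not shifts:
        raise ValueError(
            f"no shifts of at least {config.min_duration_min} min remain "
            f"(started with {n_before})"
        )

    records = population_performance(
        shifts,
        config.strategies,
        config.variables,
        sectors=config.sectors,
        policy=config.policy,
    )
    perf = records_to_frame(records)
    paths["performance"] = out / "performance.csv"
    perf.to_csv(paths["performance"], index=False)

    by_cell: dict[tuple[int, str], list] = {}
    for r in records:
        by_cell.setdefault((r.strategy.window_duration_min, r.variable), []).append(r)
    for statistic in _ECDF_STATISTICS:
        rows = []
        for (duration, variable), cell in sorted(by_cell.items()):
            finite = [r for r in cell if np.isfinite(getattr(r, statistic))]
            if not finite:
                continue
            curve = ecdf_across_shifts(finite, statistic)
            rows.append(
                pd.DataFrame(
                    {
                        "window_duration_min": duration,
                        "variable": variable,
                        "value": curve.values,
                        "cumulative_probability": curve.probabilities,
                    }
                )
            )
        key = f"ecdf_{statistic}"
        paths[key] = out / f"{key}.csv"
        pd.concat(rows, ignore_index=True).to_csv(paths[key], index=False)

    corr = correlations_to_frame(correlation_table(records))
    paths["correlations"] = out / "correlations.csv"
    corr.to_csv(paths["correlations"], index=False)

    paths["median_bias"] = out / "median_bias.csv"
    median_bias_table(records).to_csv(paths["median_bias"], index=False)

    log = {
        "tool": "posturesim",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "input_source": source,
        "n_shifts_before_filter": n_before,
        "n_shifts_after_filter": n_after,
        "n_performance_records": len(records),
        "n_correlation_cells": len(corr),
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return paths
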