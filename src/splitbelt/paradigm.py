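"""Belt-speed protocols for split-belt treadmill experiments.

A protocol is a stride-indexed schedule of left/right belt speeds with phase
and configuration labels. Ramp tasks change the right belt speed in exact
0.05 m/s increments every fixed number of strides; all speeds are represented
internally as integer multiples of 0.01 m/s so that schedule arithmetic
(configuration counts, grid membership, tied-belt endpoints) is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

#: internal grid resolution: speeds are integer multiples of 0.01 m/s
_GRID = 0.01

SCHEDULE_COLUMNS = ["stride_index", "phase", "config_index", "left_speed", "right_speed"]


def _to_grid(speed: float, name: str) -> int:
    """Convert a speed in m/s to integer centi-m/s, rejecting off-grid values."""
    units = speed / _GRID
    rounded = round(units)
    if abs(units - rounded) > 1e-9:
        raise ValueError(f"{name}={speed} m/s is not a multiple of {_GRID} m/s")
    if rounded < 0:
        raise ValueError(f"{name}={speed} m/s must be non-negative")
    return int(rounded)


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of a protocol: either a constant-speed block or a ramp.

    For a constant phase, give ``right_speed`` and ``n_strides``. For a ramp,
    give ``ramp=(start, end, step, strides_per_speed)`` for the right belt.
    The left belt speed is constant within a phase.
    """

    name: str
    left_speed: float
    right_speed: float | None = None
    n_strides: int | None = None
    ramp: tuple[float, float, float, int] | None = None

    def __post_init__(self):
        if (self.ramp is None) == (self.right_speed is None):
            raise ValueError("give exactly one of right_speed/n_strides or ramp")
        if self.ramp is None and (self.n_strides is None or self.n_strides < 1):
            raise ValueError("constant phase needs n_strides >= 1")


@dataclass
class BeltSpeedSchedule:
    """Per-stride belt speeds with phase and configuration labels.

    Wraps a tidy DataFrame with columns stride_index (1-based, contiguous),
    phase, config_index (1-based within phase), left_speed, right_speed.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        missing = [c for c in SCHEDULE_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"schedule table missing columns {missing}")
        idx = t["stride_index"].to_numpy()
        if len(idx) == 0 or idx[0] != 1 or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError("stride_index must be 1-based, strictly increasing, without gaps")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def phases(self) -> list[str]:
        """Phase names in order of first appearance."""
        return list(dict.fromkeys(self.table["phase"]))

    @property
    def speed_diff(self) -> np.ndarray:
        """Right minus left belt speed per stride (m/s)."""
        return (self.table["right_speed"] - self.table["left_speed"]).to_numpy()

    def phase_mask(self, phase: str) -> np.ndarray:
        mask = (self.table["phase"] == phase).to_numpy()
        if not mask.any():
            raise KeyError(f"phase {phase!r} not in schedule (has {self.phases})")
        return mask

    def phase_table(self, phase: str) -> pd.DataFrame:
        return self.table[self.phase_mask(phase)]

    def n_configs(self, phase: str) -> int:
        return int(self.phase_table(phase)["config_index"].max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeltSpeedSchedule":
        t = pd.read_csv(path)
        t["left_speed"] = _snap(t["left_speed"].to_numpy())
        t["right_speed"] = _snap(t["right_speed"].to_numpy())
        return cls(t[SCHEDULE_COLUMNS])

    @classmethod
    def concat(cls, parts: list[pd.DataFrame]) -> "BeltSpeedSchedule":
        t = pd.concat(parts, ignore_index=True)
        t["stride_index"] = np.arange(1, len(t) + 1)
        return cls(t)


def _units_to_speed(units) -> np.ndarray:
    """Integer centi-m/s to float m/s, exact on the 0.05 grid.

    Speeds that are multiples of 0.05 m/s are built as (units/5)/20 so that
    ``speed * 20`` round-trips to an exact integer in floating point.
    """
    units = np.asarray(units)
    return np.where(units % 5 == 0, (units // 5) / 20, units / 100)


def _snap(speeds: np.ndarray) -> np.ndarray:
    """Snap float speeds back onto the exact 0.01 m/s grid after round-trips."""
    units = np.round(np.asarray(speeds, dtype=float) / _GRID).astype(int)
    return _units_to_speed(units)


def _phase_frame(phase: str, config_index, left_units: int, right_units) -> pd.DataFrame:
    right_units = np.asarray(right_units)
    return pd.DataFrame(
        {
            "stride_index": np.arange(1, len(right_units) + 1),
            "phase": phase,
            "config_index": np.asarray(config_index, dtype=int),
            "left_speed": np.full(len(right_units), _units_to_speed(left_units)),
            "right_speed": _units_to_speed(right_units),
        }
    )


def build_ramp_schedule(
    start: float,
    end: float,
    step: float,
    strides_per_speed: int,
    left_speed: float,
    phase: str = "ramp",
) -> BeltSpeedSchedule:
    """Build a right-belt ramp from ``start`` to ``end`` m/s in exact steps.

    The right belt holds each speed for ``strides_per_speed`` strides and moves
    by ``step`` m/s between configurations (either direction). The number of
    configurations is |start − end|/step + 1; the range must divide evenly.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if strides_per_speed < 1:
        raise ValueError("strides_per_speed must be >= 1")
    s, e = _to_grid(start, "start"), _to_grid(end, "end")
    st = _to_grid(step, "step")
    left = _to_grid(left_speed, "left_speed")
    span = abs(s - e)
    if span % st != 0:
        raise ValueError(
            f"ramp range |{start} - {end}| = {span * _GRID:.2f} m/s is not divisible by "
            f"step {step} m/s (residue {span % st * _GRID:.2f} m/s)"
        )
    n_configs = span // st + 1
    direction = 1 if e >= s else -1
    config_speeds = s + direction * st * np.arange(n_configs)
    right = np.repeat(config_speeds, strides_per_speed)
    config_index = np.repeat(np.arange(1, n_configs + 1), strides_per_speed)
    return BeltSpeedSchedule(_phase_frame(phase, config_index, left, right))


def _constant_phase(phase: str, left: float, right: float, n: int) -> pd.DataFrame:
    lu, ru = _to_grid(left, "left_speed"), _to_grid(right, "right_speed")
    return _phase_frame(phase, np.ones(n, dtype=int), lu, np.full(n, ru))


# Protocol constants (m/s / strides). Speeds follow the experimental paradigms:
# baseline ramp 0.35->0.65, adaptation at right 1.5 / left 0.5, post-adaptation
# Ramp Down 1.5->0.5 (21 configs) or Ramp Up & Down 1.5->2.0 then 1.95->0.5
# (11 + 30 = 41 configs). Left belt fixed at 0.5 m/s in all ramp tasks.
RAMP_STEP = 0.05
STRIDES_PER_SPEED = 3
LEFT_SPEED = 0.5
ADAPT_RIGHT = 1.5
DEFAULT_ADAPTATION_STRIDES = 750  # ~15 min at a typical stride rate
DEFAULT_BASELINE_STRIDES = 120  # ~2 min tied-belt block


def build_protocol(
    experiment: Literal["exp1", "exp2"],
    adaptation_strides: int = DEFAULT_ADAPTATION_STRIDES,
    baseline_strides: int = DEFAULT_BASELINE_STRIDES,
) -> BeltSpeedSchedule:
    """Assemble the full stride schedule for Experiment 1 or 2.

    Both experiments share: tied baseline, baseline ramp (7 configs,
    0.35->0.65 m/s), second tied baseline, adaptation (right 1.5 / left
    0.5 m/s). They differ in the post-adaptation task: Exp 1 ramps the right
    belt down 1.5->0.5 m/s (phase ``ramp_down``); Exp 2 ramps up 1.5->2.0 then
    down 1.95->0.5 with no pause (single phase ``ramp_up_down``, 41 configs).
    """
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}; expected 'exp1' or 'exp2'")
    if adaptation_strides < 1:
        raise ValueError("adaptation_strides must be >= 1")
    parts = [
        _constant_phase("baseline_tied_1", LEFT_SPEED, LEFT_SPEED, baseline_strides),
        build_ramp_schedule(0.35, 0.65, RAMP_STEP, STRIDES_PER_SPEED, LEFT_SPEED, "baseline_ramp").table,
        _constant_phase("baseline_tied_2", LEFT_SPEED, LEFT_SPEED, baseline_strides),
        _constant_phase("adaptation", LEFT_SPEED, ADAPT_RIGHT, adaptation_strides),
    ]
    if experiment == "exp1":
        parts.append(
            build_ramp_schedule(ADAPT_RIGHT, LEFT_SPEED, RAMP_STEP, STRIDES_PER_SPEED, LEFT_SPEED, "ramp_down").table
        )
    else:
        up = build_ramp_schedule(ADAPT_RIGHT, 2.0, RAMP_STEP, STRIDES_PER_SPEED, LEFT_SPEED, "ramp_up_down").table
        down = build_ramp_schedule(1.95, LEFT_SPEED, RAMP_STEP, STRIDES_PER_SPEED, LEFT_SPEED, "ramp_up_down").table
        down["config_index"] += int(up["config_index"].max())
        parts.append(pd.concat([up, down], ignore_index=True))
    return BeltSpeedSchedule.concat(parts)


def schedule_from_phases(phases: list[PhaseSpec]) -> BeltSpeedSchedule:
    """Assemble a schedule from an ordered list of PhaseSpecs."""
    if not phases:
        raise ValueError("need at least one phase")
    parts = []
    for spec in phases:
        if spec.ramp is not None:
            start, end, step, strides_per_speed = spec.ramp
            parts.append(
                build_ramp_schedule(start, end, step, strides_per_speed,
                                    spec.left_speed, phase=spec.name).table
            )
        else:
            parts.append(
                _constant_phase(spec.name, spec.left_speed, spec.right_speed, spec.n_strides)
            )
    return BeltSpeedSchedule.concat(parts)


def load_protocol(path) -> BeltSpeedSchedule:
    """Build a schedule from a JSON/YAML config: a list of phase mappings.

    Each entry needs ``name`` and ``left_speed`` plus either
    ``right_speed``/``n_strides`` (constant phase) or ``ramp``
    [start, end, step, strides_per_speed].
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML superset: also parses JSON
    phases = [
        PhaseSpec(
            name=entry["name"],
            left_speed=entry["left_speed"],
            right_speed=entry.get("right_speed"),
            n_strides=entry.get("n_strides"),
            ramp=tuple(entry["ramp"]) if "ramp" in entry else None,
        )
        for entry in raw
    ]
    return schedule_from_phases(phases)


def post_ramp_phase(schedule: BeltSpeedSchedule) -> str:
    """Name of the post-adaptation ramp phase present in the schedule."""
    for name in ("ramp_down", "ramp_up_down"):
        if name in schedule.phases:
            return name
    raise KeyError("schedule has no post-adaptation ramp phase")
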