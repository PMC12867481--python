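"""Synthetic participants with planted ground truth.

Generates stride-level gait series (sla, perturbation, Δ motor output) over
any belt-speed schedule, with a planted recalibration level, mapping type
(memory- vs structure-based), perceptual point of subjective equality (PSE),
and stride-to-stride Gaussian noise — so that every downstream analysis stage
(decomposition, model fitting, perception, clustering, statistics) can be
validated against known truth.

The planted dynamics follow the recalibration + mapping account:

* baseline tied blocks and the baseline ramp: no adaptation, u = 0;
* adaptation: u approaches the ideal plateau perturbation along a
  double-exponential transient (sla = u − p rises from negative toward 0);
* post-adaptation ramps: u = max(p*, r_true) for perturbations at or below the
  adaptation plateau; above it (Exp 2 ramp up), memory-based participants cap
  u at the plateau while structure-based participants keep tracking p*.

Observation noise is a single iid Gaussian sequence added to u, with
sla = u − p* defined from the noisy u, so the decomposition identity
sla = u − p holds exactly for synthetic data. Button presses are planted at
the first strides whose belt-speed difference drops to the true upper/lower
PSE, with optional rounded-Gaussian jitter in strides.

A dual-state generator (``generate_dual_state_participant``) plants
recalibration-only dynamics instead, for model-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gait_metrics import KINEMATIC_COLUMNS, GaitSeries, double_exponential
from .models import simulate_dual_state
from .paradigm import RAMP_STEP, BeltSpeedSchedule, build_protocol, post_ramp_phase

#: ideal plateau perturbation per 1 m/s belt-speed difference (sla units)
DEFAULT_P_GAIN = 0.27
#: stride-to-stride sla noise (sla units)
DEFAULT_NOISE_SD = 0.02
#: adaptation transient of sla (A1, tau1, A2, tau2); amplitudes sum to
#: −p_plateau at a 1 m/s split so adaptation starts near u = 0
DEFAULT_ADAPT_PARAMS = (-0.12, 322.072, -0.15, 29.662)
#: planted PSE bounds (m/s): the study conditions this generator emulates
DEFAULT_PSE_UPPER = 0.64
DEFAULT_PSE_LOWER = 0.39


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of one synthetic participant.

    ``r_true`` is the recalibration level in perturbation (sla) units;
    ``mapping_type`` controls behavior above the adaptation plateau
    perturbation; ``p_gain`` maps the belt-speed difference (m/s) to the ideal
    plateau perturbation; the PSE bounds are in m/s of belt-speed difference.
    """

    r_true: float = 0.56 * DEFAULT_P_GAIN
    mapping_type: str = "memory"
    p_gain: float = DEFAULT_P_GAIN
    adapt_params: tuple[float, float, float, float] = DEFAULT_ADAPT_PARAMS
    noise_sd: float = DEFAULT_NOISE_SD
    pse_true_upper: float = DEFAULT_PSE_UPPER
    pse_true_lower: float = DEFAULT_PSE_LOWER
    press_lapse_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mapping_type not in ("memory", "structure"):
            raise ValueError(f"mapping_type must be 'memory' or 'structure', got {self.mapping_type!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.r_true <= self.p_gain * 1.0):
            raise ValueError("require 0 <= r_true <= p_gain * 1 m/s")
        if self.pse_true_lower > self.pse_true_upper:
            raise ValueError("pse_true_lower must be <= pse_true_upper")


@dataclass
class SyntheticParticipant:
    """Planted ground truth plus the generated stride series and presses."""

    ground_truth: GroundTruth
    schedule: BeltSpeedSchedule
    gait: GaitSeries
    presses: tuple[int, int] | None = None
    presses_flag: str | None = None
    u_clean: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.gait) != len(self.schedule):
            raise ValueError("gait length must equal schedule length")

    def to_frame(self) -> pd.DataFrame:
        """Stride table: schedule columns joined with the gait series."""
        return pd.concat(
            [self.schedule.table.reset_index(drop=True), self.gait.to_frame()], axis=1
        )


def clean_motor_output(gt: GroundTruth, schedule: BeltSpeedSchedule) -> np.ndarray:
    """Noise-free planted Δ motor output over the whole schedule."""
    diff = schedule.speed_diff
    p_star = gt.p_gain * diff
    p_plateau = gt.p_gain * 1.0  # adaptation split is 1 m/s
    u = np.zeros(len(schedule))
    phase = schedule.table["phase"].to_numpy()
    adapt = phase == "adaptation"
    if adapt.any():
        j = np.arange(1, adapt.sum() + 1, dtype=float)
        u[adapt] = p_star[adapt] + double_exponential(j, *gt.adapt_params)
    ramp = np.isin(phase, ("ramp_down", "ramp_up_down"))
    below = ramp & (p_star <= p_plateau)
    u[below] = np.maximum(p_star[below], gt.r_true)
    above = ramp & (p_star > p_plateau)
    u[above] = p_plateau if gt.mapping_type == "memory" else p_star[above]
    return u


def _plant_presses(gt: GroundTruth, schedule: BeltSpeedSchedule, rng: np.random.Generator):
    """Press strides bracketing the planted PSE within the post-adaptation ramp."""
    phase = post_ramp_phase(schedule)
    mask = schedule.phase_mask(phase)
    strides = schedule.table["stride_index"].to_numpy()[mask]
    diff = schedule.speed_diff[mask]
    lo, hi = int(strides[0]), int(strides[-1])
    presses = []
    # speed differences are piecewise constant on a grid; the press lands on
    # the configuration closest to the true PSE (nearest-grid quantization,
    # unbiased) rather than the first configuration strictly below it
    step = RAMP_STEP
    for target in (gt.pse_true_upper, gt.pse_true_lower):
        target = round(target / step) * step
        hits = np.flatnonzero(diff <= target + 1e-9)
        if hits.size == 0:
            return None, f"press target {target} m/s below the ramp's speed-difference range"
        stride = int(strides[hits[0]])
        if gt.press_lapse_sd > 0:
            stride += int(round(rng.normal(0.0, gt.press_lapse_sd)))
        presses.append(int(np.clip(stride, lo, hi)))
    press1, press2 = presses
    if press1 > press2:  # perception reports are ordered: 'equal' before 'no longer equal'
        press1 = press2
    return (press1, press2), None


def generate_participant(gt: GroundTruth, schedule: BeltSpeedSchedule) -> SyntheticParticipant:
    """Generate one synthetic participant over ``schedule``.

    Observed u adds iid N(0, noise_sd²) to the planted clean output; sla is
    u − p* exactly (the decomposition identity is preserved under noise).
    """
    rng = np.random.default_rng(gt.seed)
    p_star = gt.p_gain * schedule.speed_diff
    u_clean = clean_motor_output(gt, schedule)
    noise = rng.normal(0.0, gt.noise_sd, len(schedule)) if gt.noise_sd > 0 else 0.0
    u = u_clean + noise
    gait = GaitSeries(sla=u - p_star, perturbation=p_star, delta_motor_output=u)
    presses, flag = _plant_presses(gt, schedule, rng)
    return SyntheticParticipant(
        ground_truth=gt, schedule=schedule, gait=gait,
        presses=presses, presses_flag=flag, u_clean=u_clean,
    )


def generate_dual_state_participant(
    params: tuple[float, float, float, float],
    schedule: BeltSpeedSchedule,
    noise_sd: float = DEFAULT_NOISE_SD,
    p_gain: float = DEFAULT_P_GAIN,
    seed: int = 0,
) -> SyntheticParticipant:
    """Plant recalibration-only (dual-state) dynamics over the whole paradigm."""
    rng = np.random.default_rng(seed)
    p_star = p_gain * schedule.speed_diff
    u_clean = simulate_dual_state(*params, p_star).u
    u = u_clean + (rng.normal(0.0, noise_sd, len(schedule)) if noise_sd > 0 else 0.0)
    gait = GaitSeries(sla=u - p_star, perturbation=p_star, delta_motor_output=u)
    gt = GroundTruth(r_true=0.0, mapping_type="memory", p_gain=p_gain, noise_sd=noise_sd, seed=seed)
    return SyntheticParticipant(ground_truth=gt, schedule=schedule, gait=gait, u_clean=u_clean)


def generate_cohort(
    n: int,
    mix: float = 0.6,
    schedule: BeltSpeedSchedule | None = None,
    gt_sampler: dict | None = None,
    seed: int = 0,
    experiment: str = "exp1",
) -> list[SyntheticParticipant]:
    """Generate ``n`` participants; a ``mix`` fraction are memory-based.

    The memory-based count is round(n * mix) (e.g. n=20, mix=0.6 → 12 memory /
    8 structure). ``gt_sampler`` maps GroundTruth field names to callables
    rng → value, sampled per participant; unsampled fields keep their
    defaults. Participant seeds derive deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= mix <= 1):
        raise ValueError("mix must be in [0, 1]")
    if schedule is None:
        schedule = build_protocol(experiment)
    gt_sampler = gt_sampler or {}
    n_memory = int(round(n * mix))
    master = np.random.SeedSequence(seed)
    participant_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n)]
    sampler_rng = np.random.default_rng(master.spawn(1)[0])
    cohort = []
    for i in range(n):
        fields = {name: fn(sampler_rng) for name, fn in gt_sampler.items()}
        fields["mapping_type"] = "memory" if i < n_memory else "structure"
        fields["seed"] = participant_seeds[i]
        gt = replace(GroundTruth(), **fields)
        cohort.append(generate_participant(gt, schedule))
    return cohort


def kinematics_from_gait(
    gait: GaitSeries,
    stride_length: float = 1.2,
    stride_time: float = 1.2,
    step_velocity_offset: float = -1.0,
) -> pd.DataFrame:
    """Construct stride kinematics whose decomposition reproduces ``gait`` exactly.

    Inverse of the sla/p/u decomposition for testing: equal step times
    (Δstep_time = 0, mean_time = stride_time/2), Δstep_velocity chosen to give
    the requested perturbation, Δstep_position chosen so that the identity
    Δstep_length = Δstep_position − mean_velocity·Δstep_time − mean_time·Δstep_velocity
    holds stride by stride. ``step_velocity_offset`` sets the mean foot
    velocity relative to the hips (negative: feet travel backward in stance).
    """
    sla = np.asarray(gait.sla, float)
    if np.any(np.abs(sla) >= 1):
        raise ValueError("requested |sla| must be < 1")
    p = np.asarray(gait.perturbation, float)
    u = np.asarray(gait.delta_motor_output, float)
    n = len(sla)
    mean_time = stride_time / 2
    d_len = sla * stride_length
    d_vel = p * stride_length / mean_time
    d_time = np.zeros(n)
    # u = Δpos/L − (mean_vel/L)·Δtime with Δtime = 0 → Δpos = u·L
    d_pos = u * stride_length
    half = stride_length / 2
    return pd.DataFrame(
        {
            "R_step_length": half + d_len / 2,
            "L_step_length": half - d_len / 2,
            "R_step_time": mean_time + d_time / 2,
            "L_step_time": mean_time - d_time / 2,
            "R_step_position": half / 2 + d_pos / 2,
            "L_step_position": half / 2 - d_pos / 2,
            "R_step_velocity": step_velocity_offset + d_vel / 2,
            "L_step_velocity": step_velocity_offset - d_vel / 2,
        },
        columns=KINEMATIC_COLUMNS,
    )


def export_cohort(cohort: list[SyntheticParticipant], out_dir) -> None:
    """One stride-table CSV per participant plus a manifest JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, part in enumerate(cohort):
        name = f"participant_{i:03d}.csv"
        part.to_frame().to_csv(out / name, index=False)
        gt = part.ground_truth
        manifest.append(
            {
                "file": name,
                "r_true": gt.r_true,
                "mapping_type": gt.mapping_type,
                "p_gain": gt.p_gain,
                "noise_sd": gt.noise_sd,
                "pse_true_upper": gt.pse_true_upper,
                "pse_true_lower": gt.pse_true_lower,
                "seed": gt.seed,
                "presses": list(part.presses) if part.presses else None,
            }
        )
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
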