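"""Perceptual realignment measures: PSE, compensation, and model-predicted PSE.

During the post-adaptation Ramp Down, participants press a button when the
belts first feel equal (press 1) and when the right first feels faster/slower
than the left (press 2). The belt-speed difference at each press bounds the
point of subjective equality (PSE):

    PSE_upper = (right − left speed) at press 1
    PSE_lower = (right − left speed) at press 2

Motor and perceptual adaptation are compared on a common percent-compensation
scale: comp_perceptual = PSE / adaptation speed difference, comp_motor_recal =
r / p_plateau, comp_motor_total = u_plateau / p_plateau, each × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .models import SimulationResult
from .paradigm import BeltSpeedSchedule, post_ramp_phase


@dataclass
class PerceptualMeasures:
    """PSE bounds (m/s) and the compensation percentages."""

    pse_upper: float
    pse_lower: float
    comp_perceptual_upper: float
    comp_perceptual_lower: float
    comp_motor_recal: float
    comp_motor_total: float
    p_plateau: float
    u_plateau: float


def pse_from_presses(
    schedule: BeltSpeedSchedule, press1_stride: int, press2_stride: int
) -> tuple[float, float]:
    """PSE bounds from the belt-speed difference at the two press strides.

    Speeds are piecewise constant over configurations, so the bound is read
    directly from the schedule at the press stride (no interpolation).
    """
    if press1_stride > press2_stride:
        raise ValueError("press 1 must not come after press 2")
    phase = post_ramp_phase(schedule)
    mask = schedule.phase_mask(phase)
    strides = schedule.table["stride_index"].to_numpy()
    in_task = set(strides[mask].tolist())
    for name, press in (("press 1", press1_stride), ("press 2", press2_stride)):
        if press not in in_task:
            raise ValueError(f"{name} stride {press} is outside the {phase} task")
    diff = schedule.speed_diff
    pse_upper = float(diff[strides == press1_stride][0])
    pse_lower = float(diff[strides == press2_stride][0])
    return pse_upper, pse_lower


def compensation_measures(
    pse_bounds: tuple[float, float],
    r_fit: float,
    p_plateau: float,
    u_plateau: float,
    adaptation_speed_diff: float = 1.0,
) -> PerceptualMeasures:
    """Express perceptual and motor adaptation as percent perturbation compensation."""
    if p_plateau <= 0:
        raise ValueError("p_plateau must be > 0")
    if adaptation_speed_diff <= 0:
        raise ValueError("adaptation_speed_diff must be > 0")
    pse_upper, pse_lower = pse_bounds
    return PerceptualMeasures(
        pse_upper=pse_upper,
        pse_lower=pse_lower,
        comp_perceptual_upper=100 * pse_upper / adaptation_speed_diff,
        comp_perceptual_lower=100 * pse_lower / adaptation_speed_diff,
        comp_motor_recal=100 * r_fit / p_plateau,
        comp_motor_total=100 * u_plateau / p_plateau,
        p_plateau=p_plateau,
        u_plateau=u_plateau,
    )


def pse_hat_from_pm_remap(sim: SimulationResult, p, p_plateau: float):
    """Model-predicted PSE: perturbation at the p_per sign flip, normalized.

    Finds the first stride where the simulated perceived perturbation flips
    from positive to negative and returns p(that stride)/p_plateau as
    ``(pse_hat, found)``; no flip returns ``(None, False)``.
    """
    if sim.p_per is None:
        raise ValueError("simulation has no perceived perturbation series")
    p = np.asarray(p, float)
    p_per = np.asarray(sim.p_per, float)
    flips = np.flatnonzero((p_per[:-1] > 0) & (p_per[1:] < 0))
    if flips.size == 0:
        return None, False
    return float(p[flips[0] + 1] / p_plateau), True


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
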