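"""Stride-level motor measures for split-belt walking.

Step length asymmetry (sla) is the normalized right-left step length
difference; it decomposes exactly into a belt-driven *perturbation* term p and
a compensatory *Δ motor output* term u:

    sla = u − p
    sla = Δstep_length / stride_length
    p   = (mean_time / stride_length) · Δstep_velocity
    u   = Δstep_position / stride_length − (mean_velocity / stride_length) · Δstep_time

where Δ is right minus left and ``mean`` the right/left average. The identity
holds by construction for marker-derived kinematics; here the residual
sla − (u − p) is returned as a per-stride diagnostic.

The module also provides the adaptation-curve metrics: strides-to-plateau (a
run of smoothed sla values inside the plateau band), double-exponential
fitting of the adaptation time course, and residual variance over the first or
last 30 strides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

KINEMATIC_COLUMNS = [
    "R_step_length", "L_step_length",
    "R_step_time", "L_step_time",
    "R_step_position", "L_step_position",
    "R_step_velocity", "L_step_velocity",
]


@dataclass
class GaitSeries:
    """Per-stride sla, perturbation p, and Δ motor output u (dimensionless)."""

    sla: np.ndarray
    perturbation: np.ndarray
    delta_motor_output: np.ndarray
    decomposition_residual: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.sla)
        if len(self.perturbation) != n or len(self.delta_motor_output) != n:
            raise ValueError("sla, perturbation and delta_motor_output lengths differ")
        if self.decomposition_residual is None:
            self.decomposition_residual = self.sla - (self.delta_motor_output - self.perturbation)

    def __len__(self) -> int:
        return len(self.sla)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sla": self.sla,
                "perturbation": self.perturbation,
                "delta_motor_output": self.delta_motor_output,
                "decomposition_residual": self.decomposition_residual,
            }
        )


@dataclass
class ExponentialFit:
    """Double-exponential fit A1·exp(−k/τ1) + A2·exp(−k/τ2) of adaptation sla."""

    A1: float
    tau1: float
    A2: float
    tau2: float
    residuals: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.A1, self.tau1, self.A2, self.tau2)

    def predict(self, strides: np.ndarray) -> np.ndarray:
        return double_exponential(strides, *self.params)


def compute_gait_series(kin: pd.DataFrame) -> GaitSeries:
    """Compute sla, p and u from stride kinematics.

    ``kin`` is a DataFrame with the right/left step length, time, position and
    velocity columns (see ``KINEMATIC_COLUMNS``); lengths in m, times in s,
    velocities in m/s, positions relative to the mean hip marker.
    """
    missing = [c for c in KINEMATIC_COLUMNS if c not in kin.columns]
    if missing:
        raise ValueError(f"kinematics missing columns {missing}")
    if len(kin) == 0:
        raise ValueError("empty kinematics")
    R_len = kin["R_step_length"].to_numpy(float)
    L_len = kin["L_step_length"].to_numpy(float)
    stride_length = R_len + L_len
    bad = np.flatnonzero(stride_length <= 0)
    if bad.size:
        raise ValueError(f"non-positive stride length at stride {bad[0] + 1}")

    d_len = R_len - L_len
    d_pos = kin["R_step_position"].to_numpy(float) - kin["L_step_position"].to_numpy(float)
    d_time = kin["R_step_time"].to_numpy(float) - kin["L_step_time"].to_numpy(float)
    mean_time = (kin["R_step_time"].to_numpy(float) + kin["L_step_time"].to_numpy(float)) / 2
    d_vel = kin["R_step_velocity"].to_numpy(float) - kin["L_step_velocity"].to_numpy(float)
    mean_vel = (kin["R_step_velocity"].to_numpy(float) + kin["L_step_velocity"].to_numpy(float)) / 2

    sla = d_len / stride_length
    p = mean_time / stride_length * d_vel
    u = d_pos / stride_length - mean_vel / stride_length * d_time
    return GaitSeries(sla=sla, perturbation=p, delta_motor_output=u)


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    x = np.asarray(x, float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def strides_to_plateau(sla: np.ndarray, window: int = 5, run: int = 5, tail: int = 30):
    """First stride (1-based) starting 5 consecutive smoothed values in the plateau band.

    The series is smoothed with a centered 5-point moving average; the plateau
    band is mean ± 1 SD of the last ``tail`` smoothed strides. Returns
    ``(index, found)``; when no qualifying run exists, ``index`` is the series
    length and ``found`` is False.
    """
    sla = np.asarray(sla, float)
    if len(sla) < tail:
        raise ValueError(f"need at least {tail} strides, got {len(sla)}")
    smooth = moving_average(sla, window)
    tail_vals = smooth[-tail:]
    lo = tail_vals.mean() - tail_vals.std(ddof=0)
    hi = tail_vals.mean() + tail_vals.std(ddof=0)
    inside = (smooth >= lo) & (smooth <= hi)
    for i in range(len(sla) - run + 1):
        if inside[i:i + run].all():
            return i + 1, True
    return len(sla), False


def double_exponential(stride: np.ndarray, A1: float, tau1: float, A2: float, tau2: float) -> np.ndarray:
    return A1 * np.exp(-stride / tau1) + A2 * np.exp(-stride / tau2)


# initial values from group-mean fits of the two experiments
DEXP_INIT_EXP1 = (-0.177, 322.072, -0.216, 29.662)
DEXP_INIT_EXP2 = (-0.177, 418.725, -0.203, 44.307)


def fit_double_exponential(
    sla: np.ndarray,
    init: tuple[float, float, float, float] = DEXP_INIT_EXP1,
) -> ExponentialFit:
    """Bounded least-squares fit of the double-exponential adaptation curve.

    Stride numbers are 1-based. Components are reported ordered by time
    constant descending (the model is symmetric under exchange of the two
    components). An all-zero series returns the zero fit directly.
    """
    sla = np.asarray(sla, float)
    if len(sla) < 50:
        raise ValueError(f"need at least 50 strides, got {len(sla)}")
    strides = np.arange(1, len(sla) + 1, dtype=float)
    if np.allclose(sla, 0.0):
        return ExponentialFit(0.0, init[1], 0.0, init[3], residuals=sla.copy())

    def resid(theta):
        return double_exponential(strides, *theta) - sla

    lower = [-2.0, 1e-3, -2.0, 1e-3]
    upper = [2.0, 1e5, 2.0, 1e5]
    x0 = np.clip(init, lower, upper)
    sol = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    A1, tau1, A2, tau2 = sol.x
    if tau1 < tau2:  # order components by time constant, slow first
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    return ExponentialFit(A1, tau1, A2, tau2, residuals=-resid((A1, tau1, A2, tau2)),
                          converged=bool(sol.success))


def residual_variance(residuals: np.ndarray, segment: Literal["first30", "last30"]) -> float:
    """Sample variance of fit residuals over the first or last 30 strides."""
    residuals = np.asarray(residuals, float)
    if len(residuals) < 30:
        raise ValueError(f"need at least 30 residuals, got {len(residuals)}")
    if segment == "first30":
        window = residuals[:30]
    elif segment == "last30":
        window = residuals[-30:]
    else:
        raise ValueError(f"segment must be 'first30' or 'last30', got {segment!r}")
    return float(np.var(window, ddof=1))
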