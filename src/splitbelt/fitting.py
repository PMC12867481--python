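"""Fit adaptation models to Ramp Down Δ motor output and compare them by BIC.

Each model is fitted per participant by bounded nonlinear least squares on the
residual between the measured and simulated Δ motor output, evaluated on the
post-adaptation ramp strides only. State models whose hidden states depend on
history (dual state, optimal control, memory of errors, PReMo, PEA) are
simulated over the entire paradigm; the recalibration + mapping and PM-ReMap
models are simulated on the ramp alone. Models are compared by the Gaussian
BIC n·ln(RSS/n) + k·ln(n) — additive constants cancel in differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import least_squares

from .models import ModelSpec, get_model
from .paradigm import BeltSpeedSchedule, post_ramp_phase
from .stats import BootstrapCI, bootstrap_group_ci

#: strides of the adaptation tail used to define the plateau
PLATEAU_STRIDES = 30


@dataclass
class ModelFit:
    """Result of one model fitted to one participant's ramp data."""

    model_name: str
    params: dict[str, float]
    rss: float
    n_obs: int
    k_params: int
    bic: float
    u_fit: np.ndarray = field(repr=False)
    converged: bool = True
    rss_flag: str | None = None


@dataclass
class ModelComparison:
    """Per-participant BIC differences (alternative − reference) with bootstrap CI."""

    model_a: str
    model_b: str
    delta_bic: np.ndarray
    ci: BootstrapCI

    @property
    def mean(self) -> float:
        return self.ci.mean


def p_plateau_of(participant) -> float:
    """Mean perturbation over the last 30 adaptation strides."""
    mask = participant.schedule.phase_mask("adaptation")
    return float(participant.gait.perturbation[mask][-PLATEAU_STRIDES:].mean())


def u_plateau_of(participant) -> float:
    """Mean Δ motor output over the last 30 adaptation strides."""
    mask = participant.schedule.phase_mask("adaptation")
    return float(participant.gait.delta_motor_output[mask][-PLATEAU_STRIDES:].mean())


def compute_bic(rss: float, n_obs: int, k_params: int):
    """Gaussian-residual BIC up to constants: n·ln(rss/n) + k·ln(n).

    Returns ``(bic, flag)``; a zero RSS (perfect fit) yields −inf with a flag
    rather than an error, since it only arises on noise-free synthetic data.
    """
    if n_obs <= k_params:
        raise ValueError("need n_obs > k_params")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return -np.inf, "zero RSS"
    return n_obs * np.log(rss / n_obs) + k_params * np.log(n_obs), None


def _ramp_spec(spec: ModelSpec, participant) -> ModelSpec:
    """Specialize the recal_map init/bounds to the participant's plateau."""
    if spec.name != "recal_map":
        return spec
    p_plateau = p_plateau_of(participant)
    return dc_replace(
        spec,
        init_values=(0.5 * p_plateau,),
        lower_bounds=(0.0,),
        upper_bounds=(p_plateau,),
    )


def fit_model(spec: ModelSpec | str, participant, tol: float = 1e-12, multistart: int = 0) -> ModelFit:
    """Fit one model to a participant's ramp Δ motor output.

    ``participant`` needs ``schedule`` and ``gait`` attributes (e.g. a
    SyntheticParticipant). The objective is the sum of squared differences
    between data and model u over the post-adaptation ramp strides. Optional
    ``multistart`` adds that many seeded random restarts within the bounds
    (off by default; the best endpoint wins).
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    spec = _ramp_spec(spec, participant)
    schedule: BeltSpeedSchedule = participant.schedule
    ramp_mask = schedule.phase_mask(post_ramp_phase(schedule))
    p_full = np.asarray(participant.gait.perturbation, float)
    u_data = np.asarray(participant.gait.delta_motor_output, float)[ramp_mask]
    p_input = p_full[ramp_mask] if spec.ramp_only else p_full
    out_mask = None if spec.ramp_only else ramp_mask

    def residuals(theta):
        u_model = spec.simulate(theta, p_input).u
        if out_mask is not None:
            u_model = u_model[out_mask]
        return u_model - u_data

    lower = np.asarray(spec.lower_bounds, float)
    upper = np.asarray(spec.upper_bounds, float)
    starts = [np.asarray(spec.init_values, float)]
    if multistart:
        rng = np.random.default_rng(0)
        starts += [lower + (upper - lower) * rng.random(len(lower)) for _ in range(multistart)]
    best = None
    for x0 in starts:
        span = upper - lower
        x0 = np.where(span > 0, np.clip(x0, lower, upper), lower)
        if np.all(span == 0):  # fully pinned (e.g. recal_map with zero plateau)
            sol_x, sol_cost, sol_ok = lower, 0.5 * np.sum(residuals(lower) ** 2), True
        else:
            sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=tol, ftol=tol, gtol=tol)
            sol_x, sol_cost, sol_ok = sol.x, sol.cost, bool(sol.success)
        if best is None or sol_cost < best[1]:
            best = (sol_x, sol_cost, sol_ok)
    x, cost, ok = best
    u_model = spec.simulate(x, p_input).u
    if out_mask is not None:
        u_model = u_model[out_mask]
    rss = float(np.sum((u_model - u_data) ** 2))
    n_obs = len(u_data)
    bic, flag = compute_bic(rss, n_obs, spec.k_params)
    return ModelFit(
        model_name=spec.name,
        params=dict(zip(spec.param_names, map(float, x))),
        rss=rss,
        n_obs=n_obs,
        k_params=spec.k_params,
        bic=bic,
        u_fit=u_model,
        converged=ok,
        rss_flag=flag,
    )


def fitted_r(participant, **kwargs) -> float:
    """Convenience: the recalibration level fitted by the recal_map model."""
    return fit_model("recal_map", participant, **kwargs).params["r"]


def compare_models(
    fits_alternative: list[ModelFit],
    fits_reference: list[ModelFit],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ModelComparison:
    """Per-participant ΔBIC = alternative − reference with a bootstrap CI.

    A positive group mean means the reference model (conventionally
    recal_map) fits better.
    """
    if len(fits_alternative) != len(fits_reference):
        raise ValueError("fit lists must cover the same participants")
    delta = np.array([fa.bic - fr.bic for fa, fr in zip(fits_alternative, fits_reference)])
    ci = bootstrap_group_ci(delta, n_boot=n_boot, alpha=alpha, seed=seed)
    names = (fits_alternative[0].model_name, fits_reference[0].model_name)
    return ModelComparison(model_a=names[0], model_b=names[1], delta_bic=delta, ci=ci)
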