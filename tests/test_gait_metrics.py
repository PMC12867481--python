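"""Step-length-asymmetry decomposition and adaptation-curve metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitbelt.gait_metrics import (
    DEXP_INIT_EXP1,
    GaitSeries,
    compute_gait_series,
    double_exponential,
    fit_double_exponential,
    residual_variance,
    strides_to_plateau,
)
from splitbelt.synthetic import kinematics_from_gait


def _random_kinematics(rng, n=40):
    return pd.DataFrame(
        {
            "R_step_length": rng.uniform(0.4, 0.8, n),
            "L_step_length": rng.uniform(0.4, 0.8, n),
            "R_step_time": rng.uniform(0.4, 0.8, n),
            "L_step_time": rng.uniform(0.4, 0.8, n),
            "R_step_position": rng.uniform(0.1, 0.4, n),
            "L_step_position": rng.uniform(0.1, 0.4, n),
            "R_step_velocity": rng.uniform(-1.5, -0.3, n),
            "L_step_velocity": rng.uniform(-1.5, -0.3, n),
        }
    )


def test_symmetric_strides_give_zero_measures():
    kin = _random_kinematics(np.random.default_rng(0), n=10)
    for side in ("step_length", "step_time", "step_position", "step_velocity"):
        kin[f"L_{side}"] = kin[f"R_{side}"]
    gait = compute_gait_series(kin)
    assert np.allclose(gait.sla, 0) and np.allclose(gait.perturbation, 0)
    assert np.allclose(gait.delta_motor_output, 0)


def test_measures_match_independent_transcription():
    """sla, p, u agree with a direct, separately written transcription."""
    kin = _random_kinematics(np.random.default_rng(42))
    gait = compute_gait_series(kin)
    for i in range(len(kin)):
        row = kin.iloc[i]
        L = row.R_step_length + row.L_step_length
        sla = (row.R_step_length - row.L_step_length) / L
        mean_t = (row.R_step_time + row.L_step_time) / 2
        p = mean_t / L * (row.R_step_velocity - row.L_step_velocity)
        mean_v = (row.R_step_velocity + row.L_step_velocity) / 2
        u = (row.R_step_position - row.L_step_position) / L - mean_v / L * (
            row.R_step_time - row.L_step_time
        )
        assert abs(gait.sla[i] - sla) <= 1e-12
        assert abs(gait.perturbation[i] - p) <= 1e-12
        assert abs(gait.delta_motor_output[i] - u) <= 1e-12
        assert abs(gait.decomposition_residual[i] - (sla - (u - p))) <= 1e-12


@given(scale=st.floats(0.25, 4.0))
@settings(deadline=None, max_examples=20)
def test_sla_scale_invariance(scale):
    """A common rescaling of lengths and velocities leaves sla unchanged."""
    kin = _random_kinematics(np.random.default_rng(3), n=15)
    ref = compute_gait_series(kin).sla
    scaled = kin.copy()
    for col in ("R_step_length", "L_step_length", "R_step_position",
                "L_step_position", "R_step_velocity", "L_step_velocity"):
        scaled[col] = kin[col] * scale
    assert np.allclose(compute_gait_series(scaled).sla, ref, atol=1e-12)


def test_left_right_swap_negates_measures():
    kin = _random_kinematics(np.random.default_rng(5), n=15)
    swapped = kin.rename(
        columns=lambda c: c.replace("R_", "X_").replace("L_", "R_").replace("X_", "L_")
    )
    a, b = compute_gait_series(kin), compute_gait_series(swapped)
    assert np.allclose(a.sla, -b.sla, atol=1e-12)
    assert np.allclose(a.perturbation, -b.perturbation, atol=1e-12)
    assert np.allclose(a.delta_motor_output, -b.delta_motor_output, atol=1e-12)


def test_zero_stride_length_rejected():
    kin = _random_kinematics(np.random.default_rng(1), n=5)
    kin.loc[2, ["R_step_length", "L_step_length"]] = 0.0
    with pytest.raises(ValueError, match="stride 3"):
        compute_gait_series(kin)


def test_inverse_kinematics_round_trip():
    """Synthetic kinematics reproduce a planted (sla, p, u) series exactly."""
    rng = np.random.default_rng(11)
    p = rng.uniform(-0.2, 0.3, 60)
    u = rng.uniform(-0.2, 0.3, 60)
    gait = GaitSeries(sla=u - p, perturbation=p, delta_motor_output=u)
    back = compute_gait_series(kinematics_from_gait(gait))
    assert np.max(np.abs(back.perturbation - p)) <= 1e-12
    assert np.max(np.abs(back.delta_motor_output - u)) <= 1e-12
    assert np.max(np.abs(back.decomposition_residual)) <= 1e-12


def test_inverse_kinematics_step_length_arithmetic():
    gait = GaitSeries(sla=np.array([0.1]), perturbation=np.array([0.0]),
                      delta_motor_output=np.array([0.1]))
    kin = kinematics_from_gait(gait, stride_length=1.2)
    assert abs((kin.R_step_length - kin.L_step_length).iloc[0] - 0.12) <= 1e-12


class TestStridesToPlateau:
    def test_constant_series_is_at_plateau_immediately(self):
        idx, found = strides_to_plateau(np.full(100, -0.1))
        assert (idx, found) == (1, True)

    def test_step_series_matches_exhaustive_scan(self):
        sla = np.concatenate([np.full(100, -0.2), np.zeros(200)])
        idx, found = strides_to_plateau(sla)
        assert found
        # brute-force oracle: recompute the smoothed series and scan runs
        smooth = np.array([sla[max(0, i - 2):i + 3].mean() for i in range(len(sla))])
        tail = smooth[-30:]
        lo, hi = tail.mean() - tail.std(), tail.mean() + tail.std()
        expected = next(
            i + 1
            for i in range(len(sla) - 4)
            if all(lo <= smooth[j] <= hi for j in range(i, i + 5))
        )
        assert idx == expected

    def test_plateau_index_increases_with_time_constant(self):
        """Slower transients (larger τ) take longer to reach the noise floor."""
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.02, 600)  # same realization for every τ
        k = np.arange(1, 601)
        indices = [
            strides_to_plateau(-0.2 * np.exp(-k / tau) + noise)[0] for tau in (10, 50, 200)
        ]
        assert indices[0] < indices[1] < indices[2]

    def test_no_plateau_returns_length_with_flag(self):
        # period-4 square wave: smoothed values leave the tail band every few
        # strides, so no 5-stride run ever qualifies
        idx, found = strides_to_plateau(np.tile([0.0, 0.0, 10.0, 10.0], 25))
        assert not found and idx == 100


class TestDoubleExponential:
    def test_recovers_parameters_from_noiseless_series(self):
        k = np.arange(1, 751, dtype=float)
        truth = DEXP_INIT_EXP1  # (-0.177, 322.072, -0.216, 29.662)
        sla = double_exponential(k, *truth)
        fit = fit_double_exponential(sla, init=(-0.2, 300.0, -0.2, 30.0))
        assert np.allclose(fit.params, truth, rtol=1e-6)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_all_zero_series_yields_zero_amplitudes(self):
        fit = fit_double_exponential(np.zeros(100))
        assert fit.A1 == fit.A2 == 0.0
        assert np.allclose(fit.residuals, 0)

    def test_residual_sd_matches_injected_noise(self):
        rng = np.random.default_rng(8)
        k = np.arange(1, 501, dtype=float)
        sla = double_exponential(k, *DEXP_INIT_EXP1) + rng.normal(0, 0.02, len(k))
        fit = fit_double_exponential(sla)
        assert 0.015 <= fit.residuals.std() <= 0.025

    def test_components_ordered_by_time_constant(self):
        k = np.arange(1, 401, dtype=float)
        sla = double_exponential(k, -0.05, 20.0, -0.3, 250.0)
        fit = fit_double_exponential(sla)
        assert fit.tau1 >= fit.tau2


class TestResidualVariance:
    def test_constant_residuals_have_zero_variance(self):
        assert residual_variance(np.full(60, 0.3), "first30") == pytest.approx(0.0, abs=1e-30)

    def test_iid_noise_variance_in_chi2_band(self):
        rng = np.random.default_rng(2)
        res = rng.normal(0, 0.02, 30)
        v = residual_variance(res, "last30")
        # 99% band for the sample variance of 30 iid N(0, 0.02^2) draws
        from scipy.stats import chi2
        lo = 0.02**2 * chi2.ppf(0.005, 29) / 29
        hi = 0.02**2 * chi2.ppf(0.995, 29) / 29
        assert lo <= v <= hi

    def test_planted_heteroscedasticity_ordering(self):
        rng = np.random.default_rng(4)
        res = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(0, 0.02, 50)])
        assert residual_variance(res, "first30") > residual_variance(res, "last30")

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 30"):
            residual_variance(np.zeros(10), "first30")
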