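"""Simulator behavior: limiting cases, independent oracles, shared invariants."""

import numpy as np
import pytest

from splitbelt.models import (
    MODEL_NAMES,
    get_model,
    lqg_gains,
    perceived_speed_prediction,
    simulate_dual_state,
    simulate_memory_of_errors,
    simulate_optimal_control,
    simulate_pea,
    simulate_pm_remap,
    simulate_premo,
    simulate_recal_map,
)

CONST_P = np.full(400, 0.27)


class TestRecalMap:
    def test_piecewise_rule(self):
        sim = simulate_recal_map(0.15, [0.27, 0.16, 0.10, 0.0])
        assert np.allclose(sim.u, [0.27, 0.16, 0.15, 0.15])

    def test_zero_r_is_pure_mapping(self):
        p = np.linspace(0.3, 0.0, 20)
        assert np.array_equal(simulate_recal_map(0.0, p).u, p)

    def test_large_r_is_pure_recalibration(self):
        p = np.linspace(0.3, 0.0, 20)
        assert np.allclose(simulate_recal_map(0.5, p).u, 0.5)

    def test_matches_brute_force_envelope(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(-0.1, 0.4, 200)
        sim = simulate_recal_map(0.12, p)
        brute = np.array([pk if pk >= 0.12 else 0.12 for pk in p])
        assert np.array_equal(sim.u, brute)


class TestDualState:
    def test_no_learning_without_error_sensitivity(self):
        sim = simulate_dual_state(0.92, 0.99, 0.0, 0.0, CONST_P)
        assert np.allclose(sim.u, 0)

    def test_closed_form_geometric_approach(self):
        """With A_f = A_s = 1 the net state approaches p at rate B_f + B_s."""
        B_f, B_s = 0.1, 0.01
        sim = simulate_dual_state(1.0, 1.0, B_f, B_s, CONST_P)
        k = np.arange(len(CONST_P))
        closed = 0.27 * (1 - (1 - B_f - B_s) ** k)
        assert np.max(np.abs(sim.u - closed)) <= 1e-12

    def test_hand_iteration_of_printed_inits(self):
        A_f, A_s, B_f, B_s = 0.92, 0.99, 0.1, 0.01
        sim = simulate_dual_state(A_f, A_s, B_f, B_s, np.full(200, 0.27))
        # first three strides by hand
        xf = xs = 0.0
        for k in range(3):
            assert abs(sim.u[k] - (xf + xs)) <= 1e-15
            err = 0.27 - (xf + xs)
            xf, xs = A_f * xf + B_f * err, A_s * xs + B_s * err

    def test_collapses_to_single_state_model(self):
        A, B = 0.95, 0.12
        sim = simulate_dual_state(A, A, B * 2 / 3, B / 3, CONST_P)
        x, ref = 0.0, []
        for pk in CONST_P:
            ref.append(x)
            x = A * x + B * (pk - x)
        assert np.max(np.abs(sim.u - np.array(ref))) <= 1e-12


class TestOptimalControl:
    def test_zero_perturbation_gives_zero_output(self):
        sim = simulate_optimal_control(0.9, 0.01, 0.01, 0.01, np.zeros(80))
        assert np.all(sim.u == 0)

    def test_cheap_control_tracks_perturbation(self):
        """With negligible effort cost and precise sensing, u converges to p."""
        sim = simulate_optimal_control(0.999, 1e-4, 1e-4, 1e-6, CONST_P, r_u=1e-8)
        assert abs(sim.u[-1] - 0.27) < 0.01

    def test_kalman_gain_matches_independent_riccati_iteration(self):
        a, sp2, ss2, sy2 = 0.9, 0.01, 0.02, 0.005
        _, K = lqg_gains(a, sp2, ss2, sy2, horizon=10)
        # independent elementwise fixed-point iteration of the filter Riccati
        A = np.array([[a, 0.0], [-1.0, 0.0]])
        Qx = np.diag([sp2, ss2])
        P = np.eye(2)
        for _ in range(5000):
            S = P[1, 1] + sy2
            Kk = P[:, [1]] / S
            P = A @ (P - Kk @ P[[1], :]) @ A.T + Qx
        K_ref = P[:, [1]] / (P[1, 1] + sy2)
        assert np.max(np.abs(K - K_ref)) <= 1e-10

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_optimal_control(0.9, -0.01, 0.01, 0.01, CONST_P)


class TestMemoryOfErrors:
    def test_beta_zero_reduces_to_single_rate_model(self):
        eta0, a = 0.1, 0.9
        sim = simulate_memory_of_errors(0.5, 0.0, eta0, a, CONST_P)
        x, ref = 0.0, []
        for pk in CONST_P:
            ref.append(x)
            x = a * x + eta0 * (pk - x)
        assert np.max(np.abs(sim.u - np.array(ref))) <= 1e-12

    def test_alternating_errors_decrease_sensitivity(self):
        """Alternating-sign errors shrink w near the active basis centers."""
        p = np.tile([0.2, -0.2], 100)
        sim = simulate_memory_of_errors(0.02, 0.01, 0.05, 0.5, p)
        center = np.argmin(np.abs(np.linspace(-0.5, 0.5, 21) - 0.2))
        assert sim.hidden["w"][center] < 0.05

    def test_consistent_errors_increase_sensitivity(self):
        sim = simulate_memory_of_errors(0.02, 0.01, 0.01, 0.999, np.full(200, 0.3))
        center = np.argmin(np.abs(np.linspace(-0.5, 0.5, 21) - 0.3))
        assert sim.hidden["w"][center] > 0.01

    def test_zero_errors_leave_output_at_retention_decay(self):
        sim = simulate_memory_of_errors(0.5, 0.5, 0.1, 0.9, np.zeros(50))
        assert np.allclose(sim.u, 0)


class TestPremo:
    def test_no_learning_with_zero_rate(self):
        sim = simulate_premo(0.0, 0.4, CONST_P)
        assert np.allclose(sim.u, 0)
        # with x = 0: x_p = −p, x_p_per = −W_p·p, so p_per = W_p·p
        assert np.allclose(sim.p_per, 0.4 * CONST_P)

    def test_full_weight_reduces_to_error_correction(self):
        """W_p = 1: the update is plain error correction on sla."""
        K = 0.1
        sim = simulate_premo(K, 1.0, CONST_P)
        x, ref = 0.0, []
        for pk in CONST_P:
            ref.append(x)
            x = x + K * (0 - (x - pk))
        assert np.max(np.abs(sim.u - np.array(ref))) <= 1e-12

    def test_constant_input_fixed_point(self):
        """At steady state the perceptual error vanishes: W_p (x − p) = 0."""
        sim = simulate_premo(0.2, 0.4, np.full(2000, 0.27))
        assert abs(sim.u[-1] - 0.27) < 1e-8


class TestPea:
    def test_frozen_dynamics(self):
        sim = simulate_pea(1.0, 0.0, 0.5, CONST_P)
        assert np.allclose(sim.u, 0)

    def test_zero_weight_removes_drive(self):
        sim = simulate_pea(0.9, 0.3, 0.0, CONST_P)
        assert np.allclose(sim.u, 0)  # x̂_p = T = 0, decay from zero state

    def test_constant_input_fixed_point_matches_algebra(self):
        A, B, W_p, p0 = 0.97, 0.2, 1 / 3, 0.27
        sim = simulate_pea(A, B, W_p, np.full(3000, p0))
        x_star = B * W_p * p0 / (1 - A + B * W_p)
        assert abs(sim.u[-1] - x_star) <= 1e-10


class TestPmRemap:
    def _ramp_p(self):
        return 0.27 * np.repeat(np.linspace(1.0, 0.0, 21), 3)

    def test_no_shift_limit_has_no_sign_flip(self):
        sim = simulate_pm_remap(0.0, 0.05, 1 / 3, self._ramp_p(), mode="mapping")
        assert np.allclose(sim.hidden["beta_p"], 0)
        assert sim.hidden["sign_flip_stride"] is None
        assert not np.any(sim.p_per < 0)

    def test_sign_flip_matches_exhaustive_scan(self):
        sim = simulate_pm_remap(0.56, 0.01, 1 / 3, self._ramp_p(), mode="mapping")
        p_per = sim.p_per
        scan = next(
            (k + 2 for k in range(len(p_per) - 1) if p_per[k] > 0 and p_per[k + 1] < 0), None
        )
        assert scan is not None
        assert sim.hidden["sign_flip_stride"] == scan

    def test_mapping_mode_tracks_then_floors(self):
        """u follows p down to η_p·p_plateau, then floors near that level."""
        eta_p = 0.5
        sim = simulate_pm_remap(eta_p, 0.01, 1 / 3, self._ramp_p(), mode="mapping")
        assert np.allclose(sim.u[:12], self._ramp_p()[:12], atol=0.02)
        # the floor sits near η_p·p_plateau, eroded slightly by forgetting (K)
        assert 0.7 * eta_p * 0.27 < sim.u[-1] < 1.1 * eta_p * 0.27

    def test_implicit_mode_shares_premo_fixed_point(self):
        """η_p = 1 implicit dynamics and PReMo converge to the same point.

        For constant p both settle where the perceived motor-output error
        vanishes: PM-ReMap at x_p = η_p·p, PReMo at x = p.
        """
        p = np.full(4000, 0.27)
        ours = simulate_pm_remap(1.0, 0.05, 1 / 3, p, mode="implicit")
        ref = simulate_premo(0.1, 1 / 3, p)
        assert abs(ours.u[-1] - 0.27) <= 1e-6
        assert abs(ours.u[-1] - ref.u[-1]) <= 1e-6

    def test_mapping_mode_requires_positive_weight(self):
        with pytest.raises(ValueError, match="W_p"):
            simulate_pm_remap(0.5, 0.1, 0.0, self._ramp_p(), mode="mapping")


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_simulators_are_length_preserving_and_deterministic(name):
    spec = get_model(name)
    p = np.repeat(np.linspace(0.3, 0.0, 7), 3)
    a = spec.simulate(spec.init_values, p)
    b = spec.simulate(spec.init_values, p)
    assert len(a.u) == len(p)
    assert np.array_equal(a.u, b.u)


@pytest.mark.parametrize("name", [n for n in MODEL_NAMES if n != "pm_remap"])
def test_zero_input_zero_output(name):
    """Every model started from rest stays at rest under p ≡ 0.

    recal_map is evaluated at r = 0 (a positive recalibration level is, by
    definition, a nonzero floor even without a perturbation).
    """
    spec = get_model(name)
    params = (0.0,) if name == "recal_map" else spec.init_values
    sim = spec.simulate(params, np.zeros(50))
    assert np.allclose(sim.u, 0)


def test_pm_remap_zero_input_implicit_mode_stays_at_rest():
    sim = simulate_pm_remap(0.5, 0.1, 1 / 3, np.zeros(50), mode="implicit")
    assert np.allclose(sim.u, 0)


def test_perceived_speed_three_way_rule():
    assert perceived_speed_prediction(0.1) == "faster"
    assert perceived_speed_prediction(-0.1) == "slower"
    assert perceived_speed_prediction(0.0) == "equal"
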