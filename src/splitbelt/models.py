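"""Forward simulators for models of Δ motor output during split-belt walking.

Every simulator maps a per-stride perturbation series p (in sla units) to the
modelled Δ motor output u, plus any internal states; perceptual models also
return the perceived perturbation p_per. All simulators are deterministic and
length-preserving, and start from zero internal state unless noted.

Models
------
recal_map
    Recalibration + mapping: u(k) = p(k) while p(k) ≥ r, else u(k) = r. The
    single parameter r is the fixed motor-output floor produced by forward
    model recalibration; the mapping mechanism tracks the perturbation above
    it instantaneously.
dual_state
    Two-rate state-space learner: fast and slow states with retention A and
    error sensitivity B, u = x_f + x_s.
optimal_control
    Finite-horizon LQG regulator over hidden state [p; s] with a forgetting
    perturbation estimate; u = −G·x̂ with LQR feedback gains and a
    steady-state Kalman gain.
memory_of_errors
    Single state with an error-history-dependent learning rate carried by a
    Gaussian basis over error space.
premo
    Proprioceptive re-alignment: perception of sla is the Bayesian integration
    of proprioception and the goal; the perceptual error drives adaptation.
pea
    Perceptual error adaptation: Bayesian-integrated perceived movement drives
    a retention/learning update; a separate Bayesian report defines p_per.
pm_remap
    Perceptuomotor recalibration + mapping: PReMo-style integration plus
    gradually learned perceptual shifts (rate K, extent η_p) and, in mapping
    mode, a goal G that re-targets the motor output to the current
    perturbation on the ramp down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: Gaussian basis grid for memory-of-errors (error units = sla)
DEFAULT_BASIS_CENTERS = np.linspace(-0.5, 0.5, 21)


@dataclass
class SimulationResult:
    """Per-stride simulator output: u, optional p_per, and internal states."""

    u: np.ndarray
    p_per: np.ndarray | None = None
    hidden: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.u)


def _as_series(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("perturbation series must be one-dimensional")
    return p


def simulate_recal_map(r: float, p) -> SimulationResult:
    """u(k) = p(k) if p(k) ≥ r, else r (pointwise upper envelope max(p, r))."""
    if r < 0:
        raise ValueError("recalibration level r must be >= 0")
    p = _as_series(p)
    return SimulationResult(u=np.maximum(p, r))


def simulate_dual_state(A_f: float, A_s: float, B_f: float, B_s: float, p) -> SimulationResult:
    """Two-rate model: x_·(k+1) = A_·x_·(k) + B_·(p(k) − x(k)), u = x_f + x_s."""
    # the simulator admits the closure of the fitting constraints
    # (0 < A_f < A_s < 1, 0 < B_s < B_f < 1); strict ordering is enforced by
    # the fitting parameterization
    if not (0 < A_f <= A_s <= 1):
        raise ValueError("require 0 < A_f <= A_s <= 1")
    if not (0 <= B_s <= B_f <= 1):
        raise ValueError("require 0 <= B_s <= B_f <= 1")
    p = _as_series(p)
    n = len(p)
    x_f = np.zeros(n)
    x_s = np.zeros(n)
    for k in range(n - 1):
        err = p[k] - (x_f[k] + x_s[k])
        x_f[k + 1] = A_f * x_f[k] + B_f * err
        x_s[k + 1] = A_s * x_s[k] + B_s * err
    return SimulationResult(u=x_f + x_s, hidden={"x_f": x_f, "x_s": x_s})


def lqg_gains(
    a: float,
    sigma_p2: float,
    sigma_s2: float,
    sigma_y2: float,
    horizon: int,
    q: float = 1.0,
    r_u: float = 0.01,
):
    """Finite-horizon LQR feedback gains and steady-state Kalman gain.

    System: x = [p; s], A = [[a, 0], [−1, 0]], B = [0; 1], y = Hx with
    H = [0, 1]; process noise cov diag(σ_p², σ_s²), observation noise σ_y².
    Cost J = Σ (q·y² + r_u·u²). Returns (G, K): G has shape (horizon, 2).
    """
    if not (0 <= a <= 1):
        raise ValueError("forgetting rate a must be in [0, 1]")
    if min(sigma_p2, sigma_s2, sigma_y2) <= 0:
        raise ValueError("noise variances must be positive")
    A = np.array([[a, 0.0], [-1.0, 0.0]])
    B = np.array([[0.0], [1.0]])
    H = np.array([[0.0, 1.0]])
    Q = q * (H.T @ H)
    # backward Riccati recursion for the feedback gains
    G = np.zeros((horizon, 2))
    S = Q.copy()
    for k in range(horizon - 1, -1, -1):
        denom = r_u + (B.T @ S @ B).item()
        Gk = (B.T @ S @ A) / denom
        G[k] = Gk[0]
        S = Q + A.T @ S @ (A - B @ Gk)
    # steady-state Kalman gain by fixed-point iteration of the filter Riccati
    Qx = np.diag([sigma_p2, sigma_s2])
    P = Qx.copy()
    for _ in range(10_000):
        innov_var = (H @ P @ H.T).item() + sigma_y2
        K = P @ H.T / innov_var
        P_new = A @ (P - K @ H @ P) @ A.T + Qx
        if np.max(np.abs(P_new - P)) < 1e-14:
            P = P_new
            break
        P = P_new
    K = P @ H.T / ((H @ P @ H.T).item() + sigma_y2)
    return G, K


def simulate_optimal_control(
    a: float,
    sigma_p2: float,
    sigma_s2: float,
    sigma_y2: float,
    p,
    q: float = 1.0,
    r_u: float = 0.01,
) -> SimulationResult:
    """LQG regulator of step length asymmetry.

    The controller issues u(k) = −G(k)·x̂(k) and updates its state estimate
    x̂ = [p̂; ŝ] from the sensory prediction error (−p(k) + p̂(k)), i.e. the
    difference between estimated and actual perturbation. The simulation is
    deterministic: the noise variances enter only through the Kalman gain.
    """
    p = _as_series(p)
    n = len(p)
    A = np.array([[a, 0.0], [-1.0, 0.0]])
    B = np.array([[0.0], [1.0]])
    G, K = lqg_gains(a, sigma_p2, sigma_s2, sigma_y2, n, q=q, r_u=r_u)
    x_hat = np.zeros((n, 2))
    u = np.zeros(n)
    for k in range(n):
        u[k] = -(G[k] @ x_hat[k])
        if k + 1 < n:
            innovation = -p[k] + x_hat[k, 0]
            x_hat[k + 1] = A @ x_hat[k] + B[:, 0] * u[k] + (A @ K)[:, 0] * innovation
    return SimulationResult(u=u, hidden={"x_hat": x_hat, "G": G, "K": K[:, 0]})


def simulate_memory_of_errors(
    sigma2: float,
    beta: float,
    eta0: float,
    a: float,
    p,
    basis_centers: np.ndarray = DEFAULT_BASIS_CENTERS,
) -> SimulationResult:
    """Single-state learner with an error-history-dependent learning rate.

        u(k+1) = a·u(k) + η(k, e(k))·e(k),   e(k) = p(k) − u(k)

    The learning rate is carried by a Gaussian basis over error space,
    η = wᵀ ĝ(e) with sum-normalized activations ĝ(e) = g(e)/Σ g(e); w is
    initialized at the naive rate η₀ and updated by β·sign(e(k−1)·e(k)) in the
    direction of the previous activation pattern, so sensitivity grows for
    consistently signed errors and shrinks for alternating ones. e(0) = 0, so
    no update occurs at the first stride.
    """
    if sigma2 <= 0:
        raise ValueError("basis variance sigma2 must be > 0")
    for name, val in (("beta", beta), ("eta0", eta0), ("a", a)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    centers = np.asarray(basis_centers, float)
    if centers.size == 0:
        raise ValueError("basis grid is empty")
    p = _as_series(p)
    n = len(p)

    def activations(e: float) -> np.ndarray:
        return np.exp(-((e - centers) ** 2) / (2 * sigma2))

    w = np.full(centers.size, eta0)
    u = np.zeros(n)
    eta = np.zeros(n)
    e_prev = 0.0
    degenerate = False
    for k in range(n):
        e = p[k] - u[k]
        g = activations(e)
        total = g.sum()
        if total < 1e-300:
            degenerate = True
            eta[k] = 0.0
        else:
            eta[k] = float(w @ (g / total))
        if k > 0:
            g_prev = activations(e_prev)
            norm = float(g_prev @ g_prev)
            if norm > 1e-300:
                w = w + beta * np.sign(e_prev * e) * g_prev / norm
        if k + 1 < n:
            u[k + 1] = a * u[k] + eta[k] * e
        e_prev = e
    return SimulationResult(u=u, hidden={"eta": eta, "w": w, "degenerate": degenerate})


def _goal_series(G, n: int) -> np.ndarray:
    if G is None:
        return np.zeros(n)
    if np.isscalar(G):
        return np.full(n, float(G))
    G = _as_series(G)
    if len(G) != n:
        raise ValueError("goal series length must match perturbation series")
    return G


def simulate_premo(K: float, W_p: float, p, G=None) -> SimulationResult:
    """Proprioceptive re-alignment model (no-vision form).

    Perceived sla is the Bayesian integration of proprioception and the goal,
    x_p^per = W_p·x_p + (1−W_p)·G (the visual shift β_p is zero without visual
    feedback); adaptation x(k+1) = x(k) + K·(G − x_p^per) with x_p = x − p and
    p_per = p − (x_p^per − x_p).
    """
    for name, val in (("K", K), ("W_p", W_p)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    p = _as_series(p)
    n = len(p)
    goal = _goal_series(G, n)
    x = np.zeros(n)
    p_per = np.zeros(n)
    x_p_per = np.zeros(n)
    for k in range(n):
        x_p = x[k] - p[k]
        x_p_per[k] = W_p * x_p + (1 - W_p) * goal[k]
        p_per[k] = p[k] - (x_p_per[k] - x_p)
        if k + 1 < n:
            x[k + 1] = x[k] + K * (goal[k] - x_p_per[k])
    return SimulationResult(u=x, p_per=p_per, hidden={"x_p_per": x_p_per})


def simulate_pea(A: float, B: float, W_p: float, p, T: float = 0.0) -> SimulationResult:
    """Perceptual error adaptation model.

    Perceived movement x̂_p = W_p·x_p + (1−W_p)·T drives a retention/learning
    update x(k+1) = A·x(k) + B·(T − x̂_p) with x_p = x − p. The reported sla
    used for perception is x_report = W_R·x_p + (1−W_R)·x̂_p with
    W_R = W_p/(1+W_p), and p_per = p − (x_report − x_p).
    """
    for name, val in (("A", A), ("B", B), ("W_p", W_p)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    p = _as_series(p)
    n = len(p)
    W_R = W_p / (1 + W_p)
    x = np.zeros(n)
    p_per = np.zeros(n)
    for k in range(n):
        x_p = x[k] - p[k]
        x_hat_p = W_p * x_p + (1 - W_p) * T
        x_report = W_R * x_p + (1 - W_R) * x_hat_p
        p_per[k] = p[k] - (x_report - x_p)
        if k + 1 < n:
            x[k + 1] = A * x[k] + B * (T - x_hat_p)
    return SimulationResult(u=x, p_per=p_per)


def simulate_pm_remap(
    eta_p: float,
    K: float,
    W_p: float,
    p,
    mode: str = "mapping",
    eta_v: float = 0.0,
    W_v: float | None = None,
) -> SimulationResult:
    """Perceptuomotor recalibration + mapping model.

    x_p is the motor-output estimate, x_v = x_p − p the actual sla. Integrated
    estimates mix each with the goal G by weights W_p / W_v; perceptual shifts
    β_p, β_v relax at rate K toward η_p(x_v^I − x_p^I) and η_v(x_p^I − x_v^I);
    perceived perturbation p_per = x_p^per − x_v^per; adaptation
    x_p(k+1) = x_p(k) + G(k) − x_p^per(k).

    mode='implicit': G ≡ 0, zero initial state (whole-paradigm simulation).
    mode='mapping' (ramp-down only): the goal re-targets the motor output to
    the upcoming perturbation, G(k+1) = max(0, β_p(k)/W_p + p(k+1)), starting
    from the adaptation-plateau fixed point: x_p(1) = p(1),
    β_p(1) = −η_p·W_p·p(1), β_v(1) = 0, G(1) = max(0, β_p(1)/W_p + p(1)).

    By default η_v = 0: without visual feedback the perception of the actual
    sla is not shifted (only the sensed motor output realigns). Returns the
    stride (1-based) of the first positive→negative sign flip of p_per in
    ``hidden['sign_flip_stride']`` (None if no flip).
    """
    for name, val in (("eta_p", eta_p), ("K", K), ("W_p", W_p), ("eta_v", eta_v)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if mode not in ("implicit", "mapping"):
        raise ValueError(f"mode must be 'implicit' or 'mapping', got {mode!r}")
    if W_v is None:
        W_v = W_p
    p = _as_series(p)
    n = len(p)
    x_p = np.zeros(n)
    beta_p = np.zeros(n)
    beta_v = np.zeros(n)
    goal = np.zeros(n)
    if mode == "mapping":
        if W_p <= 0:
            raise ValueError("mapping mode needs W_p > 0")
        x_p[0] = p[0]
        beta_p[0] = -eta_p * W_p * p[0]
        goal[0] = max(0.0, beta_p[0] / W_p + p[0])
    p_per = np.zeros(n)
    u = np.zeros(n)
    for k in range(n):
        u[k] = x_p[k]
        x_v = x_p[k] - p[k]
        x_p_I = W_p * x_p[k] + (1 - W_p) * goal[k]
        x_v_I = W_v * x_v + (1 - W_v) * goal[k]
        x_p_per = x_p_I + beta_p[k]
        x_v_per = x_v_I + beta_v[k]
        p_per[k] = x_p_per - x_v_per
        if k + 1 < n:
            beta_p[k + 1] = beta_p[k] + K * (eta_p * (x_v_I - x_p_I) - beta_p[k])
            beta_v[k + 1] = beta_v[k] + K * (eta_v * (x_p_I - x_v_I) - beta_v[k])
            x_p[k + 1] = x_p[k] + goal[k] - x_p_per
            if mode == "mapping":
                goal[k + 1] = max(0.0, beta_p[k] / W_p + p[k + 1])
    flips = np.flatnonzero((p_per[:-1] > 0) & (p_per[1:] < 0))
    sign_flip = int(flips[0] + 2) if flips.size else None  # 1-based stride of first negative
    return SimulationResult(
        u=u,
        p_per=p_per,
        hidden={"beta_p": beta_p, "beta_v": beta_v, "goal": goal, "sign_flip_stride": sign_flip},
    )


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: parameter names, defaults, bounds, and the simulator.

    ``simulate(params, p)`` runs the model over a perturbation series;
    ``ramp_only`` marks models that are simulated on the post-adaptation ramp
    alone (no pre-ramp hidden-state history).
    """

    name: str
    param_names: tuple[str, ...]
    init_values: tuple[float, ...]
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]
    simulate: Callable[..., SimulationResult]
    ramp_only: bool = False

    def __post_init__(self):
        k = len(self.param_names)
        if not (len(self.init_values) == len(self.lower_bounds) == len(self.upper_bounds) == k):
            raise ValueError("parameter name/init/bound lengths differ")
        for init, lo, hi in zip(self.init_values, self.lower_bounds, self.upper_bounds):
            if not (lo <= init <= hi) or lo > hi:
                raise ValueError("initial values must lie within ordered bounds")

    @property
    def k_params(self) -> int:
        return len(self.param_names)


def _dual_state_sim(params, p):
    # fitted in an ordering-preserving parameterization:
    # (A_s, rho_A = A_f/A_s, B_f, rho_B = B_s/B_f), each in (0, 1)
    A_s, rho_A, B_f, rho_B = params
    return simulate_dual_state(A_s * rho_A, A_s, B_f, B_f * rho_B, p)


MODEL_REGISTRY: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in [
        ModelSpec(
            "recal_map", ("r",), (0.135,), (0.0,), (0.27,),
            lambda params, p: simulate_recal_map(params[0], p),
            ramp_only=True,
        ),
        ModelSpec(
            # printed inits A_f=0.92, A_s=0.99, B_f=0.1, B_s=0.01 expressed in
            # the ordering-preserving parameterization
            "dual_state",
            ("A_s", "rho_A", "B_f", "rho_B"),
            (0.99, 0.92 / 0.99, 0.1, 0.1),
            (1e-6, 1e-6, 1e-6, 1e-6),
            (1 - 1e-6, 1 - 1e-6, 1 - 1e-6, 1 - 1e-6),
            _dual_state_sim,
        ),
        ModelSpec(
            "optimal_control",
            ("a", "sigma_p2", "sigma_s2", "sigma_y2"),
            (0.9, 0.01, 0.01, 0.01),
            (0.0, 1e-6, 1e-6, 1e-6),
            (1.0, 10.0, 10.0, 10.0),
            lambda params, p: simulate_optimal_control(*params, p),
        ),
        ModelSpec(
            "memory_of_errors",
            ("sigma2", "beta", "eta0", "a"),
            (0.5, 0.001, 0.001, 0.9),
            (1e-6, 0.0, 0.0, 0.0),
            (10.0, 1.0, 1.0, 1.0),
            lambda params, p: simulate_memory_of_errors(*params, p),
        ),
        ModelSpec(
            "premo", ("K", "W_p"), (0.03, 1 / 3), (0.0, 0.0), (1.0, 1.0),
            lambda params, p: simulate_premo(*params, p),
        ),
        ModelSpec(
            "pea", ("A", "B", "W_p"), (0.97, 0.2, 1 / 3), (0.0, 0.0, 0.0), (1.0, 1.0, 1.0),
            lambda params, p: simulate_pea(*params, p),
        ),
        ModelSpec(
            "pm_remap", ("eta_p", "K", "W_p"), (0.5, 0.01, 1 / 3),
            (0.0, 0.0, 1e-6), (1.0, 1.0, 1.0),
            lambda params, p: simulate_pm_remap(*params, p, mode="mapping"),
            ramp_only=True,
        ),
    ]
}

MODEL_NAMES = tuple(MODEL_REGISTRY)


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {MODEL_NAMES}") from None


def perceived_speed_prediction(p_per: float) -> str:
    """Three-way verbal prediction from the perceived perturbation sign."""
    if p_per > 0:
        return "faster"
    if p_per < 0:
        return "slower"
    return "equal"
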