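"""Gain-regulated three-state Kalman filter for stride-length estimation.

The state is ``x = [p, v, a]`` — per-stride displacement (m), velocity
(m/s) and acceleration (m/s²) along the measurement axis. The transition
uses the printed kinematic form

    A = [[1, Δt, 0],
         [0, 1, Δt],
         [0, 0, 1]]

(no ½Δt² coupling of acceleration into displacement; a config switch
offers the full constant-acceleration discretisation for comparison), and
the measurement ``z = H x + v`` with ``H = [0, 0, 1]`` observes the
acceleration state directly. Because A and H are constant the filter is
the constant-Jacobian special case of an EKF, i.e. numerically a linear
Kalman filter.

Two modifications distinguish the "modified" filter from the plain one:

* **Zero-crossing gain regulation** — when the measured acceleration
  changes sign (strictly: ``z_prev * z_curr < 0``), the effective
  measurement variance is divided by ``boost_factor`` for the next
  ``boost_samples`` updates, raising the Kalman gain toward the
  measurement and speeding convergence through the signal's fast turning
  regions.
* **Sign-flip consistency rule** — a logical check on the emitted
  displacement sequence: if adjacent displacements have strictly negative
  product the current one's sign is flipped to match its predecessor,
  magnitude preserved. It is applied on output only — it feeds nothing
  back into the state recursion and never alters the gain or covariance
  (fed back, the rule can pin a noisy near-zero displacement and stall
  the integration entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterState",
    "FilterConfig",
    "kf_predict",
    "kf_update",
    "detect_zero_crossing",
    "sign_flip_correct",
    "run_mekf",
    "stride_length_from_states",
]

_SYM_TOL = 1e-10


@dataclass
class FilterState:
    """State mean ``x = [p, v, a]`` with its 3×3 covariance ``P``."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.P = np.asarray(self.P, dtype=float).reshape(3, 3)
        if np.max(np.abs(self.P - self.P.T)) > _SYM_TOL:
            raise ValueError("covariance P must be symmetric")
        if np.min(np.linalg.eigvalsh(self.P)) < -1e-10:
            raise ValueError("covariance P must be positive semi-definite")

    @property
    def displacement(self) -> float:
        return float(self.x[0])

    @property
    def velocity(self) -> float:
        return float(self.x[1])

    @property
    def acceleration(self) -> float:
        return float(self.x[2])


@dataclass
class FilterConfig:
    """All filter tunables.

    Defaults (Q, R, P0) are chosen for stability on the synthetic gait
    generator and are all settable from config files. ``boost_factor`` /
    ``boost_samples`` parametrise the zero-crossing gain regulation;
    ``full_ca_transition`` switches the transition matrix to the textbook
    constant-acceleration discretisation with the ½Δt² term.
    """

    dt: float = 0.02
    Q: np.ndarray = field(
        default_factory=lambda: np.diag([1e-6, 1e-4, 1e-2])
    )
    R: float = 0.05
    x0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    P0: np.ndarray = field(default_factory=lambda: np.eye(3))
    boost_factor: float = 10.0
    boost_samples: int = 3
    sign_flip_enabled: bool = True
    calibration: float = 1.0
    full_ca_transition: bool = False

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float).reshape(3, 3)
        self.x0 = np.asarray(self.x0, dtype=float).reshape(3)
        self.P0 = np.asarray(self.P0, dtype=float).reshape(3, 3)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.R > 0:
            raise ValueError("R must be positive")
        if np.min(np.linalg.eigvalsh((self.Q + self.Q.T) / 2)) < -1e-10:
            raise ValueError("Q must be positive semi-definite")
        if self.boost_factor < 1:
            raise ValueError("boost_factor must be ≥ 1")
        if self.boost_samples < 0:
            raise ValueError("boost_samples must be ≥ 0")

    @property
    def A(self) -> np.ndarray:
        dt = self.dt
        A = np.array([[1.0, dt, 0.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
        if self.full_ca_transition:
            A[0, 2] = 0.5 * dt * dt
        return A

    @property
    def B(self) -> np.ndarray:
        # stored for dimensional completeness only; the control input u ≡ 0
        dt = self.dt
        return np.array([[0.5 * dt * dt], [dt], [1.0]])

    @property
    def H(self) -> np.ndarray:
        return np.array([[0.0, 0.0, 1.0]])


def kf_predict(state: FilterState, cfg: FilterConfig) -> FilterState:
    """Time update: ``x̄⁻ = A x`` and ``P̄ = A P Aᵀ + Q`` (u contributes
    nothing)."""
    A = cfg.A
    x_prior = A @ state.x
    P_prior = A @ state.P @ A.T + cfg.Q
    return FilterState(x=x_prior, P=(P_prior + P_prior.T) / 2)


def kf_update(
    prior: FilterState, z: float, cfg: FilterConfig, boosted: bool = False
) -> FilterState:
    """Measurement update with optional gain boost.

    ``K = P̄Hᵀ (HP̄Hᵀ + R_eff)⁻¹`` with ``R_eff = R / boost_factor`` at
    boosted steps; then ``x = x̄⁻ + K (z − Hx̄⁻)`` and ``P = (I − KH) P̄``,
    re-symmetrised.
    """
    H = cfg.H
    r_eff = cfg.R / cfg.boost_factor if boosted else cfg.R
    S = (H @ prior.P @ H.T).item() + r_eff
    if S <= 0:
        raise ValueError("innovation variance HP̄Hᵀ + R is not positive")
    K = (prior.P @ H.T) / S  # 3×1
    innov = z - (H @ prior.x).item()
    x_post = prior.x + (K[:, 0] * innov)
    P_post = (np.eye(3) - K @ H) @ prior.P
    return FilterState(x=x_post, P=(P_post + P_post.T) / 2)


def detect_zero_crossing(z_prev: float, z_curr: float) -> bool:
    """True iff the measurement strictly changes sign (exact zeros do not
    trigger)."""
    return z_prev * z_curr < 0


def sign_flip_correct(p_curr: float, p_prev: float) -> float:
    """Make the displacement sign consistent with its predecessor.

    Returns ``−p_curr`` when ``p_curr * p_prev < 0``, else ``p_curr``;
    magnitude is always preserved.
    """
    if p_curr * p_prev < 0:
        return -p_curr
    return p_curr


def run_mekf(measurements: np.ndarray, cfg: FilterConfig) -> list[FilterState]:
    """Filter a measurement sequence, returning the posterior trajectory.

    Per sample: predict; test for a zero crossing against the previous
    measurement and, if crossed, boost the next ``boost_samples`` updates;
    update; then (when enabled) pass the posterior displacement through
    the sign-flip consistency check against the previously *emitted*
    displacement before emitting it. The check is a logical filter on the
    output sequence only — it feeds nothing back into the recursion and
    touches neither gain nor covariance — so the emitted displacement
    sequence carries no non-physical sign reversals while the state
    recursion stays a pure Kalman filter. With ``boost_factor = 1`` and
    the sign-flip disabled the trajectory is identical to a textbook
    linear Kalman filter with the same A, H, Q, R.
    """
    z = np.asarray(measurements, dtype=float)
    if z.ndim != 1 or len(z) < 2:
        raise ValueError("need at least 2 measurements")
    state = FilterState(x=cfg.x0.copy(), P=cfg.P0.copy())
    out: list[FilterState] = []
    boost_left = 0
    p_emitted = float(state.x[0])
    for k in range(len(z)):
        prior = kf_predict(state, cfg)
        if k > 0 and detect_zero_crossing(z[k - 1], z[k]):
            boost_left = cfg.boost_samples
        boosted = boost_left > 0 and cfg.boost_factor > 1
        if boost_left > 0:
            boost_left -= 1
        state = kf_update(prior, float(z[k]), cfg, boosted=boosted)
        if cfg.sign_flip_enabled:
            p_out = sign_flip_correct(float(state.x[0]), p_emitted)
            emitted = FilterState(
                x=np.array([p_out, state.x[1], state.x[2]]), P=state.P
            )
        else:
            emitted = state
        p_emitted = float(emitted.x[0])
        out.append(emitted)
    return out


def stride_length_from_states(
    states: list[FilterState], cfg: FilterConfig
) -> float:
    """Stride length as |p_end − p_start| of the filtered displacement,
    scaled by the calibration factor."""
    if len(states) < 3:
        raise ValueError("need at least 3 states for a stride")
    return (
        abs(states[-1].displacement - states[0].displacement) * cfg.calibration
    )
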