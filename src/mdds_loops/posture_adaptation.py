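"""Posture stabilization and internal-model adaptation.

A normalized linearized inverted pendulum (unit inertia) models body posture:

    theta'' = omega_u**2 * theta + u_C + u_A + d(t)

Loop C is a proportional-derivative stabilizer ``u_C = -Kp theta - Kd theta'``.
Loop A is the adaptation mechanism: a second-order resonant compensator with
poles at ``-rho*omega_c +/- i*omega_c*sqrt(1-rho**2)``, driven by the posture
error with gain ``k_a``; its output ``u_A`` is the compensator's velocity
state.  By the internal-model principle, an undamped compensator
(``rho = 0``) tuned to the disturbance frequency cancels a sinusoidal
disturbance exactly, in phase opposition.  After the disturbance stops
(disembarkation) the compensator rings down with time constant
``1/(rho*omega_c)`` — the transient "mal de debarquement"; at ``rho = 0`` it
is a permanent oscillator whose output is the phantom-motion signal of MdDS.
The stabilizing loop always prevails: the oscillator perturbs but never
destabilizes posture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import butter, filtfilt, periodogram

__all__ = [
    "PostureParams",
    "DisturbanceSpec",
    "PostureTrajectory",
    "entrained_state",
    "simulate_posture",
    "steady_state_residual",
    "post_removal_response",
    "phantom_motion_signal",
    "frequency_response",
    "pd_only_gain",
]

DISTURBANCE_KINDS = ("pure_sine", "sine_plus_noise", "broadband")


@dataclass(frozen=True)
class PostureParams:
    """Pendulum, PD-stabilizer and internal-model-compensator parameters.

    omega_u : gravitational destabilization rate of the linearized pendulum
        (1/s); ~sqrt(g/l) for a 1 m inverted pendulum.
    kp, kd : PD gains; stability of loop C alone requires kp > omega_u**2
        and kd > 0.
    omega_c : compensator centre frequency (rad/s); set to the entrained
        disturbance frequency.
    rho : compensator damping ratio (>= 0); 0 = permanent oscillator.
    k_a : adaptation gain coupling the posture error into the compensator.
        Weak coupling keeps the ashore ring-down governed by rho itself.
    """

    omega_u: float = 3.0
    kp: float = 20.0
    kd: float = 8.0
    omega_c: float = 2 * math.pi * 0.25
    rho: float = 0.02
    k_a: float = 5e-4

    def __post_init__(self) -> None:
        vals = [self.omega_u, self.kp, self.kd, self.omega_c, self.rho, self.k_a]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("posture parameters must be finite")
        if self.kp <= self.omega_u**2:
            raise ValueError("kp must exceed omega_u**2 (loop C must stabilize the pendulum)")
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.omega_c <= 0:
            raise ValueError("omega_c must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.k_a < 0:
            raise ValueError("k_a must be non-negative")


@dataclass(frozen=True)
class DisturbanceSpec:
    """Synthetic disturbance: regular wave versus noise-dominated travel.

    ``pure_sine`` emulates the single-component swell of boat or plane
    travel; ``sine_plus_noise`` adds white noise; ``broadband`` is filtered
    noise with no dominant line (car or train).
    """

    kind: str = "pure_sine"
    amplitude: float = 0.05  # rad/s^2 equivalent forcing
    frequency: float = 0.25  # Hz
    noise_level: float = 0.0
    t_aboard: float = 200.0
    t_ashore: float = 500.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DISTURBANCE_KINDS:
            raise ValueError(f"kind must be one of {DISTURBANCE_KINDS}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frequency >= 0.5 / self.dt:
            raise ValueError("frequency at or above Nyquist for this dt")
        if self.t_aboard <= 0 or self.t_ashore < 0:
            raise ValueError("phase durations must be positive")
        if self.amplitude < 0 or self.noise_level < 0:
            raise ValueError("amplitude and noise level must be non-negative")


@dataclass(frozen=True)
class PostureTrajectory:
    """Simulated posture angle, loop outputs and disturbance, phase-tagged."""

    t: np.ndarray
    aboard: np.ndarray  # boolean mask
    theta: np.ndarray
    theta_dot: np.ndarray
    u_C: np.ndarray
    u_A: np.ndarray
    d: np.ndarray
    params: PostureParams
    spec: DisturbanceSpec

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def state_matrix(params: PostureParams) -> np.ndarray:
    """Closed-loop state matrix for x = [theta, theta', xi, xi']; u_A = xi'."""
    p = params
    return np.array([
        [0.0, 1.0, 0.0, 0.0],
        [p.omega_u**2 - p.kp, -p.kd, 0.0, 1.0],
        [0.0, 0.0, 0.0, 1.0],
        [-p.k_a, 0.0, -p.omega_c**2, -2.0 * p.rho * p.omega_c],
    ])


_B_DIST = np.array([0.0, 1.0, 0.0, 0.0])


def is_stable(params: PostureParams, margin: float = 0.0) -> bool:
    return bool(np.all(np.linalg.eigvals(state_matrix(params)).real < -margin))


def entrained_state(params: PostureParams, amplitude: float, frequency: float) -> np.ndarray:
    """Steady (entrained) state at t = 0 under ``d(t) = D sin(2 pi f t)``.

    Solved by phasors: the paper's scenario treats entrainment aboard as
    accomplished, so simulations default to starting here.
    """
    w = 2 * math.pi * frequency
    if params.k_a == 0.0:
        # compensator decoupled (and possibly resonant): pendulum phasor only
        s = 1j * w
        th = amplitude / (s**2 + params.kd * s + (params.kp - params.omega_u**2))
        x_ph = np.array([th, s * th, 0.0, 0.0])
    else:
        a = state_matrix(params)
        x_ph = np.linalg.solve(1j * w * np.eye(4) - a, _B_DIST * amplitude)
    return x_ph.imag.copy()


def _disturbance_series(spec: DisturbanceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sampled disturbance on the aboard grid (helper shared with scenarios_io)."""
    n = int(round(spec.t_aboard / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "pure_sine":
        d = spec.amplitude * np.sin(2 * np.pi * spec.frequency * t)
    elif spec.kind == "sine_plus_noise":
        d = spec.amplitude * np.sin(2 * np.pi * spec.frequency * t)
        d = d + spec.noise_level * rng.standard_normal(n)
    else:  # broadband: low-pass filtered white noise, no dominant line
        white = rng.standard_normal(n)
        b, a = butter(4, min(4.0 * spec.frequency * spec.dt * 2.0, 0.9))
        d = filtfilt(b, a, white)
        rms = float(np.sqrt(np.mean(d**2)))
        if rms > 0:
            d = d * (spec.amplitude / math.sqrt(2.0) / rms)
    return t, d


def simulate_posture(
    params: PostureParams,
    dist: DisturbanceSpec,
    entrained_start: bool = True,
    x0: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> PostureTrajectory:
    """Integrate both phases: aboard (disturbance on) then ashore (off).

    With ``entrained_start`` the aboard phase begins at the phasor steady
    state; otherwise from rest, exposing the adaptation transient.  An
    explicit ``x0 = [theta, theta', xi, xi']`` overrides both.
    """
    a = state_matrix(params)
    if dist.kind == "pure_sine":
        w = 2 * math.pi * dist.frequency

        def d_fn(t):
            return dist.amplitude * math.sin(w * t)
    else:
        td, dd = _disturbance_series(dist)

        def d_fn(t):
            return float(np.interp(t, td, dd))

    def rhs(t, x):
        dx = a @ x
        dx[1] += d_fn(t)
        return dx

    if x0 is None:
        x0 = (entrained_state(params, dist.amplitude, dist.frequency)
              if entrained_start else np.zeros(4))
    else:
        x0 = np.asarray(x0, dtype=float)
    n_ab = int(round(dist.t_aboard / dist.dt))
    t_ab = dist.dt * np.arange(n_ab + 1)
    sol1 = solve_ivp(rhs, (0.0, t_ab[-1]), x0, t_eval=t_ab, rtol=rtol, atol=atol,
                     max_step=1.0 / max(dist.frequency, 0.1))
    if not sol1.success:  # pragma: no cover
        raise RuntimeError(sol1.message)

    def rhs_free(t, x):
        return a @ x

    n_as = int(round(dist.t_ashore / dist.dt))
    t_as = t_ab[-1] + dist.dt * np.arange(1, n_as + 1)
    sol2 = solve_ivp(rhs_free, (t_ab[-1], t_as[-1]), sol1.y[:, -1], t_eval=t_as,
                     rtol=rtol, atol=atol)
    if not sol2.success:  # pragma: no cover
        raise RuntimeError(sol2.message)

    t = np.concatenate([sol1.t, sol2.t])
    x = np.concatenate([sol1.y, sol2.y], axis=1).T
    aboard = t <= t_ab[-1] + 0.5 * dist.dt
    aboard[len(sol1.t):] = False
    d = np.array([d_fn(tt) for tt in sol1.t] + [0.0] * len(sol2.t))
    theta, theta_dot = x[:, 0], x[:, 1]
    u_C = -params.kp * theta - params.kd * theta_dot
    u_A = x[:, 3]
    return PostureTrajectory(t, aboard, theta, theta_dot, u_C, u_A, d, params, dist)


def _amplitude(y: np.ndarray) -> float:
    return 0.5 * float(y.max() - y.min())


def steady_state_residual(traj: PostureTrajectory, window: float) -> float:
    """Half peak-to-peak of theta over the last ``window`` seconds aboard."""
    t_ab = traj.t[traj.aboard]
    if window <= 0 or window > t_ab[-1] - t_ab[0]:
        raise ValueError("window must lie within the aboard phase")
    sel = traj.aboard & (traj.t >= t_ab[-1] - window)
    return _amplitude(traj.theta[sel])


def _peak_envelope(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # the ring-down oscillates around zero; no detrending, or its own mean
    # would masquerade as an envelope plateau
    mag = np.abs(y)
    pk = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    idx = np.where(pk)[0] + 1
    # keep peaks well above the integrator noise floor, or the fitted slope
    # is biased once the ring-down reaches the solver tolerance
    floor = 1e-6 * max(float(mag.max()), 1e-300)
    idx = idx[mag[idx] > floor]
    return t[idx], mag[idx]


def post_removal_response(traj: PostureTrajectory) -> tuple[float, float, str]:
    """Ring-down analysis of the adaptation output ashore.

    Returns ``(ringing frequency Hz, decay time constant tau, regime)``;
    regime is ``persistent_MdDS`` iff the fitted envelope drifts by less
    than 1% over the last 50 cycles, else ``recovering_MdD``.
    """
    ashore = ~traj.aboard
    t, y = traj.t[ashore], traj.u_A[ashore]
    period = 2 * math.pi / traj.params.omega_c
    if t[-1] - t[0] < 20 * period:
        raise ValueError("ashore phase shorter than 20 compensator periods")
    fs = 1.0 / traj.dt
    yc = y - y.mean()
    if np.abs(yc).max() < 1e-300:
        return 0.0, 0.0, "recovering_MdD"
    freqs, power = periodogram(yc, fs=fs)
    f_ring = float(freqs[1:][np.argmax(power[1:])])
    tp, ep = _peak_envelope(t, y)
    if len(tp) < 4:
        return f_ring, 0.0, "recovering_MdD"
    slope, _ = np.polyfit(tp, np.log(ep), 1)
    tau = math.inf if slope >= 0 else -1.0 / slope
    window = 50 * period
    drift = abs(1.0 - math.exp(slope * window))
    regime = "persistent_MdDS" if drift < 0.01 else "recovering_MdD"
    return f_ring, tau, regime


def phantom_motion_signal(traj: PostureTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """The adaptation output ashore: the undesired input into loop C that is
    perceived as phantom self-motion."""
    ashore = ~traj.aboard
    if not ashore.any():
        raise ValueError("trajectory has no ashore phase")
    return traj.t[ashore], traj.u_A[ashore]


def frequency_response(params: PostureParams, f_grid) -> np.ndarray:
    """Closed-form disturbance-to-angle gain |theta/d| at each frequency (Hz).

    The transfer function is ``(s^2 + 2 rho w_c s + w_c^2) / Delta(s)`` with
    ``Delta = (s^2 + kd s + kp - w_u^2)(s^2 + 2 rho w_c s + w_c^2) + k_a s``:
    a notch at ``w_c`` whose depth diverges as ``rho -> 0``.
    """
    if not is_stable(params):
        raise ValueError("closed loop is unstable for these parameters")
    f_grid = np.atleast_1d(np.asarray(f_grid, dtype=float))
    s = 1j * 2 * np.pi * f_grid
    p = params
    comp = s**2 + 2 * p.rho * p.omega_c * s + p.omega_c**2
    pd = s**2 + p.kd * s + (p.kp - p.omega_u**2)
    return np.abs(comp / (pd * comp + p.k_a * s))


def pd_only_gain(params: PostureParams, f: float) -> float:
    """|theta/d| of the PD loop alone (adaptation disabled)."""
    s = 1j * 2 * math.pi * f
    return float(abs(1.0 / (s**2 + params.kd * s + (params.kp - params.omega_u**2))))


def without_adaptation(params: PostureParams) -> PostureParams:
    """Same parameters with loop A disabled."""
    return replace(params, k_a=0.0)
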