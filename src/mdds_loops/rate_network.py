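"""Nonlinear firing-rate realization of the loop network.

The four node activities evolve as

    dx_i/dt = -d_i x_i + sum_j W_ij tanh(s x_j) + u_i(t)

so the linearization at the origin is ``J = -D + s W``, whose sign pattern
matches the canonical loop structure.  The module exists to verify the
spectral predictions of the Jacobian ensemble in the time domain and to
demonstrate entrainment of the network by a periodic (wave-like) input at
the vestibular nuclei.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import periodogram

from . import jacobian_ensemble as je
from .modal import exponential_modes, has_growing_oscillation

__all__ = [
    "RateNetworkParams",
    "NetworkTrajectory",
    "OscillationDescriptor",
    "params_from_scheme",
    "params_from_jacobian",
    "simulate",
    "linearize",
    "detect_oscillation",
    "entrain",
    "oscillatory_departure",
]

#: Envelope-slope dead band (per cycle) inside which an oscillation counts
#: as sustained rather than decaying or growing.
SUSTAINED_DEADBAND = 1e-3

_VN_NODES = (1, 2)  # indices of VN_A, VN_B in the canonical node order


@dataclass(frozen=True)
class RateNetworkParams:
    """Connection matrix, per-node decay, activation slope and input gains."""

    W: np.ndarray
    decay: np.ndarray
    slope: float = 1.0
    input_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        decay = np.broadcast_to(np.asarray(self.decay, dtype=float), (4,)).copy()
        gain = (np.ones(4) if self.input_gain is None
                else np.broadcast_to(np.asarray(self.input_gain, dtype=float), (4,)).copy())
        if W.shape != (4, 4) or not np.all(np.isfinite(W)):
            raise ValueError("W must be a finite 4x4 matrix")
        if np.any(decay <= 0) or not np.all(np.isfinite(decay)):
            raise ValueError("decays must be positive and finite")
        if self.slope <= 0 or not np.isfinite(self.slope):
            raise ValueError("activation slope must be positive and finite")
        sign = je.canonical_structure().sign_pattern
        nz = np.abs(W) > 1e-9  # entries below this are treated as absent
        if np.any(np.sign(W[nz]) != sign[nz]):
            raise ValueError("sign(W) must match the canonical loop structure")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "decay", decay)
        object.__setattr__(self, "input_gain", gain)

    def digest(self) -> str:
        payload = json.dumps(
            {"W": self.W.tolist(), "decay": self.decay.tolist(),
             "slope": self.slope, "input_gain": self.input_gain.tolist()},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class NetworkTrajectory:
    """Uniformly sampled node activities with the applied input."""

    t: np.ndarray
    x: np.ndarray  # shape (n, 4)
    u: np.ndarray  # shape (n, 4)
    params_digest: str = ""
    seed: int | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class OscillationDescriptor:
    dominant_frequency: float  # Hz
    damping_label: str  # decaying | sustained | growing
    envelope_rate: float  # 1/s, sign matches the label


def params_from_scheme(
    scheme: je.WeightScheme,
    mode: str = "mean",
    rng: np.random.Generator | None = None,
    decay: float = 0.5,
    slope: float = 1.0,
    structure: je.LoopStructure | None = None,
) -> RateNetworkParams:
    """Build network weights from a class-weight scheme.

    ``mode='mean'`` uses the deterministic mid-scale value ``sign * w_class``;
    ``mode='sample'`` freezes one random draw (requires ``rng``).
    """
    structure = structure or je.canonical_structure()
    if mode == "mean":
        W = structure.sign_pattern * je.weight_matrix(structure, scheme)
    elif mode == "sample":
        if rng is None:
            raise ValueError("mode='sample' requires an rng")
        W = je.sample_jacobian(structure, scheme, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return params_from_jacobian(W + 0.0, decay=decay, slope=slope)


def params_from_jacobian(J, decay: float = 0.5, slope: float = 1.0) -> RateNetworkParams:
    """Embed a sampled Jacobian: choose positive decays d_i < |J_ii| and set
    ``W = (J + D)/s`` so that ``linearize(params, 0) == J`` exactly."""
    J = np.asarray(J, dtype=float)
    d = np.minimum(decay, 0.5 * np.abs(np.diag(J)))
    d = np.maximum(d, 1e-9)  # decays must stay positive even for tiny J_ii
    W = (J + np.diag(d)) / slope
    return RateNetworkParams(W=W, decay=d, slope=slope)


def _rhs(params: RateNetworkParams) -> Callable[[float, np.ndarray, Callable], np.ndarray]:
    W, d, s, g = params.W, params.decay, params.slope, params.input_gain

    def rhs(t, x, u_fn):
        return -d * x + W @ np.tanh(s * x) + g * u_fn(t)

    return rhs


def state_bound(params: RateNetworkParams, u_max: float = 0.0) -> float:
    """Analytic bound: |x_i| <= (sum_j |W_ij| + max|u|) / min d_i at large t."""
    return float((np.abs(params.W).sum(axis=1).max() + u_max) / params.decay.min())


def simulate(
    params: RateNetworkParams,
    input_fn: Callable[[float], np.ndarray] | None,
    t_span: tuple[float, float],
    dt: float,
    x0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> NetworkTrajectory:
    """Integrate the rate equations with an adaptive RK scheme.

    ``input_fn(t)`` returns the 4-vector input (None = autonomous).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    u_fn = (lambda t: np.zeros(4)) if input_fn is None else input_fn
    x0 = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float)
    t_eval = t0 + dt * np.arange(int(round((t1 - t0) / dt)) + 1)
    sol = solve_ivp(
        _rhs(params), (t0, t_eval[-1]), x0, t_eval=t_eval,
        args=(u_fn,), rtol=rtol, atol=atol, method="RK45",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"integration failed: {sol.message}")
    u = np.array([u_fn(t) for t in sol.t])
    return NetworkTrajectory(sol.t, sol.y.T, u, params.digest())


def linearize(params: RateNetworkParams, x_star, tol: float = 1e-8) -> np.ndarray:
    """Jacobian at an equilibrium: ``J_ij = -d_i delta_ij + W_ij s sech^2(s x*_j)``.

    Raises if ``x_star`` is not an equilibrium of the autonomous system
    (residual norm reported in the error).
    """
    x_star = np.broadcast_to(np.asarray(x_star, dtype=float), (4,))
    resid = _rhs(params)(0.0, x_star, lambda t: np.zeros(4))
    rnorm = float(np.linalg.norm(resid))
    if rnorm > tol:
        raise ValueError(f"x_star is not an equilibrium: residual norm {rnorm:.3e} > {tol:.1e}")
    s = params.slope
    sech2 = 1.0 / np.cosh(s * x_star) ** 2
    return -np.diag(params.decay) + params.W * (s * sech2)[None, :]


def _envelope_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Log-envelope slope (1/s) fitted on local |maxima| of the signal."""
    y = y - y.mean()
    mag = np.abs(y)
    # local peaks of |y|
    pk = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    idx = np.where(pk)[0] + 1
    idx = idx[mag[idx] > 1e-12 * max(mag.max(), 1e-300)]
    if len(idx) < 4:
        return 0.0
    slope, _ = np.polyfit(t[idx], np.log(mag[idx]), 1)
    return float(slope)


def detect_oscillation(
    traj: NetworkTrajectory,
    transient_fraction: float = 0.25,
    deadband_per_cycle: float = SUSTAINED_DEADBAND,
) -> OscillationDescriptor:
    """Dominant frequency (periodogram peak) and damping label of a trajectory.

    The leading fraction of samples is discarded as transient; the damping
    label comes from the sign of the fitted log-envelope slope with a dead
    band of ``deadband_per_cycle`` (per oscillation cycle) around zero.
    """
    n = len(traj.t)
    if n < 32:
        raise ValueError("trajectory too short for oscillation analysis")
    k0 = int(n * transient_fraction)
    t, X = traj.t[k0:], traj.x[k0:]
    comp = int(np.argmax(X.std(axis=0)))
    y = X[:, comp] - X[:, comp].mean()
    fs = 1.0 / traj.dt
    freqs, power = periodogram(y, fs=fs, detrend="constant")
    noise_floor = 1e-12 * max(float(np.abs(y).max()) ** 2, 1e-300)
    if power[1:].max(initial=0.0) <= noise_floor:
        return OscillationDescriptor(0.0, "decaying", 0.0)
    f_dom = float(freqs[1:][np.argmax(power[1:])])
    rate = _envelope_rate(t, y)
    deadband = deadband_per_cycle * (f_dom if f_dom > 0 else 1.0)
    if rate > deadband:
        label = "growing"
    elif rate < -deadband:
        label = "decaying"
    else:
        label = "sustained"
    return OscillationDescriptor(f_dom, label, rate)


def entrain(
    params: RateNetworkParams,
    f_drive: float,
    amplitude: float,
    t_on: float,
    t_off: float,
    t_end: float,
    dt: float = 0.05,
    x0: np.ndarray | None = None,
) -> tuple[NetworkTrajectory, OscillationDescriptor, OscillationDescriptor]:
    """Drive the two VN nodes in antiphase with a sinusoid during
    ``[t_on, t_off]`` and describe the driven and free epochs.

    Returns the full trajectory plus oscillation descriptors measured during
    the drive and after its removal.
    """
    if not (0 < t_on < t_off < t_end):
        raise ValueError("require 0 < t_on < t_off < t_end")
    w = 2 * np.pi * f_drive

    def u_fn(t):
        u = np.zeros(4)
        if t_on <= t <= t_off:
            v = amplitude * np.sin(w * (t - t_on))
            u[_VN_NODES[0]] = v
            u[_VN_NODES[1]] = -v
        return u

    traj = simulate(params, u_fn, (0.0, t_end), dt, x0=x0)
    on = (traj.t >= t_on) & (traj.t <= t_off)
    after = traj.t > t_off
    during_traj = NetworkTrajectory(traj.t[on], traj.x[on], traj.u[on], traj.params_digest)
    after_traj = NetworkTrajectory(traj.t[after], traj.x[after], traj.u[after], traj.params_digest)
    return traj, detect_oscillation(during_traj), detect_oscillation(after_traj)


def oscillatory_departure(
    J,
    rng: np.random.Generator,
    x0_norm: float = 1e-12,
    n_samples: int = 64,
    tol_scale: float = 1e-4,
) -> bool:
    """Does a small perturbation of the origin depart in an oscillatory way?

    The *nonlinear* network built from ``J`` (via :func:`params_from_jacobian`)
    is integrated from a random initial state of norm ``x0_norm``; the
    small-amplitude epoch is decomposed into exponential modes by a matrix
    pencil and the answer is whether a growing oscillating mode is present.
    This is the time-domain counterpart of ``classify_spectrum`` run on the
    simulation rather than on the matrix.
    """
    J = np.asarray(J, dtype=float)
    params = params_from_jacobian(J)
    scale = max(1.0, float(np.abs(J).max()))
    dt = 0.3 / scale
    t_end = dt * (n_samples - 1)
    x0 = rng.standard_normal(4)
    x0 *= x0_norm / np.linalg.norm(x0)
    traj = simulate(params, None, (0.0, t_end), dt, x0=x0, rtol=1e-11, atol=1e-22)
    probe = rng.standard_normal(4)
    modes = exponential_modes(traj.x @ probe, dt)
    tol = tol_scale * scale
    return has_growing_oscillation(modes, tol, tol, amp_rtol=1e-7)
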