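"""Bistable positive-feedback model of synaptic long-term potentiation.

A single LTP activity variable L follows the canonical one-variable
positive-feedback switch

    dL/dt = -delta * L + g * L**n / (K**n + L**n) + eta * B

with BDNF level ``B`` as the stimulus and loop strength ``g = g0 * (1 + c)``
scaled by the CGRP factor ``c``.  Depending on ``g`` the stimulus-response
diagram is monostable, bistable with hysteresis (the high-LTP state relaxes
once B returns below the down-switch threshold), or irreversible: the high
state persists even at B = 0, the regime hypothesized to convert transient
mal de debarquement into the persistent syndrome.  The LTP level feeds back
onto the loop network by multiplying its inhibitory (GABAergic) connection
weights, closing the chain from biochemistry to oscillation tendency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import jacobian_ensemble as je
from . import posture_adaptation as pa

__all__ = [
    "PlasticityParams",
    "BifurcationResult",
    "CouplingMap",
    "ChainConfig",
    "ltp_rhs",
    "equilibria",
    "bifurcation_scan",
    "hysteresis_trace",
    "ltp_to_weights",
    "full_chain",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Decay, Hill self-activation and input gain of the LTP switch.

    All quantities are in arbitrary units.  ``n >= 2`` (integer) is required
    for the sigmoidal nonlinearity that produces saddle-node bifurcations.
    """

    delta: float = 1.0
    g0: float = 1.2
    cgrp: float = 0.0
    n: int = 4
    K: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.delta, self.g0, self.cgrp, self.K, self.eta]
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
            raise ValueError("plasticity parameters must be finite numbers")
        if self.delta <= 0 or self.K <= 0 or self.eta <= 0:
            raise ValueError("delta, K and eta must be positive")
        if self.g0 < 0 or self.cgrp < 0:
            raise ValueError("g0 and cgrp must be non-negative")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ValueError("Hill exponent n must be an integer >= 2")

    @property
    def g(self) -> float:
        """Effective loop strength after CGRP scaling."""
        return self.g0 * (1.0 + self.cgrp)


def ltp_rhs(L, params: PlasticityParams, B: float) -> float | np.ndarray:
    """Right-hand side ``dL/dt`` of the switch; requires ``L >= 0``."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("LTP level L must be non-negative")
    hill = L**params.n / (params.K**params.n + L**params.n)
    out = -params.delta * L + params.g * hill + params.eta * B
    return float(out) if out.ndim == 0 else out


def _rhs_derivative(L: float, params: PlasticityParams) -> float:
    n, K = params.n, params.K
    hill_prime = n * K**n * L ** (n - 1) / (K**n + L**n) ** 2
    return -params.delta + params.g * hill_prime


def equilibria(
    params: PlasticityParams,
    B: float,
    grid_points: int = 2000,
    xtol: float = 1e-12,
) -> list[tuple[float, str]]:
    """All non-negative equilibria with their stability.

    Roots are bracketed by a dense sign-change scan on
    ``[0, (g + eta*B)/delta + margin]`` and polished with Brent's method;
    stability follows the sign of the rhs derivative.
    """
    upper = (params.g + params.eta * max(B, 0.0)) / params.delta + 1.0
    grid = np.linspace(0.0, upper, grid_points)
    vals = ltp_rhs(grid, params, B)
    roots: list[float] = []
    if abs(vals[0]) < 1e-14:
        roots.append(0.0)
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0 and k > 0:
            roots.append(float(grid[k]))
        elif a * b < 0:
            roots.append(brentq(lambda L: ltp_rhs(L, params, B), grid[k], grid[k + 1],
                                xtol=xtol))
    # dedupe near-coincident roots
    roots = sorted(roots)
    unique: list[float] = []
    for r in roots:
        if not unique or r - unique[-1] > 1e-9 * max(1.0, upper):
            unique.append(r)
    return [(r, "stable" if _rhs_derivative(r, params) < 0 else "unstable")
            for r in unique]


@dataclass(frozen=True)
class BifurcationResult:
    """Saddle-node thresholds and regime of the switch.

    ``B_on``: input above which only the high branch remains (up-switch);
    ``B_off``: input below which the high branch disappears (down-switch;
    negative means the high state survives at B = 0, i.e. irreversibility).
    """

    regime: str  # monostable | reversible_bistable | irreversible
    B_on: float | None
    B_off: float | None
    equilibria_at_zero: tuple[tuple[float, str], ...]
    branches: "np.ndarray | None" = None  # structured scan table (optional)

    def __post_init__(self) -> None:
        if self.B_on is not None and self.B_off is not None and self.B_on < self.B_off:
            raise ValueError("B_on must be >= B_off in a bistable diagram")


def _fold_points(params: PlasticityParams, resolution: int) -> list[float]:
    """LTP levels where the branch folds: critical points of
    ``h(L) = delta*L - g*sigma(L)``, bracketed on a grid and polished."""
    upper = params.g / params.delta + 1.0
    grid = np.linspace(1e-12, upper, resolution)
    hp = np.array([-_rhs_derivative(L, params) for L in grid])  # h'(L)
    folds = []
    for k in range(len(grid) - 1):
        if hp[k] * hp[k + 1] < 0:
            folds.append(brentq(lambda L: -_rhs_derivative(L, params),
                                grid[k], grid[k + 1], xtol=1e-14))
    return folds


def bifurcation_scan(
    params: PlasticityParams,
    B_range: tuple[float, float] = (-2.0, 3.0),
    resolution: int = 2000,
) -> BifurcationResult:
    """Locate the saddle-node inputs by following the equilibrium branch.

    On the equilibrium manifold ``eta*B = h(L) = delta*L - g*sigma(L)``, the
    saddle-nodes are the critical points of ``h``; the branch is scanned over
    L, folds are bracketed by sign changes of ``h'`` and polished by Brent's
    method.  ``B_range`` bounds the reported diagram (it must cover 0).
    """
    b_lo, b_hi = B_range
    if not (b_lo <= 0.0 <= b_hi):
        raise ValueError("B_range must cover 0")
    folds = _fold_points(params, resolution)
    if len(folds) == 1:  # h' sign change pair unresolved: refine once
        warnings.warn("fold bracketing too coarse; rescanning finer")
        folds = _fold_points(params, resolution * 8)
    eq0 = tuple(equilibria(params, 0.0))
    grid = np.linspace(b_lo, b_hi, 401)
    if len(folds) < 2:
        return BifurcationResult("monostable", None, None, eq0, _branch_table(params, grid))
    h = lambda L: (params.delta * L
                   - params.g * L**params.n / (params.K**params.n + L**params.n))
    b_folds = sorted(h(L) / params.eta for L in folds)
    B_off, B_on = float(b_folds[0]), float(b_folds[-1])
    n_stable_zero = sum(1 for _, s in eq0 if s == "stable")
    regime = "irreversible" if (n_stable_zero >= 2 or B_off < 0) else "reversible_bistable"
    return BifurcationResult(regime, B_on, B_off, eq0, _branch_table(params, grid))


def _branch_table(params: PlasticityParams, grid: np.ndarray) -> np.ndarray:
    """Structured (B, L_low, L_unstable, L_high) table for plotting/CSV;
    NaN where a branch is absent."""
    rows = np.full((len(grid), 4), np.nan)
    rows[:, 0] = grid
    for k, b in enumerate(grid):
        eqs = equilibria(params, b, grid_points=800)
        stable = [L for L, s in eqs if s == "stable"]
        unstable = [L for L, s in eqs if s == "unstable"]
        if unstable:
            rows[k, 2] = unstable[0]
        for L in stable:
            # branches separated by the Hill half-activation scale
            if L < params.K:
                rows[k, 1] = L
            else:
                rows[k, 3] = L
    return rows


def hysteresis_trace(
    params: PlasticityParams,
    b_path: Sequence[float],
    relax_time: float | None = None,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Quasi-static stimulus sweep: at each B, relax L by a short ODE
    integration from its current value.  Returns an array of (B, L) rows.

    The up-sweep jumps to the high branch at the up-switch saddle-node, the
    down-sweep back at the down-switch (or never, if irreversible).
    """
    b_path = np.asarray(list(b_path), dtype=float)
    if len(b_path) < 2:
        raise ValueError("b_path needs at least two points")
    if relax_time is None:
        relax_time = 20.0 / params.delta
    eqs = equilibria(params, b_path[0])
    stable = [L for L, s in eqs if s == "stable"]
    if not stable:
        raise ValueError("no stable equilibrium at the start of the path")
    L = min(stable)  # low branch
    out = np.empty((len(b_path), 2))
    for k, b in enumerate(b_path):
        sol = solve_ivp(lambda t, y: [ltp_rhs(max(y[0], 0.0), params, b)],
                        (0.0, relax_time), [L], rtol=rtol, atol=1e-12)
        L = max(float(sol.y[0, -1]), 0.0)
        out[k] = (b, L)
    return out


@dataclass(frozen=True)
class CouplingMap:
    """Saturating map from LTP level to a connection-weight multiplier.

    ``m(L) = 1 + lam * L / (L + K_m)``: monotone, m(0) = 1, bounded by
    ``1 + lam``.  ``lam_exc`` optionally couples the excitatory weights too.
    """

    lam: float = 6.0
    K_m: float = 1.0
    lam_exc: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.lam_exc < 0 or self.K_m <= 0:
            raise ValueError("coupling parameters must be non-negative (K_m positive)")

    def multiplier(self, L: float) -> float:
        if L < 0:
            raise ValueError("L must be non-negative")
        return 1.0 + self.lam * L / (L + self.K_m)

    def multiplier_exc(self, L: float) -> float:
        if L < 0:
            raise ValueError("L must be non-negative")
        return 1.0 + self.lam_exc * L / (L + self.K_m)


def ltp_to_weights(L: float, cmap: CouplingMap, base: je.WeightScheme) -> je.WeightScheme:
    """Strengthen the inhibitory (and optionally excitatory) weights by the
    LTP-dependent multiplier."""
    return je.WeightScheme(
        w_self=base.w_self,
        w_exc=base.w_exc * cmap.multiplier_exc(L),
        w_inh=base.w_inh * cmap.multiplier(L),
    )


@dataclass(frozen=True)
class ChainConfig:
    """End-to-end experiment: plasticity -> weights -> oscillation -> posture."""

    plasticity: PlasticityParams = PlasticityParams()
    cgrp_low: float = 0.0
    cgrp_high: float = 1.5
    bdnf_pulse: float = 1.0
    # base point on the steep flank of the oscillation-probability curves:
    # with strong excitation, strengthening the inhibitory (GABAergic)
    # connections moves the network from the low- to the high-probability
    # regime, which is the hypothesized MdDS transition
    base_weights: je.WeightScheme = je.WeightScheme(w_self=1.0, w_exc=100.0, w_inh=10.0)
    coupling: CouplingMap = CouplingMap()
    n_samples: int = 10_000
    seed: int = 0
    disturbance_freq: float = 0.25
    disturbance_amplitude: float = 0.05
    t_aboard: float = 120.0
    t_ashore: float = 400.0
    #: interpretive mapping from switch regime to compensator damping
    rho_map: tuple[tuple[str, float], ...] = (
        ("irreversible", 0.0),
        ("reversible_bistable", 0.02),
        ("monostable", 0.2),
    )


def _pulse_and_return(params: PlasticityParams, pulse: float, n_steps: int = 100) -> float:
    """Quasi-static BDNF pulse 0 -> pulse -> 0; returns the final LTP level."""
    up = np.linspace(0.0, pulse, n_steps + 1)
    path = np.concatenate([up, up[::-1][1:]])
    trace = hysteresis_trace(params, path)
    return float(trace[-1, 1])


def full_chain(config: ChainConfig = ChainConfig()) -> dict:
    """Run the full MdDS hypothesis chain at low and high CGRP.

    For each CGRP level: classify the switch regime, apply a BDNF pulse and
    read the residual LTP at B = 0, map LTP to network weights, estimate the
    oscillation probability, then simulate disembarkation with the regime's
    compensator damping.  Returns a JSON-serializable report with every
    intermediate quantity.
    """
    rho_map = dict(config.rho_map)
    structure = je.canonical_structure()
    report: dict = {"config_seed": config.seed, "arms": {}}
    for arm, cgrp in (("low_cgrp", config.cgrp_low), ("high_cgrp", config.cgrp_high)):
        pp = replace(config.plasticity, cgrp=cgrp)
        scan = bifurcation_scan(pp)
        L_final = _pulse_and_return(pp, config.bdnf_pulse)
        weights = ltp_to_weights(L_final, config.coupling, config.base_weights)
        seed = je.point_seed(config.seed, 0 if arm == "low_cgrp" else 1)
        p, se = je.oscillation_probability(structure, weights, config.n_samples, seed)
        rho = rho_map[scan.regime]
        posture_params = pa.PostureParams(
            omega_c=2 * math.pi * config.disturbance_freq, rho=rho)
        dist = pa.DisturbanceSpec(
            kind="pure_sine", amplitude=config.disturbance_amplitude,
            frequency=config.disturbance_freq, t_aboard=config.t_aboard,
            t_ashore=config.t_ashore, seed=seed % 2**31)
        traj = pa.simulate_posture(posture_params, dist)
        f_ring, tau, posture_regime = pa.post_removal_response(traj)
        report["arms"][arm] = {
            "cgrp": cgrp,
            "loop_strength_g": pp.g,
            "switch_regime": scan.regime,
            "B_on": scan.B_on,
            "B_off": scan.B_off,
            "ltp_after_pulse": L_final,
            "weights": {"w_self": weights.w_self, "w_exc": weights.w_exc,
                        "w_inh": weights.w_inh},
            "oscillation_probability": p,
            "oscillation_probability_se": se,
            "rho": rho,
            "posture_regime": posture_regime,
            "ringing_frequency_hz": f_ring,
            "ringing_tau_s": None if math.isinf(tau) else tau,
        }
    lo = report["arms"]["low_cgrp"]
    hi = report["arms"]["high_cgrp"]
    se_comb = math.hypot(lo["oscillation_probability_se"], hi["oscillation_probability_se"])
    report["p_osc_difference"] = hi["oscillation_probability"] - lo["oscillation_probability"]
    report["p_osc_combined_se"] = se_comb
    report["p_osc_significant_3se"] = bool(
        report["p_osc_difference"] > 3.0 * se_comb)
    return report
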