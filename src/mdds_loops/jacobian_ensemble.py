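"""Structured random Jacobians of the vestibulocerebellar loop network.

The network couples the two bilateral vestibular nuclei (VN) and the Purkinje
cells (PJ) of the flocculonodular lobe on each side of the brainstem.  Its
signed connection pattern contains two ipsilateral negative loops (PJ-VN on
each side, one inhibitory edge each), a central commissural double-negative
loop between the two VN, and two extra contralateral inhibitory
vestibulocerebellar edges.  Every nonzero interaction coefficient is drawn as
``sign * u * w_class`` with ``u ~ Uniform[0, 1]`` and ``w_class`` a scaling
weight per connection class (self-inhibitory / excitatory / inhibitory).

A sampled Jacobian is called *oscillatory* when its spectrum contains a
strictly complex eigenvalue with positive real part — the linear signature of
growing (hence, after saturation, persistent) oscillations.  The module
estimates the probability of that event by Monte Carlo over weight sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .modal import exponential_modes, has_growing_oscillation

__all__ = [
    "NODE_LABELS",
    "LoopStructure",
    "WeightScheme",
    "SpectralClassification",
    "SweepResult",
    "canonical_structure",
    "weight_matrix",
    "sample_jacobian",
    "sample_jacobians",
    "classify_spectrum",
    "oscillation_probability",
    "sweep_probability",
    "inhibition_sweep",
    "self_inhibition_sweep",
    "time_domain_oscillatory",
]

#: Node order: Purkinje cells and vestibular nuclei on brainstem sides A and B.
NODE_LABELS = ("PJ_A", "VN_A", "VN_B", "PJ_B")

# Off-diagonal edge positions (row = target, column = source), 0-based.
EXCITATORY_EDGES = ((0, 1), (3, 2))
INHIBITORY_EDGES = ((0, 2), (1, 0), (1, 2), (2, 1), (2, 3), (3, 1))
ABSENT_EDGES = ((0, 3), (1, 3), (2, 0), (3, 0))

#: Relative eigenvalue tolerance separating genuine instability/oscillation
#: from numerical noise on 4x4 spectra.
DEFAULT_TOL = 1e-9

#: Monte Carlo sample size used for the published-scale sweeps.
DEFAULT_N_SAMPLES = 100_000

_CATEGORIES = (
    "stable_nonoscillatory",
    "stable_oscillatory",
    "unstable_oscillatory",
    "unstable_nonoscillatory",
)


@dataclass(frozen=True)
class LoopStructure:
    """Signed 4x4 connection pattern of the loop network.

    ``sign_pattern[i, j]`` is the sign of the influence of node ``j`` on node
    ``i``; ``entry_class`` assigns each entry to one of ``self`` /
    ``excitatory`` / ``inhibitory`` / ``absent``.
    """

    node_labels: tuple[str, ...]
    sign_pattern: np.ndarray
    entry_class: np.ndarray

    def __post_init__(self) -> None:
        sign = np.asarray(self.sign_pattern, dtype=int)
        cls = np.asarray(self.entry_class, dtype=object)
        if sign.shape != (4, 4) or cls.shape != (4, 4):
            raise ValueError("LoopStructure requires 4x4 sign and class arrays")
        object.__setattr__(self, "sign_pattern", sign)
        object.__setattr__(self, "entry_class", cls)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def canonical_structure() -> LoopStructure:
    """The loop structure of the bilateral PJ-VN network.

    Diagonal entries are self-inhibitory; the two PJ<-VN projections are the
    only excitatory edges; six inhibitory edges realize the ipsilateral
    loops, the commissural VN-VN loop, and the two extra contralateral
    connections.
    """
    sign = np.zeros((4, 4), dtype=int)
    cls = np.full((4, 4), "absent", dtype=object)
    for i in range(4):
        sign[i, i] = -1
        cls[i, i] = "self"
    for i, j in EXCITATORY_EDGES:
        sign[i, j] = 1
        cls[i, j] = "excitatory"
    for i, j in INHIBITORY_EDGES:
        sign[i, j] = -1
        cls[i, j] = "inhibitory"
    return LoopStructure(NODE_LABELS, sign, cls)


@dataclass(frozen=True)
class WeightScheme:
    """Scaling coefficients per connection class (arbitrary units).

    ``w_self`` scales the diagonal self-inhibitions (the sweep parameter
    ``d``), ``w_exc`` the excitatory and ``w_inh`` the inhibitory edges.
    """

    w_self: float = 1.0
    w_exc: float = 1.0
    w_inh: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_self", "w_exc", "w_inh"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")


def weight_matrix(structure: LoopStructure, scheme: WeightScheme) -> np.ndarray:
    """Per-entry scaling weights: ``w_class`` at each nonzero position."""
    lut = {"self": scheme.w_self, "excitatory": scheme.w_exc,
           "inhibitory": scheme.w_inh, "absent": 0.0}
    out = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            out[i, j] = lut[structure.entry_class[i, j]]
    return out


def sample_jacobians(
    structure: LoopStructure,
    scheme: WeightScheme,
    n: int,
    rng: np.random.Generator,
    random_diagonal: bool = True,
) -> np.ndarray:
    """Draw ``n`` Jacobians, shape ``(n, 4, 4)``.

    Each nonzero entry is ``sign * u * w_class`` with independent
    ``u ~ Uniform[0, 1]``.  With ``random_diagonal=False`` the diagonal is
    fixed at ``-w_self`` instead of being scaled by a random factor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = structure.sign_pattern * weight_matrix(structure, scheme)
    u = rng.uniform(0.0, 1.0, size=(n, 4, 4))
    if not random_diagonal:
        idx = np.arange(4)
        u[:, idx, idx] = 1.0
    return base * u


def sample_jacobian(
    structure: LoopStructure,
    scheme: WeightScheme,
    rng: np.random.Generator,
    random_diagonal: bool = True,
) -> np.ndarray:
    """Draw a single 4x4 Jacobian (see :func:`sample_jacobians`)."""
    return sample_jacobians(structure, scheme, 1, rng, random_diagonal)[0]


@dataclass(frozen=True)
class SpectralClassification:
    eigenvalues: np.ndarray
    oscillatory: bool
    category: str


def _as_square_matrix(J) -> np.ndarray:
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("matrix contains non-finite entries")
    return J


def _tolerances(J: np.ndarray, tol_re, tol_im) -> tuple[float, float]:
    scale = max(1.0, float(np.abs(J).max()))
    if tol_re is None:
        tol_re = DEFAULT_TOL * scale
    if tol_im is None:
        tol_im = DEFAULT_TOL * scale
    return float(tol_re), float(tol_im)


def classify_spectrum(J, tol_re: float | None = None, tol_im: float | None = None) -> SpectralClassification:
    """Eigenvalue classification of a real square matrix.

    ``oscillatory`` is True iff some eigenvalue has real part > ``tol_re``
    and |imaginary part| > ``tol_im`` (category ``unstable_oscillatory``).
    Unstable matrices whose positive-real-part eigenvalues are all real are
    ``unstable_nonoscillatory`` — they grow without oscillating.
    """
    J = _as_square_matrix(J)
    tol_re, tol_im = _tolerances(J, tol_re, tol_im)
    ev = np.linalg.eigvals(J)
    unstable = ev.real > tol_re
    complex_ = np.abs(ev.imag) > tol_im
    oscillatory = bool(np.any(unstable & complex_))
    if oscillatory:
        category = "unstable_oscillatory"
    elif np.any(unstable):
        category = "unstable_nonoscillatory"
    elif np.any(complex_):
        category = "stable_oscillatory"
    else:
        category = "stable_nonoscillatory"
    return SpectralClassification(ev, oscillatory, category)


def _oscillatory_mask(J_batch: np.ndarray, tol_re: float | None, tol_im: float | None) -> np.ndarray:
    scale = np.maximum(1.0, np.abs(J_batch).reshape(len(J_batch), -1).max(axis=1))
    t_re = DEFAULT_TOL * scale if tol_re is None else np.full(len(J_batch), tol_re)
    t_im = DEFAULT_TOL * scale if tol_im is None else np.full(len(J_batch), tol_im)
    ev = np.linalg.eigvals(J_batch)
    return np.any((ev.real > t_re[:, None]) & (np.abs(ev.imag) > t_im[:, None]), axis=1)


def oscillation_probability(
    structure: LoopStructure,
    scheme: WeightScheme,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.SeedSequence = 0,
    random_diagonal: bool = True,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte Carlo estimate of P(unstable oscillatory spectrum).

    Returns ``(p, se)`` with the binomial standard error
    ``se = sqrt(p (1 - p) / n)``.  Reproducible from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        J = sample_jacobians(structure, scheme, m, rng, random_diagonal)
        hits += int(_oscillatory_mask(J, None, None).sum())
        remaining -= m
    p = hits / n_samples
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return p, se


@dataclass(frozen=True)
class SweepResult:
    """Gridded oscillation-probability estimates.

    One row per ``(w_inh, w_exc, w_self)`` triple with columns
    ``w_inh, w_exc, w_self, n_samples, p_osc, se, seed``.
    """

    table: pd.DataFrame

    COLUMNS = ("w_inh", "w_exc", "w_self", "n_samples", "p_osc", "se", "seed")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"SweepResult table missing columns: {sorted(missing)}")
        object.__setattr__(self, "table", self.table[list(self.COLUMNS)].reset_index(drop=True))

    def lookup(self, w_inh: float, w_exc: float, w_self: float) -> pd.Series:
        t = self.table
        row = t[(t.w_inh == w_inh) & (t.w_exc == w_exc) & (t.w_self == w_self)]
        if len(row) != 1:
            raise KeyError(f"no unique row for ({w_inh}, {w_exc}, {w_self})")
        return row.iloc[0]


def point_seed(master_seed: int, index: int) -> int:
    """Stable per-grid-point seed derived from the master seed.

    Each sweep point gets its own generator stream so estimates are
    independent and individually reproducible from the stored seed.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, np.uint32)[0])


def sweep_probability(
    structure: LoopStructure,
    w_inh_grid: Sequence[float],
    w_exc_values: Sequence[float],
    w_self_values: Sequence[float],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    random_diagonal: bool = True,
) -> SweepResult:
    """Oscillation probability over the cartesian grid of weights."""
    w_inh_grid = list(w_inh_grid)
    w_exc_values = list(w_exc_values)
    w_self_values = list(w_self_values)
    if not (w_inh_grid and w_exc_values and w_self_values):
        raise ValueError("sweep grids must be nonempty")
    rows = []
    index = 0
    for w_self in w_self_values:
        for w_exc in w_exc_values:
            for w_inh in w_inh_grid:
                ps = point_seed(seed, index)
                scheme = WeightScheme(w_self=w_self, w_exc=w_exc, w_inh=w_inh)
                p, se = oscillation_probability(
                    structure, scheme, n_samples, ps, random_diagonal
                )
                rows.append((w_inh, w_exc, w_self, n_samples, p, se, ps))
                index += 1
    return SweepResult(pd.DataFrame(rows, columns=list(SweepResult.COLUMNS)))


def inhibition_sweep(
    n_samples: int = DEFAULT_N_SAMPLES,
    step: int = 1,
    seed: int = 0,
    structure: LoopStructure | None = None,
) -> SweepResult:
    """Standard inhibition sweep: w_self = 1, w_inh over 1..100, w_exc in
    {1, 10, 100}.  ``step`` coarsens the inhibition grid (endpoints kept)."""
    structure = structure or canonical_structure()
    grid = _stepped_grid(1, 100, step)
    return sweep_probability(structure, grid, [1.0, 10.0, 100.0], [1.0], n_samples, seed)


def self_inhibition_sweep(
    n_samples: int = DEFAULT_N_SAMPLES,
    step: int = 1,
    seed: int = 0,
    structure: LoopStructure | None = None,
) -> SweepResult:
    """Self-inhibition sweep: w_inh over 1..30, w_exc in {1, 10, 100},
    w_self in {0.1, 1.0, 10} — three curve families per self-weight."""
    structure = structure or canonical_structure()
    grid = _stepped_grid(1, 30, step)
    return sweep_probability(
        structure, grid, [1.0, 10.0, 100.0], [0.1, 1.0, 10.0], n_samples, seed
    )


def _stepped_grid(lo: int, hi: int, step: int) -> list[float]:
    if step < 1:
        raise ValueError("step must be >= 1")
    grid = [float(lo)]
    grid += [float(v) for v in range(step, hi + 1, step) if v > lo]
    if grid[-1] != float(hi):
        grid.append(float(hi))
    return grid


def time_domain_oscillatory(
    J,
    rng: np.random.Generator,
    n_samples: int = 64,
    tol_scale: float = 1e-6,
) -> bool:
    """Time-domain oracle: integrate ``dx/dt = J x`` from a random initial
    state and declare oscillatory iff an oscillating component grows.

    The trajectory is propagated exactly (matrix-exponential stepping) over a
    window scaled to the matrix magnitude and decomposed into exponential
    modes by a matrix pencil; the oracle never inspects ``J``'s spectrum.
    Decisions are reliable outside a dead band of half-width
    ``tol_scale * max(1, |J|_max)`` around the imaginary/real axes.
    """
    from scipy.linalg import expm

    J = _as_square_matrix(J)
    scale = max(1.0, float(np.abs(J).max()))
    dt = 0.3 / scale
    prop = expm(J * dt)
    x = rng.standard_normal(J.shape[0])
    x /= np.linalg.norm(x)
    probe = rng.standard_normal(J.shape[0])
    xs = np.empty((n_samples, J.shape[0]))
    xs[0] = x
    for k in range(1, n_samples):
        xs[k] = prop @ xs[k - 1]
    modes = exponential_modes(xs @ probe, dt)
    tol = tol_scale * scale
    return has_growing_oscillation(modes, tol, tol)
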