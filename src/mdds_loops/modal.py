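"""Exponential-mode estimation from sampled trajectories.

Matrix-pencil (ESPRIT-type) decomposition of a uniformly sampled signal into
complex exponentials ``y(t) ~ sum_k a_k exp(lambda_k t)``.  Used as the
time-domain oracle for spectral classification: a linear (or small-amplitude
nonlinear) trajectory is integrated and its modal content recovered directly
from the samples, so the question "does an oscillating component grow?" is
answered without ever forming the system's Jacobian spectrum.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import lstsq, svd


class ModeEstimate(NamedTuple):
    """Recovered continuous-time exponents and their absolute amplitudes."""

    exponents: np.ndarray  # complex, shape (m,)
    amplitudes: np.ndarray  # non-negative real, shape (m,)


def exponential_modes(
    y: np.ndarray,
    dt: float,
    max_order: int = 4,
    sv_rtol: float = 1e-9,
) -> ModeEstimate:
    """Fit ``y[k] ~ sum_j a_j z_j**k`` and return ``lambda_j = log(z_j)/dt``.

    Parameters
    ----------
    y : real or complex samples on a uniform grid with spacing ``dt``.
    max_order : cap on the number of recovered modes (4 for a 4-state
        linear system: at most four distinct eigenvalues).
    sv_rtol : relative singular-value threshold separating signal space
        from numerical noise in the Hankel pencil.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("need a 1-D signal with at least 8 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = y.size
    pencil = n // 2
    hankel = np.lib.stride_tricks.sliding_window_view(y, pencil + 1)
    _, s, vh = svd(hankel, full_matrices=False)
    if s[0] == 0.0:  # identically zero signal: no modes
        return ModeEstimate(np.empty(0, complex), np.empty(0))
    order = min(max_order, int(np.sum(s > sv_rtol * s[0])))
    v = vh[:order].conj().T
    shift = np.linalg.pinv(v[:-1]) @ v[1:]
    z = np.linalg.eigvals(shift)
    z = z[np.abs(z) > 0]
    lam = (np.log(np.abs(z)) + 1j * np.angle(z)) / dt
    vand = z[None, :] ** np.arange(n)[:, None]
    amp, *_ = lstsq(vand, y.astype(complex), lapack_driver="gelsd")
    return ModeEstimate(lam, np.abs(amp))


def has_growing_oscillation(
    modes: ModeEstimate,
    tol_re: float,
    tol_im: float,
    amp_rtol: float = 1e-8,
) -> bool:
    """True iff a recovered mode grows (Re > tol_re) while oscillating
    (|Im| > tol_im) and carries non-negligible amplitude."""
    if modes.exponents.size == 0:
        return False
    amax = modes.amplitudes.max()
    if amax == 0.0:
        return False
    keep = modes.amplitudes > amp_rtol * amax
    lam = modes.exponents[keep]
    return bool(np.any((lam.real > tol_re) & (np.abs(lam.imag) > tol_im)))
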