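"""Bistability, hysteresis and irreversibility of the LTP switch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdds_loops import jacobian_ensemble as je
from mdds_loops import plasticity_switch as ps

LOW = ps.PlasticityParams()                # g = 1.2: reversible bistable
HIGH = ps.PlasticityParams(cgrp=1.5)       # g = 3.0: irreversible


def scan_equilibria(params, B, n=10_000, iters=60):
    """Independent brute-force oracle: dense sign-change scan + bisection."""
    upper = (params.g + params.eta * max(B, 0.0)) / params.delta + 1.0
    grid = np.linspace(0.0, upper, n)
    f = lambda L: (-params.delta * L
                   + params.g * L**params.n / (params.K**params.n + L**params.n)
                   + params.eta * B)
    vals = f(grid)
    roots = []
    if abs(vals[0]) < 1e-13:
        roots.append(0.0)
    for k in range(n - 1):
        if vals[k] * vals[k + 1] < 0:
            a, b = grid[k], grid[k + 1]
            for _ in range(iters):
                m = 0.5 * (a + b)
                if f(a) * f(m) <= 0:
                    b = m
                else:
                    a = m
            roots.append(0.5 * (a + b))
    return roots


def saddle_nodes_analytic(params):
    """Fold points from the tangency condition g*sigma'(L) = delta, solved as
    a polynomial eigenproblem (independent of the package's continuation)."""
    n, K, g, d = params.n, params.K, params.g, params.delta
    # d*(K^n + L^n)^2 = g*n*K^n*L^(n-1)
    coeffs = np.zeros(2 * n + 1)
    coeffs[0] = d                     # L^(2n)
    coeffs[n] = 2 * d * K**n          # L^n
    coeffs[2 * n] = d * K**(2 * n)    # constant
    coeffs[n + 1] += -g * n * K**n    # L^(n-1)
    roots = np.roots(coeffs)
    L = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0)
    sigma = lambda x: x**n / (K**n + x**n)
    return [(Lf, (d * Lf - g * sigma(Lf)) / params.eta) for Lf in L]


class TestRhs:
    def test_origin_is_equilibrium_without_input(self):
        assert ps.ltp_rhs(0.0, LOW, 0.0) == 0.0

    def test_linear_limit_without_feedback(self):
        p = ps.PlasticityParams(g0=0.0)
        assert ps.ltp_rhs(1.0, p, 1.0) == pytest.approx(0.0)

    def test_saturation_bound(self):
        p = LOW
        L_big = (p.g + p.eta * 2.0) / p.delta + 0.5
        assert ps.ltp_rhs(L_big, p, 2.0) < 0

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            ps.ltp_rhs(-0.1, LOW, 0.0)

    @pytest.mark.parametrize("kwargs", [
        {"n": 1}, {"delta": 0.0}, {"K": -1.0}, {"cgrp": -0.5},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            ps.PlasticityParams(**kwargs)


class TestEquilibria:
    def test_no_feedback_closed_form(self):
        p = ps.PlasticityParams(g0=0.0)
        eqs = ps.equilibria(p, 1.0)
        assert len(eqs) == 1
        L, stab = eqs[0]
        assert L == pytest.approx(1.0, abs=1e-10) and stab == "stable"

    @pytest.mark.parametrize("params,B", [
        (HIGH, 0.0), (LOW, 0.42), (HIGH, 0.1), (LOW, 0.0), (LOW, 1.0),
    ])
    def test_matches_dense_scan_oracle(self, params, B):
        got = ps.equilibria(params, B)
        want = scan_equilibria(params, B)
        assert len(got) == len(want)
        for (L, _), Lw in zip(got, want):
            assert L == pytest.approx(Lw, abs=1e-8)

    def test_bistable_pattern_stable_unstable_stable(self):
        eqs = ps.equilibria(HIGH, 0.0)
        assert [s for _, s in eqs] == ["stable", "unstable", "stable"]

    def test_far_above_threshold_single_high_state(self):
        eqs = ps.equilibria(LOW, 2.0)
        assert len(eqs) == 1 and eqs[0][1] == "stable" and eqs[0][0] > LOW.K


class TestBifurcationScan:
    def test_no_feedback_monostable(self):
        res = ps.bifurcation_scan(ps.PlasticityParams(g0=0.0))
        assert res.regime == "monostable" and res.B_on is None

    def test_default_reversible_window(self):
        res = ps.bifurcation_scan(LOW)
        assert res.regime == "reversible_bistable"
        assert 0.0 < res.B_off < res.B_on

    def test_high_cgrp_irreversible(self):
        res = ps.bifurcation_scan(HIGH)
        assert res.regime == "irreversible"
        stable = [L for L, s in res.equilibria_at_zero if s == "stable"]
        assert len(stable) == 2 and max(stable) > HIGH.K

    @pytest.mark.parametrize("params", [LOW, HIGH])
    def test_saddle_nodes_match_analytic_oracle(self, params):
        res = ps.bifurcation_scan(params)
        folds = saddle_nodes_analytic(params)
        assert len(folds) == 2
        b_vals = sorted(b for _, b in folds)
        assert res.B_off == pytest.approx(b_vals[0], abs=1e-6)
        assert res.B_on == pytest.approx(b_vals[1], abs=1e-6)

    def test_regime_thresholds_ordered_along_g(self):
        """Monostable, reversible-bistable and irreversible regimes appear in
        order as the loop strength grows (g_bi < g_irr)."""
        regimes = [ps.bifurcation_scan(ps.PlasticityParams(g0=g)).regime
                   for g in (0.5, 0.9, 1.2, 1.6, 1.85, 3.0)]
        order = {"monostable": 0, "reversible_bistable": 1, "irreversible": 2}
        ranks = [order[r] for r in regimes]
        assert ranks == sorted(ranks)
        assert set(regimes) == set(order)

    def test_analytic_regime_boundaries(self):
        # for delta = K = eta = 1, n = 4: g_irr = (256/27)**0.25; g_bi = 1/max sigma'
        g_irr = (256.0 / 27.0) ** 0.25
        Ls = np.linspace(1e-4, 3.0, 200_001)
        g_bi = 1.0 / np.max(4 * Ls**3 / (1 + Ls**4) ** 2)
        assert ps.bifurcation_scan(ps.PlasticityParams(g0=g_bi * 0.99)).regime == "monostable"
        assert ps.bifurcation_scan(ps.PlasticityParams(g0=g_bi * 1.01)).regime == "reversible_bistable"
        assert ps.bifurcation_scan(ps.PlasticityParams(g0=g_irr * 0.99)).regime == "reversible_bistable"
        assert ps.bifurcation_scan(ps.PlasticityParams(g0=g_irr * 1.01)).regime == "irreversible"


class TestHysteresis:
    def _updown(self, b_max, steps):
        up = np.linspace(0.0, b_max, steps + 1)
        return np.concatenate([up, up[::-1][1:]])

    def test_monostable_traces_coincide(self):
        p = ps.PlasticityParams(g0=0.5)
        path = self._updown(1.0, 100)
        trace = ps.hysteresis_trace(p, path)
        half = len(path) // 2
        up = trace[:half + 1]
        down = trace[half:][::-1]
        # quasi-static relaxation lags the moving equilibrium by ~1e-4
        np.testing.assert_allclose(up[:, 1], down[:, 1], atol=1e-3)

    def test_reversible_jumps_at_scan_thresholds(self):
        res = ps.bifurcation_scan(LOW)
        path = self._updown(1.0, 200)
        step = 1.0 / 200
        trace = ps.hysteresis_trace(LOW, path)
        half = len(path) // 2
        up, down = trace[:half + 1], trace[half:]
        jump_up = up[np.argmax(np.diff(up[:, 1])), 0]
        jump_down = down[np.argmax(-np.diff(down[:, 1])), 0]
        assert abs(jump_up - res.B_on) <= 1.5 * step
        assert abs(jump_down - res.B_off) <= 1.5 * step
        # distinct branches inside the window
        sel = (up[:, 0] > res.B_off + step) & (up[:, 0] < res.B_on - step)
        matching_down = down[::-1][:len(up)]
        assert np.any(np.abs(up[sel, 1] - np.interp(up[sel, 0], down[::-1][:, 0],
                                                    down[::-1][:, 1])) > 0.5)

    def test_irreversible_high_state_survives_at_zero(self):
        trace = ps.hysteresis_trace(HIGH, self._updown(1.0, 100))
        L_end = trace[-1, 1]
        L_high = max(L for L, s in ps.equilibria(HIGH, 0.0) if s == "stable")
        assert abs(L_end - L_high) / L_high < 0.05


class TestCoupling:
    def test_identity_at_zero_ltp(self):
        base = je.WeightScheme(1.0, 10.0, 10.0)
        assert ps.ltp_to_weights(0.0, ps.CouplingMap(), base) == base

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(l1=st.floats(0.0, 50.0), l2=st.floats(0.0, 50.0))
    def test_multiplier_monotone_and_bounded(self, l1, l2):
        cmap = ps.CouplingMap(lam=6.0)
        lo, hi = sorted((l1, l2))
        assert cmap.multiplier(lo) <= cmap.multiplier(hi) <= 1.0 + cmap.lam

    def test_high_state_lands_in_strong_inhibition_regime(self):
        L_high = max(L for L, s in ps.equilibria(HIGH, 0.0) if s == "stable")
        w = ps.ltp_to_weights(L_high, ps.CouplingMap(), je.WeightScheme(1.0, 100.0, 10.0))
        assert w.w_inh >= 40.0


class TestFullChain:
    def test_low_vs_high_cgrp_outcomes(self):
        cfg = ps.ChainConfig(n_samples=2500, t_aboard=100.0, t_ashore=400.0)
        report = ps.full_chain(cfg)
        lo, hi = report["arms"]["low_cgrp"], report["arms"]["high_cgrp"]
        assert lo["switch_regime"] == "reversible_bistable"
        assert hi["switch_regime"] == "irreversible"
        assert lo["rho"] > 0.0 and hi["rho"] == 0.0
        assert lo["posture_regime"] == "recovering_MdD"
        assert hi["posture_regime"] == "persistent_MdDS"
        assert hi["weights"]["w_inh"] > lo["weights"]["w_inh"]
        assert report["p_osc_significant_3se"]

    def test_report_reproducible(self):
        cfg = ps.ChainConfig(n_samples=1000, t_aboard=100.0, t_ashore=400.0, seed=5)
        assert ps.full_chain(cfg) == ps.full_chain(cfg)


def test_end_to_end_monotonicity_in_ltp():
    """Oscillation probability is nondecreasing in the LTP level over the
    coupled range (3-SE Monte Carlo criterion for the strict increases)."""
    structure = je.canonical_structure()
    base = je.WeightScheme(1.0, 100.0, 10.0)
    cmap = ps.CouplingMap()
    levels = [0.0, 0.5, 1.5, 3.0]
    stats = []
    for k, L in enumerate(levels):
        w = ps.ltp_to_weights(L, cmap, base)
        stats.append(je.oscillation_probability(structure, w, 10_000, seed=300 + k))
    for (p1, se1), (p2, se2) in zip(stats, stats[1:]):
        assert p2 > p1 - 3 * math.hypot(se1, se2)
    p_first, se_first = stats[0]
    p_last, se_last = stats[-1]
    assert p_last - p_first > 3 * math.hypot(se_first, se_last)
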