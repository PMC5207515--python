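"""Pointwise kinetics: switches, thresholds, rates, reaction terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbmsim.fields import StateFields
from gbmsim.kinetics import (B_REGULARIZER, hypoxia_measure, hypoxic_threshold,
                             mitotic_rate, necrosis_rate, necrotic_threshold,
                             reaction_rhs_flat, reaction_terms, switch_above,
                             switch_below)
from gbmsim.params import ModelParams


class TestSwitches:
    @pytest.mark.parametrize("C,thresh,k,expected", [
        (1.1, 1.1, 100.0, 0.5),                      # midpoint
        (0.1, 1.1, 100.0, 1.0),                      # far below: saturated on
        (2.1, 1.1, 100.0, 0.0),                      # far above: saturated off
        (1.105, 1.1, 100.0, 0.5 * (1 + math.tanh(-0.5))),  # closed form
    ])
    def test_switch_below_values(self, C, thresh, k, expected):
        assert switch_below(C, thresh, k) == pytest.approx(expected, abs=1e-12)

    @given(C=st.floats(0, 3), thresh=st.floats(0.5, 2),
           k=st.floats(1, 1000))
    @settings(max_examples=200, derandomize=True)
    def test_complementarity(self, C, thresh, k):
        assert switch_below(C, thresh, k) + switch_above(C, thresh, k) \
            == pytest.approx(1.0, abs=1e-15)

    def test_switch_below_strictly_decreasing(self):
        C = np.linspace(1.0, 1.2, 201)
        out = switch_below(C, 1.1, 100.0)
        assert np.all(np.diff(out) < 0)
        assert np.all((out >= 0) & (out <= 1))

    def test_nonpositive_steepness_rejected(self):
        with pytest.raises(ValueError):
            switch_below(1.0, 1.1, 0.0)


class TestNecroticThreshold:
    def test_initial_threshold_on_healthy_brain(self, params):
        # no tumor: the death threshold sits at its initial value 1.1
        assert necrotic_threshold(0.0, params) == pytest.approx(1.1)

    def test_anti_angiogenic_collapse(self, params):
        p0 = params.with_sigma(0.0)
        G = np.array([0.0, 0.5, 3.0])
        assert np.allclose(necrotic_threshold(G, p0), p0.omega)

    def test_log_lift(self, params):
        # sigma*log(1+G) with natural log: G = e-1 lifts by exactly sigma
        assert necrotic_threshold(math.e - 1.0, params) == pytest.approx(
            params.sigma + params.omega)

    def test_gog_adds_fixed_gap(self, gog_params):
        chyp = hypoxic_threshold(0.7, gog_params)
        assert necrotic_threshold(0.7, gog_params) == pytest.approx(
            chyp + gog_params.phi)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            necrotic_threshold(np.array([0.1, -0.01]), params)


class TestRates:
    def test_mitotic_rate_midpoint_and_limits(self, params):
        assert mitotic_rate(1.1, 1.1, params) == pytest.approx(params.tau / 2)
        assert mitotic_rate(1.0, 1.1, params) == pytest.approx(params.tau, abs=1e-8)
        assert mitotic_rate(1.2, 1.1, params) == pytest.approx(0.0, abs=1e-8)

    def test_mitotic_rate_monotone_in_C(self, params):
        C = np.linspace(0.9, 1.3, 101)
        assert np.all(np.diff(mitotic_rate(C, 1.1, params)) <= 0)

    def test_necrosis_rate_off_below_threshold(self, params):
        assert necrosis_rate(0.5, 1.0, 1.0, 1.5, params) == pytest.approx(0.0, abs=1e-12)

    def test_necrosis_rate_at_threshold_closed_form(self, params):
        # G=0, B=1, C at threshold: gamma * (1/1.01) * 1/2
        expected = params.gamma * (1.0 / (1.0 + B_REGULARIZER)) * 0.5
        assert necrosis_rate(0.0, 1.0, 1.1, 1.1, params) == pytest.approx(expected)

    def test_necrosis_rate_saturated_limit(self, params):
        # far above threshold with G=1, B=0.99: gamma * 2/1.0 * 1 = 2 gamma
        out = necrosis_rate(1.0, 0.99, 3.0, 1.1, params)
        assert out == pytest.approx(2.0 * params.gamma, rel=1e-9)

    def test_necrosis_rate_monotone(self, params):
        C = np.linspace(1.0, 1.3, 61)
        out = necrosis_rate(0.1, 1.0, C, 1.1, params)
        assert np.all(np.diff(out) >= 0)
        B = np.linspace(1.0, 0.0, 61)
        out_b = necrosis_rate(0.1, B, 1.2, 1.1, params)
        assert np.all(np.diff(out_b) >= 0)  # rate grows as brain dies

    def test_necrosis_rate_cap_is_numerical_safety_only(self, params):
        # cap binds only in the B->0, heavy-tumor, far-above-threshold corner
        assert necrosis_rate(10.0, 0.0, 3.0, 1.1, params) == params.necrosis_rate_max
        assert necrosis_rate(1.0, 0.0, 3.0, 1.1, params) < params.necrosis_rate_max

    def test_hypoxia_measure_complementary_to_gog_mitosis(self, gog_params):
        C = np.linspace(0.8, 1.6, 41)
        chyp = 1.2
        H = hypoxia_measure(C, chyp, gog_params)
        M = mitotic_rate(C, chyp, gog_params)
        assert np.allclose(H + M / gog_params.tau, 1.0, atol=1e-15)


class TestReactionTerms:
    def _state(self, G, B, N):
        mk = lambda x: np.asarray(x, dtype=float).reshape(1, -1)
        return StateFields(B=mk(B), N=mk(N), G=mk(G))

    def test_healthy_brain_is_fixed_point(self, params):
        # the smooth switch leaves an exponentially small necrosis residual
        # (~tanh saturation, 1e-10/hr) well below any dynamical scale
        d = reaction_terms(self._state([0.0], [1.0], [0.0]), params)
        for v in d.values():
            assert np.allclose(v, 0.0, atol=1e-8)

    @pytest.mark.parametrize("G,B,N", [
        ([0.05, 0.3, 1.0], [1.0, 0.8, 0.2], [0.0, 0.1, 1.5]),
        ([0.0, 0.12], [1.0, 1.0], [0.0, 0.0]),
    ])
    def test_mass_identity_single_cell(self, params, G, B, N):
        # necrosis conserves mass: derivatives sum to the mitotic source M*G
        state = self._state(G, B, N)
        d = reaction_terms(state, params)
        total = d["G"] + d["B"] + d["N"]
        from gbmsim.kinetics import local_rates
        MG = local_rates(state, params)["M"] * state.G
        assert np.allclose(total, MG, rtol=0, atol=1e-15)

    def test_mass_identity_gog(self, gog_params):
        mk = lambda x: np.asarray(x, dtype=float).reshape(1, -1)
        state = StateFields(B=mk([0.9, 0.5]), N=mk([0.2, 0.8]),
                            P=mk([0.2, 0.4]), I=mk([0.1, 0.3]))
        d = reaction_terms(state, gog_params)
        total = d["P"] + d["I"] + d["B"] + d["N"]
        from gbmsim.kinetics import local_rates
        MP = local_rates(state, gog_params)["M"] * state.P
        assert np.allclose(total, MP, rtol=0, atol=1e-15)

    def test_gog_full_hypoxia_conversion_structure(self):
        # with a state deep in hypoxia (H ~ 1) the conversion term moves
        # alpha*P from P to I and the normoxic return flux vanishes
        p = ModelParams.gog()
        mk = lambda x: np.asarray(x, dtype=float).reshape(1, 1)
        state = StateFields(B=mk(0.1), N=mk(1.5), P=mk(0.3), I=mk(0.2))
        from gbmsim.kinetics import local_rates
        r = local_rates(state, p)
        assert r["a"] == pytest.approx(p.alpha, rel=1e-6)   # H ~ 1
        assert r["b"] == pytest.approx(0.0, abs=1e-6)

    def test_negative_fields_rejected(self, params):
        with pytest.raises(ValueError):
            reaction_terms(self._state([-0.1], [1.0], [0.0]), params)


class TestPerPixelODE:
    """The full solver at delta=eta=0 must track an adaptive ODE oracle."""

    @pytest.mark.parametrize("kind", ["single_cell", "gog"])
    def test_matches_adaptive_integration(self, kind):
        from scipy.integrate import solve_ivp

        from gbmsim.solver import reaction_update

        if kind == "single_cell":
            p = ModelParams.single_cell(delta=0.0, eta=0.0)
            y0 = [0.05, 1.0, 0.0]
        else:
            p = ModelParams.gog(delta=0.0, eta=0.0)
            y0 = [0.05, 0.01, 1.0, 0.0]
        sol = solve_ivp(reaction_rhs_flat, (0.0, 100.0), y0, args=(p,),
                        rtol=1e-10, atol=1e-13, method="LSODA")
        ref = sol.y[:, -1]

        mk = lambda v: np.array([[v]], dtype=float)
        if kind == "single_cell":
            state = StateFields(G=mk(y0[0]), B=mk(y0[1]), N=mk(y0[2]))
        else:
            state = StateFields(P=mk(y0[0]), I=mk(y0[1]), B=mk(y0[2]), N=mk(y0[3]))
        reaction_update(state, p, 100.0, substeps=50_000)
        got = np.array([float(getattr(state, n)[0, 0]) for n in
                        (("G", "B", "N") if kind == "single_cell"
                         else ("P", "I", "B", "N"))])
        scale = np.abs(ref).max()
        assert np.abs(got - ref).max() / scale < 1e-4

    def test_no_angiogenesis_cap(self):
        # sigma = 0: a pixel started below the initial threshold never
        # exceeds it by more than the finite tanh switch width allows
        from scipy.integrate import solve_ivp

        p = ModelParams.single_cell(delta=0.0, eta=0.0, sigma=0.0)
        sol = solve_ivp(reaction_rhs_flat, (0.0, 2000.0), [0.05, 1.0, 0.0],
                        args=(p,), rtol=1e-9, atol=1e-12, max_step=1.0)
        C = sol.y.sum(axis=0)
        assert C.max() < p.omega + 0.02   # ~2 switch widths of overshoot
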