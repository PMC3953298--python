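"""Model core: input function, MEK step, fluxes, RHS, resting state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gnrherk as gk
from gnrherk.model import _rhs_core, erk_conservation_total, mek_is_inhibited
from gnrherk.protocols import InterventionEvent, PulseProtocol


def make_protocol(p=0.1, period=60.0, width=5.0, horizon=480.0, events=()):
    return PulseProtocol(p=p, period=period, width=width, horizon=horizon, events=events)


class TestGnrhInput:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.5, 0.1),  # inside the first pulse
            (5.0, 0.0),  # half-open window: off exactly at the pulse end
            (4.999, 0.1),
            (61.0, 0.1),  # second pulse, one period later
            (59.0, 0.0),
        ],
    )
    def test_square_wave(self, t, expected):
        assert gk.gnrh_input(t, make_protocol(width=5.0)) == expected

    def test_washout_forces_zero(self):
        prot = make_protocol(events=(InterventionEvent(30.0, "washout"),))
        assert gk.gnrh_input(61.0, prot) == 0.0
        assert gk.gnrh_input(0.5, prot) == 0.1  # before the washout

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gk.gnrh_input(-1.0, make_protocol())

    @given(st.floats(0, 479), st.integers(0, 7))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t, k):
        prot = make_protocol()
        t2 = t + k * prot.period
        if t2 <= prot.horizon:
            assert gk.gnrh_input(t, prot) == gk.gnrh_input(t2, prot)

    def test_constant_when_width_equals_period(self):
        prot = make_protocol(period=10.0, width=10.0, horizon=60.0)
        for t in np.linspace(0, 60, 121):
            assert gk.gnrh_input(float(t), prot) == 0.1


class TestMekActive:
    def test_zero_effector(self, params):
        assert gk.mek_active(0.0, params) == 0.0

    def test_half_saturation(self, params):
        # E = K_MM_MEK gives MEK_tot/2 when basal activation is zero
        assert gk.mek_active(0.05, params) == pytest.approx(0.3, abs=1e-12)

    def test_saturates_at_mek_tot(self, params):
        assert gk.mek_active(1e6, params) == pytest.approx(0.6, rel=1e-3)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, params, e1, e2):
        lo, hi = sorted((e1, e2))
        v_lo, v_hi = gk.mek_active(lo, params), gk.mek_active(hi, params)
        assert 0.0 <= v_lo <= v_hi <= params.MEK_tot

    def test_basal_form(self, params):
        # with nonzero basal rate, E=0 no longer gives zero ppMEK
        p = params.replace(k_MEK_basal=0.1)
        expected = 0.6 * 0.1 / (0.1 + 10.0 * 0.05)
        assert gk.mek_active(0.0, p) == pytest.approx(expected)


class TestPhosphoFluxes:
    def test_all_zero_when_no_erk_species(self, params):
        state = np.zeros(10)
        assert gk.phospho_fluxes(state, 0.3, params) == (0, 0, 0, 0, 0)

    def test_v5_half_saturation(self, params):
        # ppE_n = kd_ppEn -> v5 = kcat5 * MKP_n / 2 = 0.1 uM/min
        state = np.zeros(10)
        state[7] = params.kd_ppEn
        v5 = gk.phospho_fluxes(state, 0.0, params)[4]
        assert v5 == pytest.approx(0.1, abs=1e-12)

    def test_mek_inhibition_zeroes_only_v1_v2(self, params, rest):
        state = rest.copy()
        state[4] = state[5] = state[7] = 0.1
        free = gk.phospho_fluxes(state, 0.3, params, mek_inhibited=False)
        inhib = gk.phospho_fluxes(state, 0.3, params, mek_inhibited=True)
        assert inhib[0] == inhib[1] == 0.0
        assert free[0] > 0 and free[1] > 0
        assert inhib[2:] == free[2:]

    @pytest.mark.parametrize("flux_idx, substrate_idx", [(0, 3), (1, 4), (2, 5), (3, 4), (4, 7)])
    def test_monotone_in_substrate(self, params, flux_idx, substrate_idx):
        rng = np.random.default_rng(42)
        for _ in range(20):
            state = np.abs(rng.normal(0.2, 0.2, size=10))
            values = []
            for substrate in np.linspace(0.0, 1.0, 8):
                s = state.copy()
                s[substrate_idx] = substrate
                values.append(gk.phospho_fluxes(s, 0.3, params)[flux_idx])
            assert np.all(np.diff(values) >= -1e-15)
            assert all(v >= 0 for v in values)


class TestRhs:
    def test_zero_at_rest_without_input(self, params, rest):
        deriv = gk.rhs(0.0, rest, params, make_protocol(p=0.0, width=5.0))
        assert np.abs(deriv).max() < 1e-9

    def test_receptor_equilibrium_closed_form(self, params, rest):
        # dHR/dt = 0 at HR* = R0*k1*G/(k1*G + k_minus1)
        for G, expected in [(0.1, 0.1 * 500 / 505), (1e-3, 0.05)]:
            assert gk.receptor_equilibrium(params, G) == pytest.approx(expected, abs=1e-12)
            state = rest.copy()
            state[0] = expected
            deriv = _rhs_core(state, G, False, params)
            assert abs(deriv[0]) < 1e-12

    def test_nonfinite_state_rejected(self, params):
        state = np.zeros(10)
        state[3] = np.nan
        with pytest.raises(ValueError):
            gk.rhs(0.0, state, params, make_protocol())

    def test_conservation_derivative_vanishes(self, params):
        # shuttling and flux terms cancel in d/dt of the conserved ERK amount
        rng = np.random.default_rng(7)
        C = params.C_cn
        for _ in range(1000):
            state = np.abs(rng.normal(0.3, 0.3, size=10))
            d = _rhs_core(state, rng.uniform(0, 0.1), rng.random() < 0.5, params)
            cons_rate = d[3] + d[4] + d[5] + (d[6] + d[7]) / C
            scale = max(np.abs(d[3:8]).max(), 1.0)
            assert abs(cons_rate) < 1e-12 * scale

    def test_feedback_target_switch(self, params, rest):
        state = rest.copy()
        state[2] = 0.2  # active effector
        state[5], state[7] = 0.3, 0.1  # distinct cytosolic/nuclear ppERK
        d_cyt = _rhs_core(state, 0.0, False, params)[2]
        d_nuc = _rhs_core(state, 0.0, False, params.replace(feedback_target="ppE_n"))[2]
        # weaker feedback (smaller ppE_n) removes less effector
        assert d_nuc > d_cyt


class TestRestingState:
    def test_shuttling_balance(self, params, rest):
        assert rest[6] / rest[3] == pytest.approx(0.8, abs=1e-12)

    def test_closed_form_partition(self, params, rest):
        assert rest[3] == pytest.approx(0.9 / (1 + 0.2 / 0.75), abs=1e-9)
        assert rest[6] == pytest.approx(0.8 * 0.9 / (1 + 0.2 / 0.75), abs=1e-9)

    def test_conservation_exact(self, params, rest):
        assert abs(erk_conservation_total(rest, params) - params.ERK_tot) < 1e-15

    def test_residuals_report_violations(self, params, rest):
        residual, violations = gk.conservation_residuals(rest, params)
        assert abs(residual) < 1e-15 and violations == []
        bad = rest.copy()
        bad[5] = -0.01
        _, violations = gk.conservation_residuals(bad, params)
        assert any("ppE_c" in v for v in violations)


class TestParameterSet:
    def test_defaults_match_published_values(self, params):
        # spot checks across the table, in uM / min units
        assert params.k1 == 5000.0 and params.k_minus1 == 5.0
        assert params.km_2 == 0.0339 and params.kd_ppEn == 0.01
        assert params.K_MM_TF1 == 0.4 and params.d_TF1 == 0.023
        assert params.k_MEK_basal == 0.0 and params.C_cn == 3.0

    def test_fitted_subset(self):
        assert set(gk.FITTED_PARAMS) == {
            "R0", "k2", "k_minus2", "k_exp_act", "k_exp",
            "k_imp_act", "k_imp", "k_mek", "K_MM_MEK", "MEK_tot",
        }

    def test_validation(self):
        with pytest.raises(ValueError):
            gk.ParameterSet(km_1=0.0)  # Michaelis constants strictly positive
        with pytest.raises(ValueError):
            gk.ParameterSet(k1=-1.0)
        with pytest.raises(KeyError):
            gk.ParameterSet.from_dict({"k9": 1.0})

    def test_fitted_roundtrip(self, params):
        values = params.fitted_values() * 2.0
        p2 = params.with_fitted_values(values)
        assert np.allclose(p2.fitted_values(), values)
        assert p2.k1 == params.k1  # unflagged untouched

    def test_mek_inhibition_flag(self):
        prot = make_protocol(events=(InterventionEvent(10.0, "mek_inhibition"),))
        assert not mek_is_inhibited(9.9, prot)
        assert mek_is_inhibited(10.0, prot)
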