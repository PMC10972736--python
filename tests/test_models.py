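"""Single-neuron dynamics: fixed points, bifurcation landmarks, gating rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibnet._integrators import izh_spike_times_from_state
from inhibnet.models import (
    GATING_NAMES,
    IzhikevichParams,
    ViaParams,
    find_hopf_current,
    find_snp_current,
    fi_curve,
    gating_rates,
    gating_steady_state,
    izhikevich_deriv,
    izhikevich_fixed_points,
    simulate_single,
    via_deriv,
    via_resting_potential,
)


class TestIzhikevichDeriv:
    def test_equilibrium_on_nullcline_intersection(self, izh):
        # -62.5 solves 0.04 V^2 + (5-b) V + 140 = 0; with u = bV both rates vanish
        dv, du = izhikevich_deriv(-62.5, izh.b * -62.5, 0.0, izh)
        assert dv == pytest.approx(0.0, abs=1e-12)
        assert du == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_point(self, izh):
        assert izhikevich_deriv(-65.0, 0.0, 0.0, izh) == pytest.approx((-16.0, -1.69))

    @given(v=st.floats(-80, -40), i=st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_u_nullcline_identity(self, v, i):
        p = IzhikevichParams()
        _, du = izhikevich_deriv(v, p.b * v, i, p)
        assert du == pytest.approx(0.0, abs=1e-9)

    def test_rejects_non_finite(self, izh):
        with pytest.raises(ValueError):
            izhikevich_deriv(float("nan"), 0.0, 0.0, izh)


class TestFixedPoints:
    def test_rest_and_saddle_at_zero_current(self, izh):
        fp = izhikevich_fixed_points(izh, 0.0)
        assert [round(v, 6) for v, _, _ in fp] == [-62.5, -56.0]
        assert [lab for *_, lab in fp] == ["stable", "saddle"]

    def test_degenerate_at_fold(self, izh):
        fp = izhikevich_fixed_points(izh, 0.4225)
        assert len(fp) == 1
        assert fp[0][0] == pytest.approx(-59.25)

    def test_empty_beyond_fold(self, izh):
        assert izhikevich_fixed_points(izh, 1.0) == []


class TestHopf:
    def test_default_parameters_value(self, izh):
        assert find_hopf_current(izh) == pytest.approx(0.2625, abs=1e-12)

    def test_trace_zero_voltage(self, izh):
        assert (izh.a - 5.0) / 0.08 == pytest.approx(-61.25)

    def test_no_hopf_when_determinant_negative(self):
        with pytest.raises(ValueError, match="no Hopf"):
            find_hopf_current(IzhikevichParams(a=5.0))

    @given(a=st.floats(0.05, 0.5), b=st.floats(0.1, 0.4))
    @settings(max_examples=30, deadline=None)
    def test_closed_form_matches_fixed_point_condition(self, a, b):
        # the returned I must place a fixed point exactly at the trace-zero V
        p = IzhikevichParams(a=a, b=b)
        vstar = (a - 5.0) / 0.08
        det = a * (b - (0.08 * vstar + 5.0))
        if det <= 0:
            return
        i_ah = find_hopf_current(p)
        assert 0.04 * vstar**2 + (5 - b) * vstar + 140 + i_ah == pytest.approx(0.0, abs=1e-9)


class TestSNPAndFICurve:
    def test_snp_by_bisection_and_grid_agreement(self, izh):
        snp = find_snp_current(izh, dt=0.02)
        # brute-force grid oracle at 1e-3 resolution: bisection within one step
        grid = np.arange(snp - 5e-3, snp + 5e-3, 1e-3)
        persists = []
        for I in grid:
            t, _, _ = izh_spike_times_from_state(
                izh.c, izh.b * izh.c, float(I), izh.a, izh.b, izh.c, izh.d,
                izh.Cm, izh.vpeak, 0.02, int(2500 / 0.02))
            persists.append(int(np.sum(t >= 500)) >= 20)
        first = grid[np.argmax(persists)]
        assert abs(snp - first) <= 1e-3 + 1e-9

    def test_snp_below_hopf(self, izh):
        snp = find_snp_current(izh, dt=0.02)
        assert snp < find_hopf_current(izh)

    def test_bistability_between_snp_and_hopf(self, izh):
        snp = find_snp_current(izh, dt=0.02)
        I = 0.5 * (snp + find_hopf_current(izh))
        quiet = simulate_single("izhikevich", I, t_total=2000.0, dt=0.02)
        spiking, _, _ = izh_spike_times_from_state(
            izh.c, izh.b * izh.c, I, izh.a, izh.b, izh.c, izh.d, izh.Cm,
            izh.vpeak, 0.02, int(2000 / 0.02))
        assert quiet.size == 0  # rest initial condition stays quiescent
        assert np.sum(spiking >= 500) >= 20  # spiking orbit persists

    def test_firing_dies_below_snp(self, izh):
        snp = find_snp_current(izh, dt=0.02)
        t, _, _ = izh_spike_times_from_state(
            izh.c, izh.b * izh.c, snp - 0.01, izh.a, izh.b, izh.c, izh.d,
            izh.Cm, izh.vpeak, 0.02, int(2500 / 0.02))
        assert np.sum(t >= 500) < 20

    def test_fi_hysteresis(self, izh):
        grid = np.arange(0.14, 0.32, 0.02)
        up = dict(fi_curve(izh, grid, "up", dt=0.02))
        down = dict(fi_curve(izh, grid, "down", dt=0.02))
        i_ah = find_hopf_current(izh)
        # up-sweep: silent below the Hopf, discontinuous jump above it
        below = [r for I, r in up.items() if I < i_ah]
        above = [r for I, r in up.items() if I > i_ah]
        assert max(below) == 0.0
        assert min(above) > 15.0
        # down-sweep sustains firing below the Hopf (hysteresis band)
        band = [r for I, r in down.items() if 0.17 < I < i_ah]
        assert min(band) > 0.0

    def test_rate_zero_below_snp_both_directions(self, izh):
        grid = np.array([0.10, 0.12])
        for direction in ("up", "down"):
            for _, r in fi_curve(izh, grid, direction, dt=0.02):
                assert r == 0.0

    def test_dt_convergence_of_spike_times(self, izh):
        # halving dt moves single-neuron spike times by < 1% over 1 s
        def spikes(dt):
            t, _, _ = izh_spike_times_from_state(
                izh.c, izh.b * izh.c, 0.3, izh.a, izh.b, izh.c, izh.d,
                izh.Cm, izh.vpeak, dt, int(1000 / dt))
            return t
        a, b = spikes(0.01), spikes(0.005)
        n = min(a.size, b.size)
        assert n > 10
        assert np.max(np.abs(a[:n] - b[:n]) / b[:n]) < 0.01


class TestViaGating:
    def test_alpha_m_limit_at_theta(self, via):
        al, _ = gating_rates("m", -47.95, via)
        assert al == pytest.approx(0.25 * 4.0, rel=1e-9)

    @pytest.mark.parametrize("name", GATING_NAMES)
    def test_beta_at_zero_mv_equals_k2(self, name, via):
        _, be = gating_rates(name, 0.0, via)
        assert be == pytest.approx(via.gating[name].k2)

    @pytest.mark.parametrize("name", GATING_NAMES)
    def test_alpha_continuous_across_theta(self, name, via):
        th = via.gating[name].theta
        a0 = gating_rates(name, th, via)[0]
        for eps in (-1e-6, 1e-6):
            assert abs(gating_rates(name, th + eps, via)[0] - a0) < 1e-6

    def test_h_available_at_rest_inactivated_at_peak(self, via):
        vr = via_resting_potential(via)
        assert gating_steady_state(vr, via)["h"] > 0.99
        assert gating_steady_state(40.0, via)["h"] < 0.05


class TestViaDeriv:
    def test_gating_derivative_zero_at_steady_state(self, via):
        V = -60.0
        g = gating_steady_state(V, via)
        d = via_deriv((V, g["m"], g["h"], g["n"], g["a"]), 0.0, via)
        assert np.allclose(d[1:], 0.0, atol=1e-12)

    def test_resting_equilibrium(self, via):
        vr = via_resting_potential(via)
        g = gating_steady_state(vr, via)
        d = via_deriv((vr, g["m"], g["h"], g["n"], g["a"]), 0.0, via)
        assert np.max(np.abs(d)) < 1e-9

    def test_k_currents_vanish_at_ek(self, via):
        # at V = EK both potassium terms have zero driving force: dV reflects
        # only Na, leak and applied current
        V = via.EK
        d_full = via_deriv((V, 0.0, 1.0, 0.5, 0.5), 0.0, via)[0]
        d_nok = via_deriv((V, 0.0, 1.0, 0.0, 0.0), 0.0, via)[0]
        assert d_full == pytest.approx(d_nok)

    def test_gating_stays_in_unit_interval(self, via):
        # arbitrary bounded voltage excursions keep all gates in [0, 1]
        rng = np.random.default_rng(7)
        state = [-70.0, 0.1, 0.9, 0.1, 0.1]
        dt = 0.01
        for _ in range(20000):
            V = -90.0 + 140.0 * rng.random()
            d = via_deriv((V, *state[1:]), 0.0, via)
            state[1:] = [min(1.0, max(0.0, x + dt * dd)) for x, dd in zip(state[1:], d[1:])]
        assert all(0.0 <= x <= 1.0 for x in state[1:])

    def test_type2_onset_with_nonzero_minimum_rate(self, via):
        # repetitive-firing onset is abrupt: no sustained sub-20 Hz firing
        silent = simulate_single("via", 250.0, t_total=800.0, dt=0.02)
        firing = simulate_single("via", 400.0, t_total=800.0, dt=0.02)
        assert np.sum(silent > 300) <= 1
        rate = np.sum(firing > 300) / 0.5
        assert rate > 20.0
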