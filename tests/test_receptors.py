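"""Unit and property tests of the two-gate receptor kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtanic.receptors import (
    AgonistLevels,
    ReceptorParams,
    ReceptorState,
    a_inf,
    activation_drive,
    desensitization_drive,
    equilibrium_state,
    half_max_concentration,
    load_params,
    load_preset,
    open_fraction,
    peak_pulse_response,
    s_inf,
    save_params,
    step_receptor,
    tau_s,
)

conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestParams:
    def test_presets_match_published_constants(self, a4b2, a7):
        assert a4b2.ec50 == 30.0 and a4b2.alpha == 3.0 and a4b2.n_a == 1.05
        assert a4b2.ic50 == 0.061 and a4b2.n_d == 0.5
        assert a4b2.tau_a == 0.005 and a4b2.k_tau == 0.11 and a4b2.n_tau == 3.0
        assert a4b2.tau_max == 600.0 and a4b2.tau_0 == 0.5
        assert a7.ec50 == 80.0 and a7.alpha == 2.0 and a7.n_a == 1.73
        assert a7.ic50 == 1.3 and a7.n_d == 2.0
        assert a7.tau_max == 120.0 and a7.tau_0 == 0.05

    def test_unit_conversion_round_trips(self, tmp_path, a4b2, a7):
        for p in (a4b2, a7):
            path = tmp_path / f"{p.subtype}.json"
            save_params(p, path)
            assert load_params(path) == p

    @pytest.mark.parametrize(
        "field,value",
        [("ec50", -1.0), ("ec50", 0.0), ("eta", 1.5), ("eta", -0.1),
         ("alpha", 0.5), ("n_d", 0.0), ("tau_0", 700.0), ("tau_a", 2.0)],
    )
    def test_invalid_parameters_rejected(self, a4b2, field, value):
        kwargs = {f: getattr(a4b2, f) for f in (
            "subtype", "ec50", "alpha", "n_a", "ic50", "n_d", "tau_a",
            "k_tau", "n_tau", "tau_max", "tau_0", "eta")}
        kwargs[field] = value
        with pytest.raises(ValueError):
            ReceptorParams(**kwargs)

    def test_gate_fractions_bounded(self):
        with pytest.raises(ValueError):
            ReceptorState(a=1.2, s=0.5)
        with pytest.raises(ValueError):
            AgonistLevels(ach=-1.0)


class TestDrives:
    def test_activation_drive_mixes_with_nicotine_potency(self, a4b2):
        assert activation_drive(AgonistLevels(0, 0), a4b2) == 0.0
        assert activation_drive(AgonistLevels(30, 0), a4b2) == 30.0
        assert activation_drive(AgonistLevels(0, 1), a4b2) == pytest.approx(3.0)

    def test_desensitization_drive_weights_ach_by_eta(self, a4b2):
        assert desensitization_drive(AgonistLevels(5, 0), a4b2) == 0.0
        p1 = a4b2.with_eta(1.0)
        assert desensitization_drive(AgonistLevels(5, 0.5), p1) == pytest.approx(5.5)
        p05 = a4b2.with_eta(0.5)
        assert desensitization_drive(AgonistLevels(2, 1), p05) == pytest.approx(2.0)


class TestSteadyStates:
    def test_hill_anchors(self, a4b2):
        assert a_inf(0.0, a4b2) == 0.0
        assert a_inf(a4b2.ec50, a4b2) == pytest.approx(0.5)
        assert s_inf(0.0, a4b2) == 1.0
        assert s_inf(a4b2.ic50, a4b2) == pytest.approx(0.5)

    def test_weak_nicotine_activation_is_small(self, a4b2):
        # 0.5 µM nicotine alone: activation drive 1.5 µM, direct Hill value
        assert a_inf(activation_drive(AgonistLevels(0, 0.5), a4b2), a4b2) == (
            pytest.approx(0.041268, abs=1e-5))

    def test_half_micromolar_nicotine_desensitizes_most_a4b2(self, a4b2):
        assert 1.0 - s_inf(0.5, a4b2) == pytest.approx(0.741, abs=1e-3)

    def test_tau_s_limits_and_midpoint(self, a4b2):
        assert tau_s(0.0, a4b2) == pytest.approx(600.0)
        assert tau_s(1e9, a4b2) == pytest.approx(a4b2.tau_0, rel=1e-6)
        assert tau_s(a4b2.k_tau, a4b2) == pytest.approx(
            0.5 * (a4b2.tau_max + a4b2.tau_0))

    @given(c1=conc, c2=conc)
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, a4b2, c1, c2):
        lo, hi = sorted((c1, c2))
        assert a_inf(lo, a4b2) <= a_inf(hi, a4b2)
        assert s_inf(lo, a4b2) >= s_inf(hi, a4b2)
        assert tau_s(lo, a4b2) >= tau_s(hi, a4b2)

    def test_subtype_contrast_at_physiological_nicotine(self, a4b2, a7):
        des_a4b2 = 1.0 - s_inf(0.5, a4b2)
        des_a7 = 1.0 - s_inf(0.5, a7)
        assert des_a4b2 > 4.0 * des_a7


class TestStepping:
    def test_fixed_point_is_stationary(self, a4b2):
        levels = AgonistLevels(ach=1.0, nic=0.3)
        eq = equilibrium_state(levels, a4b2)
        stepped = step_receptor(eq, levels, dt=0.5, p=a4b2)
        assert stepped.a == pytest.approx(eq.a, abs=1e-12)
        assert stepped.s == pytest.approx(eq.s, abs=1e-12)

    def test_long_step_converges_to_steady_state(self, a4b2):
        levels = AgonistLevels(ach=10.0, nic=1.0)
        state = step_receptor(ReceptorState(0.0, 1.0), levels,
                              dt=100 * a4b2.tau_max, p=a4b2)
        eq = equilibrium_state(levels, a4b2)
        assert state.a == pytest.approx(eq.a, abs=1e-12)
        assert state.s == pytest.approx(eq.s, abs=1e-10)

    def test_many_small_steps_match_closed_form(self, a4b2, a7):
        """Sub-stepping reproduces the analytic exponential to <1e-8."""
        rng = np.random.default_rng(7)
        for p in (a4b2, a7):
            state = ReceptorState(0.2, 0.8)
            t_tot = 0.0
            ref_a, ref_s = state.a, state.s
            for _ in range(5):
                levels = AgonistLevels(*rng.uniform(0, 5, size=2))
                dt_seg = float(rng.uniform(0.5, 30.0))
                n = 200
                for _ in range(n):
                    state = step_receptor(state, levels, dt_seg / n, p)
                from vtanic.receptors import (
                    a_inf as ai, activation_drive as ad,
                    desensitization_drive as dd, s_inf as si, tau_s as ts)
                ainf = ai(ad(levels, p), p)
                sinf = si(dd(levels, p), p)
                ref_a = ainf + (ref_a - ainf) * math.exp(-dt_seg / p.tau_a)
                ref_s = sinf + (ref_s - sinf) * math.exp(
                    -dt_seg / ts(dd(levels, p), p))
                t_tot += dt_seg
                assert state.a == pytest.approx(ref_a, abs=1e-8)
                assert state.s == pytest.approx(ref_s, abs=1e-8)

    @given(
        seq=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 50),
                      st.floats(1e-4, 60.0)),
            min_size=1, max_size=20),
        qss=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_gates_stay_in_unit_interval(self, a4b2, seq, qss):
        state = ReceptorState(0.0, 1.0)
        for ach, nic, dt in seq:
            state = step_receptor(state, AgonistLevels(ach, nic), dt, a4b2, qss)
            assert 0.0 <= state.a <= 1.0
            assert 0.0 <= state.s <= 1.0
            assert 0.0 <= open_fraction(state) <= 1.0

    def test_open_fraction_product(self):
        assert open_fraction(ReceptorState(1.0, 1.0)) == 1.0
        assert open_fraction(ReceptorState(0.5, 0.5)) == 0.25
        assert open_fraction(ReceptorState(0.7, 0.0)) == 0.0


class TestDoseResponse:
    def test_zero_agonist_gives_no_response(self, a4b2):
        assert peak_pulse_response(0.0, a4b2) == 0.0

    def test_peak_monotone_in_pulse_concentration(self, a7):
        grid = [1.0, 10.0, 100.0, 1000.0]
        peaks = [peak_pulse_response(c, a7, dt=5e-4) for c in grid]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_half_max_inverts_exact_hill_curve(self):
        curve = lambda c: c / (30.0 + c)
        assert half_max_concentration(curve) == pytest.approx(30.0, rel=5e-3)
        scaled = lambda c: 0.37 * c / (30.0 + c)
        assert half_max_concentration(scaled) == pytest.approx(
            half_max_concentration(curve), rel=1e-3)

    def test_half_max_rejects_non_monotone_curve(self):
        bump = lambda c: c * math.exp(-c / 10.0)
        with pytest.raises(ValueError):
            half_max_concentration(bump)

    def test_pulse_half_max_near_published_ec50(self, a4b2, a7):
        """Peak-based EC50 of 200 ms pulses sits at the activation EC50."""
        for p, ec50 in ((a4b2, 30.0), (a7, 80.0)):
            c_half = half_max_concentration(
                lambda c: peak_pulse_response(c, p, dt=5e-4))
            assert c_half == pytest.approx(ec50, rel=0.05)

    def test_no_pretreatment_means_no_reduction(self, a4b2):
        from vtanic.receptors import pretreatment_reduction
        assert pretreatment_reduction(a4b2, 0.0) == 0.0
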