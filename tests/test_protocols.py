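"""Protocol-level behaviour: pharmacokinetics, blockades, scenario timing."""

import math

import numpy as np
import pytest

from vtanic.circuit import BlockadeFlags
from vtanic.metrics import compute_metrics
from vtanic.protocols import (
    NicotineApplication,
    nic_at_site,
    run_protocol,
    scenario_protocol,
    sweep,
    eta_sweep,
    in_vitro_epsc,
    in_vitro_ipsc,
)


class TestPharmacokinetics:
    app = NicotineApplication(onset=30.0, duration=300.0, concentration=2.0)

    def test_zero_before_onset(self):
        assert nic_at_site(0.0, [self.app]) == 0.0
        assert nic_at_site(29.99, [self.app]) == 0.0

    def test_saturates_toward_applied_concentration(self):
        c = nic_at_site(self.app.onset + 5 * self.app.pk_tau, [self.app])
        assert c == pytest.approx(2.0, rel=0.01)

    def test_washout_is_exponential(self):
        end = self.app.onset + self.app.duration
        c_end = nic_at_site(end - 1e-9, [self.app])
        c_tau = nic_at_site(end + self.app.pk_tau, [self.app])
        assert c_tau == pytest.approx(c_end / math.e, rel=1e-4)

    def test_overlapping_applications_sum(self):
        a = NicotineApplication(onset=0.0, duration=100.0, concentration=1.0)
        b = NicotineApplication(onset=50.0, duration=100.0, concentration=1.0)
        t = 90.0
        assert nic_at_site(t, [a, b]) == pytest.approx(
            nic_at_site(t, [a]) + nic_at_site(t, [b]))

    def test_continuous_at_washout(self):
        end = self.app.onset + self.app.duration
        assert nic_at_site(end - 1e-6, [self.app]) == pytest.approx(
            nic_at_site(end + 1e-6, [self.app]), abs=1e-6)


class TestRunProtocol:
    def test_zero_nicotine_keeps_all_normalized_traces_flat(self):
        proto = scenario_protocol("disinhibition", nic_dose=0.0, horizon=120.0)
        res = run_protocol(proto)
        assert np.allclose(res.column("nu_da_norm"), 1.0, atol=1e-12)
        assert np.allclose(res.column("nu_g_norm"), 1.0, atol=1e-12)

    def test_a4b2_knockout_abolishes_the_da_response(self):
        proto = scenario_protocol("disinhibition", duration=120.0,
                                  blockade=BlockadeFlags(a4b2=True))
        res = run_protocol(proto)
        assert np.max(np.abs(res.column("nu_da_norm") - 1.0)) < 5e-3

    def test_a7_knockout_barely_changes_the_da_response(self):
        control = compute_metrics(run_protocol(
            scenario_protocol("disinhibition", duration=120.0)), "da")
        ko = compute_metrics(run_protocol(
            scenario_protocol("disinhibition", duration=120.0,
                              blockade=BlockadeFlags(a7=True))), "da")
        assert ko.peak_rel_change == pytest.approx(
            control.peak_rel_change, rel=0.10)

    def test_identical_protocols_yield_identical_csv_bytes(self, tmp_path):
        from vtanic.io import write_result

        paths = []
        for i in range(2):
            proto = scenario_protocol("direct_stimulation", duration=60.0,
                                      horizon=300.0)
            path = tmp_path / f"run{i}.csv"
            write_result(run_protocol(proto), path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestInVitro:
    def test_ipsc_modulation_is_a4b2_mediated(self):
        res = in_vitro_ipsc()
        m = compute_metrics(res, "i_gaba")
        assert m.peak_rel_change == pytest.approx(300.0, rel=0.01)
        assert m.post_washout_min < 0.0          # undershoot after washout
        blocked = compute_metrics(
            in_vitro_ipsc(blockade=BlockadeFlags(a4b2=True)), "i_gaba")
        assert blocked.degenerate

    def test_ipsc_undershoot_recovers_on_the_tau_max_scale(self, a4b2):
        res = in_vitro_ipsc()
        t = res.column("time_s")
        rel = res.column("i_gaba") / res.baseline["i_gaba"] - 1.0
        post = t > res.washout + 240.0           # past residual-nicotine phase
        tp, relp = t[post], rel[post]
        i_min = int(np.argmin(relp))
        # fit an exponential to the recovery tail; it should sit near tau_max
        tail = slice(i_min, i_min + int(1200 / (t[1] - t[0])))
        y = -relp[tail]
        ln = np.log(y[y > 1e-6])
        tt = tp[tail][y > 1e-6]
        slope = np.polyfit(tt, ln, 1)[0]
        assert -1.0 / slope == pytest.approx(a4b2.tau_max, rel=0.25)

    def test_epsc_modulation_is_a7_mediated(self):
        m = compute_metrics(in_vitro_epsc(), "i_glu")
        assert m.peak_rel_change == pytest.approx(325.0, rel=0.01)
        same = compute_metrics(
            in_vitro_epsc(blockade=BlockadeFlags(a4b2=True)), "i_glu")
        assert same.peak_rel_change == m.peak_rel_change
        flat = compute_metrics(
            in_vitro_epsc(blockade=BlockadeFlags(a7=True)), "i_glu")
        assert flat.degenerate or abs(flat.peak_rel_change) < 1e-9

    def test_epsc_supra_linear_ipsc_sub_linear_dose_curves(self):
        doses = [0.1, 0.55, 1.0]
        ipsc = [compute_metrics(in_vitro_ipsc(nic_dose=d), "i_gaba"
                                ).peak_rel_change for d in doses]
        epsc = [compute_metrics(in_vitro_epsc(nic_dose=d), "i_glu"
                                ).peak_rel_change for d in doses]
        assert epsc[2] - epsc[1] > epsc[1] - epsc[0]   # increasing slope
        assert ipsc[2] - ipsc[1] < ipsc[1] - ipsc[0]   # decreasing slope


@pytest.fixture(scope="module")
def direct():
    return run_protocol(scenario_protocol("direct_stimulation", duration=120.0))


@pytest.fixture(scope="module")
def disinh():
    return run_protocol(scenario_protocol("disinhibition", duration=120.0))


class TestScenarioTiming:

    @staticmethod
    def _last_elevated(res, frac=0.05):
        t = res.column("time_s")
        d = res.column("nu_da_norm") - 1.0
        level = frac * d.max()
        idx = np.nonzero(d > level)[0]
        return t[idx[-1]]

    @staticmethod
    def _nic_gone(res, frac=0.05):
        t = res.column("time_s")
        nic = res.column("nic_site_uM")
        idx = np.nonzero(nic > frac * nic.max())[0]
        return t[idx[-1]]

    def test_direct_stimulation_does_not_outlast_nicotine(self, direct):
        assert self._last_elevated(direct) <= self._nic_gone(direct) + 5.0

    def test_disinhibition_outlasts_nicotine_by_the_recovery_scale(
            self, disinh, a4b2):
        excess = self._last_elevated(disinh) - self._nic_gone(disinh)
        assert excess > a4b2.tau_max

    def test_disinhibition_boost_is_preceded_by_a_brief_dip(self, disinh):
        t = disinh.column("time_s")
        d = disinh.column("nu_da_norm") - 1.0
        t_peak = t[np.argmax(d)]
        early = d[(t >= disinh.onset) & (t < t_peak)]
        assert early.min() < -1e-4               # transient inhibition
        assert np.argmin(d) < np.argmax(d)

    def test_peak_timing_contrast(self, direct, disinh):
        t_peak_direct = compute_metrics(direct, "da").time_of_peak
        t_peak_disinh = compute_metrics(disinh, "da").time_of_peak
        assert t_peak_direct < direct.washout        # during nicotine rise
        assert t_peak_disinh > disinh.washout        # after clearance


class TestSweeps:
    def test_da_peak_decreases_with_ach_under_direct_stimulation(self):
        table = sweep(scenario_protocol("direct_stimulation"),
                      "nu_ach", [0.1, 0.5, 1.0, 1.77])
        peaks = table["peak_rel_change_pct"].to_numpy()
        assert np.all(np.diff(peaks) < 0)

    def test_net_da_boost_increases_with_ach_under_disinhibition(self):
        table = sweep(scenario_protocol("disinhibition"),
                      "nu_ach", [0.5, 1.0, 1.77, 2.0])
        nets = table["net_change_integral"].to_numpy()
        assert np.all(np.diff(nets) > 0)

    def test_disinhibition_peak_saturates_at_low_nicotine(self):
        table = sweep(scenario_protocol("disinhibition"),
                      "nic_dose", [0.5, 1.0, 3.0])
        peaks = table["peak_rel_change_pct"].to_numpy()
        # 0.5 µM already achieves most of the asymptotic peak
        assert peaks[0] > 0.85 * peaks[-1]

    def test_per_point_failures_are_recorded_and_sweep_continues(self):
        table = sweep(scenario_protocol("disinhibition", horizon=400.0),
                      "r", [0.2, 1.5, 0.8])
        assert table.loc[1, "error"] != ""
        assert table.loc[2, "error"] == ""
        assert np.isfinite(table.loc[2, "peak_rel_change_pct"])


class TestEtaSweep:
    def test_eta_zero_reproduces_default_bit_for_bit(self):
        base = run_protocol(scenario_protocol("disinhibition", horizon=600.0))
        swept = eta_sweep("disinhibition", [0.0], horizon=600.0)[0.0]
        assert base.frame.equals(swept.frame)

    def test_direct_stimulation_marginally_affected_by_eta(self):
        res = eta_sweep("direct_stimulation", [0.0, 1.0], duration=120.0)
        m0 = compute_metrics(res[0.0], "da")
        m1 = compute_metrics(res[1.0], "da")
        # the boost survives with the same sign, timing and order of
        # magnitude — in contrast to the disinhibition case, which inverts
        assert m1.peak_rel_change == pytest.approx(m0.peak_rel_change, rel=0.5)
        assert m0.net_change_integral > 0 and m1.net_change_integral > 0
        washout = res[0.0].washout
        assert m0.time_of_peak <= washout + 1.0   # boost tracks nicotine
        assert m1.time_of_peak <= washout + 1.0

    def test_full_ach_desensitization_inverts_the_disinhibition_response(self):
        res = eta_sweep("disinhibition", [0.0, 1.0], duration=120.0)
        net0 = compute_metrics(res[0.0], "da").net_change_integral
        net1 = compute_metrics(res[1.0], "da").net_change_integral
        assert net0 > 0 > net1
        # GABA activity now rises under nicotine, suppressing DA
        g1 = compute_metrics(res[1.0], "gaba")
        assert g1.peak_rel_change > 0
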