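"""EP and W' measurements: integration oracle, 3MT, CPT partition."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import critpow as cw
from critpow.analysis import duration_bin


def _trace(power, fs=1.0):
    power = np.asarray(power, float)
    return cw.PowerTrace(time=np.arange(power.size) / fs, power=power)


class TestIntegrateAbove:
    def test_linear_ramp_triangle_area(self):
        power = np.linspace(400.0, 300.0, 101)  # 100 s ramp
        assert cw.integrate_above(_trace(power), 300.0) == pytest.approx(5000.0)

    def test_constant_at_reference_is_zero(self):
        assert cw.integrate_above(_trace(np.full(50, 250.0)), 250.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("fs,tol", [(1.0, 0.005), (8.0, 0.0005)])
    def test_exponential_against_quadrature_oracle(self, fs, tol):
        """Trapezoid on the sampled exponential decline vs fine quadrature."""
        cp, pmax, tau, T = 250.0, 700.0, 100.0 / 3.0, 180.0
        n = int(T * fs)
        t = np.arange(n + 1) / fs
        tr = cw.PowerTrace(time=t, power=cp + (pmax - cp) * np.exp(-t / tau))
        est = cw.integrate_above(tr, cp)
        oracle, _ = quad(lambda s: (pmax - cp) * math.exp(-s / tau), 0, T,
                         epsabs=1e-10, epsrel=1e-12)
        assert abs(est - oracle) / oracle < tol

    def test_clip_negative_floors_interval_contributions(self):
        power = np.array([270.0, 230.0, 230.0, 270.0])
        tr = _trace(power)
        signed = cw.integrate_above(tr, 250.0)
        clipped = cw.integrate_above(tr, 250.0, clip_negative=True)
        # middle interval contributes -20 J signed, 0 J clipped
        assert signed == pytest.approx(-20.0)
        assert clipped == pytest.approx(0.0)

    def test_window_outside_trace_rejected(self):
        tr = _trace(np.full(10, 300.0))
        with pytest.raises(cw.AnalysisError):
            cw.integrate_above(tr, 250.0, 0.0, 20.0)
        with pytest.raises(cw.AnalysisError):
            cw.integrate_above(tr, 250.0, 5.0, 5.0)

    def test_fractional_window_interpolates(self):
        power = np.array([300.0, 300.0, 300.0])
        assert cw.integrate_above(_trace(power), 250.0, 0.5, 1.5) == pytest.approx(50.0)


class TestAnalyze3mt:
    def test_constant_trace(self):
        res = cw.analyze_3mt(_trace(np.full(181, 250.0)))
        assert res.ep == pytest.approx(250.0)
        assert res.w_prime == pytest.approx(0.0, abs=1e-9)

    def test_simulated_3mt_matches_analytic_oracle(self, allout_profile, canonical_3mt):
        """EP equals the geometric-series mean of the closed-form curve; W'
        equals the quadrature integral above that EP."""
        p = allout_profile
        tau = p.w_prime / (p.p_max - p.cp)
        r = math.exp(-1.0 / tau)
        # mean of the 31 samples t = 150..180 of cp + (pmax-cp) e^{-t/tau}
        geo = math.exp(-150.0 / tau) * (1.0 - r ** 31) / (1.0 - r) / 31.0
        ep_oracle = p.cp + (p.p_max - p.cp) * geo
        res = cw.analyze_3mt(canonical_3mt.trace)
        assert res.ep == pytest.approx(ep_oracle, abs=1e-9)
        w_oracle, _ = quad(
            lambda t: p.cp + (p.p_max - p.cp) * math.exp(-t / tau) - ep_oracle,
            0, 180)
        assert res.w_prime == pytest.approx(w_oracle, rel=0.005)
        # EP sits above true CP (finite-horizon bias) but within a few watts
        assert 0 < res.ep - p.cp < 5.0
        assert res.w_prime == pytest.approx(p.w_prime, rel=0.05)

    def test_time_shift_invariance_and_power_equivariance(self, canonical_3mt):
        tr = canonical_3mt.trace
        base = cw.analyze_3mt(tr)
        shifted = cw.PowerTrace(time=tr.time + 12.0, power=tr.power)
        offset = cw.PowerTrace(time=tr.time, power=tr.power + 30.0)
        res_s = cw.analyze_3mt(shifted)
        res_o = cw.analyze_3mt(offset)
        assert res_s.ep == pytest.approx(base.ep)
        assert res_s.w_prime == pytest.approx(base.w_prime)
        assert res_o.ep == pytest.approx(base.ep + 30.0)
        assert res_o.w_prime == pytest.approx(base.w_prime, rel=1e-9)

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(cw.AnalysisError, match="shorter"):
            cw.analyze_3mt(_trace(np.full(10, 400.0)), ep_window_s=30)


@pytest.fixture(scope="module")
def analyzed(canonical_cpt):
    seg = cw.segment_cpt(canonical_cpt.trace, 300.0)
    res = cw.analyze_cpt(canonical_cpt.trace, canonical_cpt.meta, seg,
                         ep_reference=250.0)
    return seg, res


class TestAnalyzeCpt:
    def test_partition_matches_truth_with_true_cp_reference(self, canonical_cpt, analyzed):
        _, res = analyzed
        truth = canonical_cpt.truth
        assert res.constant_w_prime == pytest.approx(truth["constant_w_prime_true"], rel=0.01)
        assert res.unaccounted_w_prime == pytest.approx(truth["unaccounted_w_prime_true"], rel=0.02)
        assert res.total_w_prime == pytest.approx(truth["total_w_prime_true"], rel=0.01)
        assert not res.used_fallback

    def test_total_is_exact_sum(self, analyzed):
        _, res = analyzed
        assert res.total_w_prime == res.constant_w_prime + res.unaccounted_w_prime

    def test_duration_bin_from_failure_time(self, analyzed):
        _, res = analyzed
        assert res.constant_duration_s == pytest.approx(192.0)
        assert res.duration_bin == "3-6 min"

    def test_negative_constant_triggers_fallback(self, canonical_cpt):
        """A reference EP above the prescribed power forces the fallback to
        the test's own EP."""
        seg = cw.segment_cpt(canonical_cpt.trace, 300.0)
        res = cw.analyze_cpt(canonical_cpt.trace, canonical_cpt.meta, seg,
                             ep_reference=320.0)
        assert res.used_fallback
        assert res.ep_reference == res.ep_individual
        assert res.constant_w_prime >= 0

    def test_plateau_shorter_than_ep_window_rejected(self, canonical_cpt):
        seg = cw.segment_cpt(canonical_cpt.trace, 300.0)
        short = cw.CptSegmentation(t_fail=seg.t_fail,
                                   t_plateau_start=seg.t_end - 10.0,
                                   t_end=seg.t_end, tolerance_w=10.0,
                                   plateau_rule={})
        with pytest.raises(cw.AnalysisError, match="plateau"):
            cw.analyze_cpt(canonical_cpt.trace, canonical_cpt.meta, short,
                           ep_reference=250.0)

    def test_finer_sampling_reduces_partition_error(self, canonical_profile):
        errs = {}
        for fs in (1.0, 8.0):
            test = cw.simulate_cpt(canonical_profile, prescribed_power=300.0, fs=fs)
            seg = cw.segment_cpt(test.trace, 300.0)
            res = cw.analyze_cpt(test.trace, test.meta, seg, ep_reference=250.0)
            errs[fs] = abs(res.total_w_prime - test.truth["total_w_prime_true"])
        assert errs[8.0] < errs[1.0]


class TestDurationBin:
    @pytest.mark.parametrize("t,label", [
        (45.0, "<1 min"), (59.999, "<1 min"), (60.0, "1-3 min"),
        (90.0, "1-3 min"), (180.0, "3-6 min"), (192.0, "3-6 min"),
        (360.0, ">6 min"), (400.0, ">6 min"),
    ])
    def test_half_open_edges(self, t, label):
        assert duration_bin(t) == label
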