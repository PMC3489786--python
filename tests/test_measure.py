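import json

import numpy as np
import pandas as pd
import pytest

from actonet import hill_fit, mechanical_power, stall_census, summarize
from actonet.measure import MeasurementSeries, motor_force_distribution
from actonet.network import (ACTIVE, KIND_MOTOR, Arm, DomainBoundary,
                             Filament, Linker, NetworkState)


def _series(t, sigma, eps, E=1000.0):
    df = pd.DataFrame({"t_s": t, "sigma_Pa": sigma, "eps": eps,
                       "V_um3": np.full_like(t, 125.0)})
    return MeasurementSeries(df, {"E": E})


class TestSummarize:
    def test_saturating_series_slope(self, p):
        tau, s_inf = 100.0, 50.0
        t = np.arange(0, 200.1, 0.1)
        sigma = s_inf * (1 - np.exp(-t / tau))
        m = summarize(_series(t, sigma, sigma / p.E, p.E), p)
        # OLS slope over t<10 of the closed form, computed independently
        sel = t < 10
        A = np.column_stack([t[sel], np.ones(sel.sum())])
        ref = np.linalg.lstsq(A, sigma[sel], rcond=None)[0][0]
        assert m.sigma_dot0_Pa_s == pytest.approx(ref, rel=1e-9)
        # and within 2% of the analytic derivative-based early slope
        assert m.sigma_dot0_Pa_s == pytest.approx(
            s_inf / tau * (1 - 10 / (2 * tau)), rel=0.02)
        assert m.sigma_p_Pa == pytest.approx(sigma[-1])

    def test_constant_series(self, p):
        t = np.arange(0, 30.0, 0.1)
        m = summarize(_series(t, np.full_like(t, 7.0), np.zeros_like(t)), p)
        assert m.sigma_dot0_Pa_s == pytest.approx(0.0, abs=1e-12)
        assert m.sigma_p_Pa == 7.0

    def test_strain_rate_is_stress_rate_over_E_exactly(self, p):
        t = np.arange(0, 15.0, 0.1)
        m = summarize(_series(t, 3.0 * t, 3.0 * t / p.E), p)
        assert m.eps_dot0_per_s * p.E == m.sigma_dot0_Pa_s

    def test_short_horizon_rejected(self, p):
        t = np.arange(0, 5.0, 0.1)
        with pytest.raises(ValueError, match="horizon"):
            summarize(_series(t, t, t / p.E), p)


class TestHillFit:
    A, B, C = 10.0, 0.0103, 1.0023     # Pa, 1/s, Pa/s

    def _points(self, n=8, noise=0.0, rng=None):
        sig_max = self.C / self.B - self.A
        s = np.linspace(0.05, 0.95, n) * sig_max
        e = self.C / (s + self.A) - self.B
        if noise:
            s = s * (1 + rng.normal(0, noise, n))
            e = e * (1 + rng.normal(0, noise, n))
        return np.column_stack([s, e])

    def test_exact_recovery_to_4_significant_digits(self):
        fit = hill_fit(self._points())
        assert fit.a_Pa == pytest.approx(self.A, rel=1e-4)
        assert fit.b_per_s == pytest.approx(self.B, rel=1e-4)
        assert fit.c_Pa_s == pytest.approx(self.C, rel=1e-4)
        sig_max = self.C / self.B - self.A
        assert fit.shape_factor == pytest.approx(self.A / sig_max, rel=1e-3)

    def test_degenerate_points_rejected(self):
        pts = [(s, 0.0) for s in (1.0, 2.0, 3.0, 4.0)]
        with pytest.raises(ValueError):
            hill_fit(pts)
        with pytest.raises(ValueError):
            hill_fit([(1.0, 0.1)] * 5)

    def test_noisy_recovery_bias_below_10pc(self):
        rng = np.random.default_rng(0)
        fits = [hill_fit(self._points(noise=0.05, rng=rng))
                for _ in range(50)]
        assert np.mean([f.a_Pa for f in fits]) == pytest.approx(
            self.A, rel=0.10)
        assert np.mean([f.b_per_s for f in fits]) == pytest.approx(
            self.B, rel=0.10)
        assert np.mean([f.c_Pa_s for f in fits]) == pytest.approx(
            self.C, rel=0.10)


class TestMechanicalPower:
    def test_zero_strain_rate(self):
        assert mechanical_power(10.0, 0.0, 125.0) == 0.0

    def test_linearity_in_volume(self):
        assert mechanical_power(10.0, 0.01, 250.0) == pytest.approx(
            2 * mechanical_power(10.0, 0.01, 125.0))

    def test_hill_power_curve_is_unimodal(self):
        a, b, c = 10.0, 0.0103, 1.0023
        s = np.linspace(0.01, 0.99, 200) * (c / b - a)
        e = c / (s + a) - b
        P = np.array([mechanical_power(si, ei, 125.0)
                      for si, ei in zip(s, e)])
        peaks = np.sum((P[1:-1] > P[:-2]) & (P[1:-1] > P[2:]))
        assert peaks == 1


# ---------------------------------------------------------------------------
# stall census and motor force distribution
# ---------------------------------------------------------------------------

def _motor_on_two_filaments(p, node0, node1, bp_offset=0.0):
    n = 8
    x = np.arange(n) * p.r0_A
    f0 = Filament(np.column_stack([x, np.zeros(n), np.zeros(n)]))
    f1 = Filament(np.column_stack([x, np.full(n, 140.0), np.zeros(n)]))
    a = f0.nodes[node0]
    b = f1.nodes[node1]
    d = (b - a) / np.linalg.norm(b - a)
    bp = np.vstack([a + d * (p.r0_M + bp_offset), b - d * p.r0_M])
    lk = Linker(KIND_MOTOR, ACTIVE, [Arm(0, node0), Arm(1, node1)], bp)
    lk.backbone_r0 = float(np.linalg.norm(bp[1] - bp[0]))
    st = NetworkState({0: f0, 1: f1}, {},
                      DomainBoundary.cube(5000.0, p.E, False))
    return st, lk


def test_census_all_motors_at_barbed_ends(p):
    st, lk = _motor_on_two_filaments(p, 7, 7)   # barbed index is n-1
    st.linkers[0] = lk
    cen = stall_census(st, p)
    assert cen.barbed == 1.0
    assert cen.fractions().sum() == pytest.approx(1.0)


def test_census_blocked_by_planted_acp(p):
    from actonet.network import INACTIVE, KIND_ACP
    st, lk = _motor_on_two_filaments(p, 3, 3)
    st.linkers[0] = lk
    for fid, node in ((0, 4), (1, 4)):          # both next sites occupied
        xyz = st.filaments[fid].nodes[node] + np.array([0, 0, p.r0_ACP])
        st.linkers[len(st.linkers)] = Linker(
            KIND_ACP, INACTIVE, [Arm(fid, node), Arm()],
            np.vstack([xyz, xyz]))
    cen = stall_census(st, p)
    # the census is over motors; the planted ACPs only provide the blockade
    assert cen.blocked == 1.0
    assert cen.fractions().sum() == pytest.approx(1.0)


def test_census_force_stalled_motor(p):
    st, lk = _motor_on_two_filaments(p, 3, 3)
    # stretch the arm hard along the filament axis toward the pointed end
    lk.bp[0] = st.filaments[0].nodes[3] + np.array(
        [-(p.r0_M + 100.0), 0.0, 0.0])
    st.linkers[0] = lk
    cen = stall_census(st, p)
    assert cen.force == 1.0


def test_motor_force_distribution_quartiles_match_sort(p):
    rng = np.random.default_rng(2)
    st, lk = _motor_on_two_filaments(p, 2, 2)
    st.linkers[0] = lk
    for k in range(1, 6):
        st2, lk2 = _motor_on_two_filaments(p, 2 + (k % 4), 2,
                                           bp_offset=rng.uniform(0, 80))
        st.linkers[k] = lk2
    d = motor_force_distribution(st, p)
    forces = np.sort(d["forces_pN"])
    assert d["median_pN"] == pytest.approx(np.percentile(forces, 50))
    assert d["q1_pN"] == pytest.approx(np.percentile(forces, 25))
    assert d["q3_pN"] == pytest.approx(np.percentile(forces, 75))


def test_single_stretched_motor_distribution(p):
    st, lk = _motor_on_two_filaments(p, 3, 3, bp_offset=50.0)
    st.linkers[0] = lk
    d = motor_force_distribution(st, p)
    ks = p.kappa_s_M * 1e3
    # one stretched arm, one at rest
    assert sorted(d["forces_pN"]) == pytest.approx([0.0, ks * 50.0])


def test_series_round_trip(tmp_path, p):
    t = np.arange(0, 12.0, 0.1)
    s = _series(t, 2 * t, 2 * t / p.E, p.E)
    s.metadata = {"params": p.to_dict(), "seed": 3}
    path = tmp_path / "series.csv"
    s.to_csv(path)
    back = MeasurementSeries.from_csv(path)
    assert back.metadata["seed"] == 3
    pd.testing.assert_frame_equal(back.records, s.records)
    json.dumps(back.metadata)       # metadata stays JSON-serializable
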