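"""Histogram/cut profiles, validation scan, diffusion, MFPT and kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import committor_lab as cl


def make_rc(r, seg=None, in_A=None, in_B=None):
    r = np.asarray(r, float)
    n = len(r)
    seg = np.zeros(n, int) if seg is None else np.asarray(seg)
    in_A = np.zeros(n, bool) if in_A is None else np.asarray(in_A)
    in_B = np.zeros(n, bool) if in_B is None else np.asarray(in_B)
    return cl.RCSeries(r, seg, in_A, in_B)


EDGES = np.linspace(0.0, 1.0, 101)


class TestZC1:
    def test_single_unit_step(self):
        z = cl.zc1(np.array([0.0, 1.0]), np.zeros(2, int), 1, EDGES)
        assert np.allclose(z, 1.0)

    def test_half_step_straddling(self):
        z = cl.zc1(np.array([0.0, 0.5, 1.0]), np.zeros(3, int), 1, EDGES)
        assert z[25] == pytest.approx(0.5)   # only the first step straddles
        assert z[75] == pytest.approx(0.5)   # only the second
        assert z[49] == pytest.approx(0.5)   # bin below the 0.5 meeting point
        assert z[50] == pytest.approx(0.5)   # bin above it

    def test_telegraph_counts_transitions(self):
        z = cl.zc1(np.array([0, 1, 0, 1, 0.0]), np.zeros(5, int), 1, EDGES)
        assert np.allclose(z, 4.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2, 4, 8]))
    def test_integral_identity_phase_scaled(self, seed, lag):
        """integral Z_C,1(r, lag) dr = TSD(lag)/lag with phase averaging
        (exactly TSD at the base lag); machine precision."""
        rng = np.random.default_rng(seed)
        r = rng.random(400)
        seg = np.zeros(400, int)
        rc = make_rc(r)
        z = cl.zc1(r, seg, lag, EDGES)
        integral = cl.nab_integral(z, EDGES)
        assert integral == pytest.approx(cl.tsd(rc, lag) / lag, rel=1e-12)

    def test_cross_segment_pairs_excluded(self):
        r = np.array([0.0, 1.0, 1.0, 0.0])
        z_two = cl.zc1(r, np.array([0, 0, 1, 1]), 1, EDGES)
        assert cl.nab_integral(z_two, EDGES) == pytest.approx(2.0)

    def test_phase_average_toggle(self):
        rng = np.random.default_rng(1)
        r = rng.random(256)
        seg = np.zeros(256, int)
        z_avg = cl.zc1(r, seg, 4, EDGES, phase_average=True)
        z_one = cl.zc1(r, seg, 4, EDGES, phase_average=False)
        # single-pass keeps only phase 0; averaging mixes all four
        assert not np.allclose(z_avg, z_one)


class TestZH:
    def test_plain_histogram_at_base_lag(self):
        rng = np.random.default_rng(2)
        r = rng.random(1000)
        zh = cl.histogram_zh(r, np.zeros(1000, int), 1, EDGES)
        assert zh.sum() == 1000

    @pytest.mark.parametrize("lag", [2, 4, 8, 16])
    def test_lag_halving_exact(self, lag):
        rng = np.random.default_rng(3)
        r = rng.random(4096)
        seg = np.zeros(4096, int)
        zh = cl.histogram_zh(r, seg, lag, EDGES)
        zh2 = cl.histogram_zh(r, seg, 2 * lag, EDGES)
        assert zh2.sum() == pytest.approx(zh.sum() / 2, rel=1e-14)

    def test_uniform_series_flat(self):
        rng = np.random.default_rng(4)
        r = rng.random(200_000)
        zh = cl.histogram_zh(r, np.zeros(len(r), int), 1, EDGES)
        expect = len(r) / 100
        assert np.all(np.abs(zh - expect) < 5 * np.sqrt(expect))


class TestDiffusion:
    def test_arithmetic(self):
        D = cl.diffusion_coefficient(np.array([100.0]), np.array([400.0]), 1)
        assert D[0] == pytest.approx(0.25)

    def test_unsampled_bins_masked(self):
        D = cl.diffusion_coefficient(np.array([1.0, 0.0]), np.array([4.0, 0.0]), 2)
        assert D[0] == pytest.approx(0.125)
        assert np.isnan(D[1])
        with pytest.raises(ValueError):
            cl.diffusion_coefficient(np.zeros(3), np.zeros(3), 1)

    def test_brownian_recovery(self):
        """compute_profiles recovers the diffusion coefficient of reflected
        Brownian motion on [0,1] within 5% on interior bins."""
        rng = np.random.default_rng(5)
        D0 = 1e-3
        steps = rng.normal(0, np.sqrt(2 * D0), 300_000)
        r = np.abs((np.cumsum(steps) + 0.5) % 2 - 1)
        prof = cl.compute_profiles(make_rc(r), nbins=20)
        assert np.nanmean(prof.D[5:15]) == pytest.approx(D0, rel=0.05)

    def test_rescale_identity_and_scaling(self):
        rng = np.random.default_rng(6)
        D0 = 1e-3
        steps = rng.normal(0, np.sqrt(2 * D0), 300_000)
        r = np.abs((np.cumsum(steps) + 0.5) % 2 - 1)
        rs = cl.rescale_unit_diffusion(make_rc(r), nbins=20)
        # constant D: the map is linear with slope 1/sqrt(D)
        assert rs.qt_max == pytest.approx(1 / np.sqrt(D0), rel=0.06)
        # re-estimated diffusion on the rescaled coordinate is ~1
        edges2 = np.linspace(0, rs.qt_max, 21)
        zh = cl.histogram_zh(rs.values, rs.segment_ids, 1, edges2)
        zc = cl.zc1(rs.values, rs.segment_ids, 1, edges2)
        h2 = edges2[1] - edges2[0]
        D2 = cl.diffusion_coefficient(zc, 2 * zh / h2, 1)
        assert np.nanmean(D2[5:15]) == pytest.approx(1.0, abs=0.05)


class TestMFPTModel:
    def grid(self, n=20_000):
        return (np.arange(n) + 0.5) / n

    def test_uniform(self):
        q = self.grid()
        m = cl.DiffusiveModel(q, np.ones(len(q)), np.ones(len(q)))
        assert cl.mfpt_model(m) == pytest.approx(0.5, abs=1e-6)

    def test_uniform_scaled_diffusion(self):
        q = self.grid()
        m = cl.DiffusiveModel(q, np.ones(len(q)), 2 * np.ones(len(q)))
        assert cl.mfpt_model(m) == pytest.approx(0.25, abs=1e-6)

    def test_linear_density(self):
        q = self.grid()
        m = cl.DiffusiveModel(q, 2 * (1 - q), np.ones(len(q)))
        assert cl.mfpt_model(m) == pytest.approx(0.25, abs=1e-6)

    def test_reverse_direction_symmetry(self):
        q = self.grid(2000)
        p = np.exp(-((q - 0.5) / 0.2) ** 2)
        p /= p.sum() * (q[1] - q[0])
        m = cl.DiffusiveModel(q, p, np.ones(len(q)))
        # symmetric density: A->B equals B->A
        assert cl.mfpt_model(m, frm=0.0, to=1.0) == pytest.approx(
            cl.mfpt_model(m, frm=1.0, to=0.0), rel=1e-9)


class TestEventCounting:
    def test_mfpt_direct_hand_case(self):
        rc = make_rc([1.0, 0.5, 0.0], in_A=[0, 0, 1], in_B=[1, 0, 0])
        tau, ev = cl.mfpt_direct(rc, "B->A")
        assert tau == 2.0 and list(ev) == [2]

    def test_never_leaving_b_errors(self):
        rc = make_rc([1.0, 1.0], in_A=[0, 0], in_B=[1, 1])
        with pytest.raises(ValueError, match="no completed"):
            cl.mfpt_direct(rc, "B->A")

    def test_nab_direct_telegraph(self):
        r = np.array([0, 1, 0, 1, 0.0])
        rc = make_rc(r, in_A=r == 0, in_B=r == 1)
        assert cl.nab_direct(rc) == 4

    def test_nab_confined(self):
        rc = make_rc([0.0, 0.0], in_A=[1, 1], in_B=[0, 0])
        assert cl.nab_direct(rc) == 0

    def test_mtpt_hand_cases(self):
        rc = make_rc([0.0, 0.5, 1.0], in_A=[1, 0, 0], in_B=[0, 0, 1])
        assert cl.mtpt_direct(rc)[0] == 2.0
        r = np.array([0, 1, 0, 1.0])
        rc = make_rc(r, in_A=r == 0, in_B=r == 1)
        assert cl.mtpt_direct(rc)[0] == 1.0  # instantaneous jumps

    def test_mtpt_matches_bruteforce(self, walk_traj):
        states = walk_traj[:100_000]
        rc = make_rc(states / 4.0, in_A=states == 0, in_B=states == 4)
        tau_hat, ev = cl.mtpt_direct(rc)
        # brute force: scan reactive segments by hand
        durations = []
        last_state, last_exit = 0, 0
        for k, s in enumerate(states):
            if s == 0 or s == 4:
                lab = 1 if s == 0 else 2
                if last_state and lab != last_state:
                    durations.append(k - last_exit)
                last_state, last_exit = lab, k
        assert list(ev) == durations

    def test_mfpt_direct_matches_chain_solve(self, walk_spec, walk_traj):
        """Direct MFPT from the trajectory agrees with the linear-algebra
        hitting time of the chain within bootstrap error."""
        states = walk_traj
        rc = make_rc(states / 4.0, in_A=states == 0, in_B=states == 4)
        tau, ev = cl.mfpt_direct(rc, "B->A")
        t_exact = cl.markov_mfpt(walk_spec.P, targets=[0])[4]
        se = np.std(ev) / np.sqrt(len(ev))
        assert abs(tau - t_exact) < 3 * se


class TestValidationScan:
    def test_telegraph_flat_at_ln_nab(self):
        rng = np.random.default_rng(7)
        # perfect two-state committor series: random telegraph with dwell
        # times long compared to the largest lag scanned
        r = (np.cumsum(rng.random(20_000) < 0.005) % 2).astype(float)
        rc = make_rc(r, in_A=r == 0, in_B=r == 1)
        scan = cl.validation_scan(rc, i_max=4, nbins=20)
        n_ab = cl.nab_direct(rc)
        assert scan["n_AB"] == n_ab
        # every straddling interval is the full [0, 1] jump, so each lag's
        # profile is exactly constant in r ...
        assert np.allclose(scan["spreads"], 0.0, atol=1e-12)
        # ... equal to ln(transition count) exactly at the base lag
        assert scan["means"][0] == pytest.approx(-np.log(n_ab), abs=1e-12)
        assert scan["passed"]

    def test_committor_passes_distortion_fails(self, dw_spec, dw_traj, dw_rc):
        scan = cl.validation_scan(dw_rc, i_max=8)
        assert scan["passed"]
        rc_bad = cl.project_on_committor(dw_traj, dw_spec,
                                         transform=lambda q: q**2)
        scan_bad = cl.validation_scan(rc_bad, i_max=8)
        assert not scan_bad["passed"]
        assert scan_bad["max_deviation"] > scan["max_deviation"]

    def test_no_transitions_errors(self):
        rc = make_rc(np.full(100, 0.0), in_A=np.ones(100, bool))
        with pytest.raises(ValueError, match="transitions"):
            cl.validation_scan(rc)


class TestFluxAndClosure:
    def test_flux_flat_for_uniform_model(self):
        q = (np.arange(100) + 0.5) / 100
        m = cl.DiffusiveModel(q, np.ones(100), np.ones(100))
        out = cl.flux_profile(m)
        assert out["cv_interior"] == pytest.approx(0.0, abs=1e-12)

    def test_flux_committor_flatter_than_distorted(self, dw_spec, dw_traj, dw_rc):
        m_good = cl.DiffusiveModel.from_rc(dw_rc, nbins=50)
        rc_bad = cl.project_on_committor(dw_traj, dw_spec,
                                         transform=lambda q: q**2)
        m_bad = cl.DiffusiveModel.from_rc(rc_bad, nbins=50)
        cv_good = cl.flux_profile(m_good)["cv_interior"]
        cv_bad = cl.flux_profile(m_bad)["cv_interior"]
        assert cv_good < cv_bad

    def test_kinetic_closure_oracle(self, dw_rc):
        """Eq.-style model MFPT from (p_eq, D) of the committor projection
        agrees with the direct first-passage estimate within 10%."""
        model = cl.DiffusiveModel.from_rc(dw_rc, nbins=50)
        tau_model = cl.mfpt_model(model, frm=1.0, to=0.0)
        tau_direct, _ = cl.mfpt_direct(dw_rc, "B->A")
        assert tau_model == pytest.approx(tau_direct, rel=0.10)
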