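"""Logistic recovery fitting: curves, mixed fits, unperturbed equilibria."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosaicpop as mp
from mosaicpop.recovery import logistic3, logistic4


class TestLogistic3:
    def test_midpoint_gives_sqrt_K(self):
        # at t = m, ln N = ln(K)/2, so N = sqrt(K): K = 10000 -> N = 100
        lnN = logistic3(5.0, math.log(10_000.0), 5.0, 2.0)
        assert math.exp(lnN) == pytest.approx(100.0, rel=1e-12)

    def test_upper_asymptote(self):
        lnK = math.log(1000.0)
        assert abs(logistic3(5 + 50 * 2.0, lnK, 5.0, 2.0) - lnK) < 1e-10

    def test_tail_e_folding_is_return_time(self):
        """The log-scale deviation from equilibrium decays by a factor e per
        phi years (phi is the reciprocal of the return rate).  The decay is
        asymptotic: deep in the tail the ratio equals e to high precision."""
        lnK, m, phi = math.log(1000.0), 5.0, 2.0
        d1 = lnK - logistic3(m + 15 * phi, lnK, m, phi)
        d2 = lnK - logistic3(m + 16 * phi, lnK, m, phi)
        assert d1 / d2 == pytest.approx(math.e, rel=1e-6)
        # one e-fold closer to the inflection the ratio is already within
        # the curvature correction exp(-10) of e
        d1 = lnK - logistic3(m + 10 * phi, lnK, m, phi)
        d2 = lnK - logistic3(m + 11 * phi, lnK, m, phi)
        assert d1 / d2 == pytest.approx(math.e, rel=1e-4)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            logistic3(1.0, 1.0, 1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        lnK=st.floats(0.5, 12.0), m=st.floats(-5.0, 15.0), phi=st.floats(0.1, 8.0),
        t=st.floats(-20.0, 40.0),
    )
    def test_strictly_increasing_in_t(self, lnK, m, phi, t):
        from hypothesis import assume

        # beyond ~30 phi past the inflection the increment underflows float64
        assume((t + 0.5 - m) / phi < 30.0)
        assert logistic3(t + 0.5, lnK, m, phi) > logistic3(t, lnK, m, phi)


class TestLogistic4:
    def test_reduces_to_logistic3_when_A_zero(self):
        t = np.linspace(0, 20, 7)
        assert np.allclose(logistic4(t, 0.0, 6.0, 5.0, 2.0), logistic3(t, 6.0, 5.0, 2.0))

    def test_lower_asymptote(self):
        assert abs(logistic4(5 - 50 * 2.0, 1.5, 7.0, 5.0, 2.0) - 1.5) < 1e-10

    def test_midpoint_by_symmetry(self):
        assert logistic4(5.0, 1.5, 7.0, 5.0, 2.0) == pytest.approx((1.5 + 7.0) / 2)


class TestFitRecovery:
    def test_exact_recovery_noiseless_3param(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0, 0, 10, 17, 10, seed=1)
        f = mp.fit_recovery(segs, form=3, n_boot=0)
        assert f.converged
        assert abs(f.K - 1000) / 1000 < 1e-4
        assert abs(f.m - 5) / 5 < 1e-4
        assert abs(f.phi - 2) / 2 < 1e-4

    def test_exact_recovery_noiseless_4param(self):
        rows = []
        for year in range(1, 171):
            t = (year - 1) % 17 + 1
            rows.append((float(t), logistic4(float(t), 1.2, math.log(800.0), 6.0, 1.8),
                         f"w{(year - 1) % 10}"))
        segs = [pd.DataFrame(rows[i * 17:(i + 1) * 17], columns=["t", "lnN", "weather_label"])
                for i in range(10)]
        f = mp.fit_recovery(segs, form=4, n_boot=0)
        assert f.converged
        assert abs(f.K - 800) / 800 < 1e-4
        assert abs(f.A - 1.2) < 1e-4
        assert abs(f.phi - 1.8) / 1.8 < 1e-4

    def test_constant_series_flags_no_growth(self):
        segs = [
            pd.DataFrame({"t": np.arange(1.0, 18.0), "lnN": math.log(1000.0),
                          "weather_label": [f"w{i % 10}" for i in range(17)]})
        ]
        f = mp.fit_recovery(segs, form=3, n_boot=0)
        assert not f.converged
        assert "no growth" in f.diagnostic

    def test_single_weather_label_rejected(self):
        segs = [pd.DataFrame({"t": np.arange(1.0, 18.0),
                              "lnN": np.linspace(1, 5, 17), "weather_label": "w0"})]
        with pytest.raises(ValueError, match="label"):
            mp.fit_recovery(segs, form=3)

    def test_too_few_points_rejected(self):
        segs = [pd.DataFrame({"t": [1.0, 2.0], "lnN": [1.0, 2.0],
                              "weather_label": ["w0", "w1"]})]
        with pytest.raises(ValueError, match="8"):
            mp.fit_recovery(segs, form=3)

    def test_noisy_recovery_small_study(self):
        errK, errP = [], []
        for r in range(15):
            segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0.1, 0.2, 10, 17, 10, seed=r)
            f = mp.fit_recovery(segs, form=3, n_boot=0)
            assert f.converged
            errK.append(abs(f.K - 1000) / 1000)
            errP.append(abs(f.phi - 2) / 2)
        assert np.median(errK) < 0.10
        assert np.median(errP) < 0.10

    def test_invariant_to_segment_order_and_label_renaming(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0.1, 0.2, 6, 17, 10, seed=4)
        f1 = mp.fit_recovery(segs, form=3, n_boot=0)
        f2 = mp.fit_recovery(segs[::-1], form=3, n_boot=0)
        assert f1.K == pytest.approx(f2.K, rel=1e-9)
        assert f1.phi == pytest.approx(f2.phi, rel=1e-9)
        renamed = []
        mapping = {f"w{i}": f"W{(i + 3) % 10}" for i in range(10)}
        for s in segs:
            s2 = s.copy()
            s2["weather_label"] = s2["weather_label"].map(mapping)
            renamed.append(s2)
        f3 = mp.fit_recovery(renamed, form=3, n_boot=0)
        assert f3.K == pytest.approx(f1.K, rel=1e-9)
        for lab, b in f1.b_y.items():
            assert f3.b_y[mapping[lab]] == pytest.approx(b, abs=1e-9)

    def test_fitted_tail_e_folds_per_phi(self):
        segs = mp.simulate_logistic_trajectory(2000, 4, 1.5, 0.05, 0.1, 10, 17, 10, seed=9)
        f = mp.fit_recovery(segs, form=3, n_boot=0)
        assert f.converged
        d1 = f.lnK - logistic3(f.m + 12 * f.phi, f.lnK, f.m, f.phi)
        d2 = f.lnK - logistic3(f.m + 13 * f.phi, f.lnK, f.m, f.phi)
        assert d1 / d2 == pytest.approx(math.e, rel=1e-5)


class TestFitUnperturbed:
    def _traj(self, Ns):
        years = np.arange(1, len(Ns) + 1)
        rec = pd.DataFrame({
            "year": years, "N": Ns,
            "weather_label": [f"w{(y - 1) % 10}" for y in years],
            "perturbed": False, "analyzed": True, "segment": -1, "t": np.nan,
        })
        return mp.Trajectory(rec, mp.Schedule(removal_fraction=0.0,
                                              total_years=len(Ns), burn_in_years=0))

    def test_constant_series(self):
        f = mp.fit_unperturbed(self._traj([500] * 40))
        assert f.K == pytest.approx(500.0)
        assert all(v == pytest.approx(math.log(500)) for v in f.intercepts.values())

    def test_alternating_labels_geometric_mean(self):
        # labels w0..w9 get N=100 on even labels, 200 on odd -> K = sqrt(100*200)
        Ns = [100 if (y - 1) % 2 == 0 else 200 for y in range(1, 41)]
        f = mp.fit_unperturbed(self._traj(Ns))
        assert f.K == pytest.approx(math.sqrt(100 * 200), rel=1e-12)

    def test_residual_sd_recovered(self):
        """Median relative error of sigma_e over replicates at n = 170 is
        within 10% (a single replicate carries ~6% sampling error)."""
        errs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            base = {f"w{i}": rng.normal(6.0, 0.3) for i in range(10)}
            Ns = [math.exp(base[f"w{(y - 1) % 10}"] + rng.normal(0, 0.2))
                  for y in range(1, 171)]
            f = mp.fit_unperturbed(self._traj(Ns))
            errs.append(abs(f.sigma_e - 0.2) / 0.2)
        assert np.median(errs) < 0.10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mp.fit_unperturbed(self._traj([0] * 10))


class TestSegmentwiseK:
    def test_single_segment_rejected(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0.05, 0, 1, 17, 10, seed=0)
        with pytest.raises(ValueError):
            mp.segmentwise_K(segs)

    def test_constant_K_no_trend(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0.05, 0.0, 8, 17, 10, seed=2)
        ks = mp.segmentwise_K(segs)
        verdict = mp.recovery_decline_test(ks)
        assert not verdict.incomplete_recovery
        assert verdict.slope_ci[0] <= 0 <= verdict.slope_ci[1]

    def test_stepped_decline_recovered(self):
        """K halving every 3rd segment is reproduced by the per-segment
        asymptotes within 15%."""
        segs, true_K = [], []
        for j in range(9):
            K = 1000.0 / (2 ** (j // 3))
            s = mp.simulate_logistic_trajectory(K, 4, 1.5, 0.05, 0.0, 1, 17, 10, seed=10 + j)
            segs.append(s[0])
            true_K.append(K)
        ks = mp.segmentwise_K(segs)
        for k_hat, k_true in zip(ks["K"], true_K):
            assert abs(k_hat - k_true) / k_true < 0.15


class TestSimulateLogisticTrajectory:
    def test_noiseless_points_on_curve(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0, 0, 3, 17, 10, seed=3)
        for s in segs:
            expect = logistic3(s["t"].to_numpy(), math.log(1000.0), 5.0, 2.0)
            assert np.allclose(s["lnN"].to_numpy(), expect)

    def test_same_seed_identical(self):
        a = mp.simulate_logistic_trajectory(1000, 5, 2, 0.1, 0.2, 4, 17, 10, seed=5)
        b = mp.simulate_logistic_trajectory(1000, 5, 2, 0.1, 0.2, 4, 17, 10, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_residual_variance_matches_sigma(self):
        segs = mp.simulate_logistic_trajectory(1000, 5, 2, 0.1, 0.0, 10, 17, 10, seed=6)
        resid = np.concatenate([
            s["lnN"].to_numpy() - logistic3(s["t"].to_numpy(), math.log(1000.0), 5.0, 2.0)
            for s in segs
        ])
        assert abs(resid.var(ddof=1) - 0.01) / 0.01 < 0.25
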