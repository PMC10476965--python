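"""Two-stage SRM estimation: design matrix, least squares, penalized MLE,
validation metrics and filter summaries."""

import numpy as np
import pytest

from dgdecode import fitting, srm
from dgdecode.stimulus import StimulusTrace, OUSpec, ScalingSpec, sample_ou, scale
from dgdecode.metrics import SpikeTrain

from conftest import make_mini_params, mini_bases, MINI_DT


@pytest.fixture(scope="module")
def mini_recording():
    p = make_mini_params()
    eta = sample_ou(OUSpec(3.0, MINI_DT, 30_000.0, seed=1))
    i = scale(eta, ScalingSpec(120.0, 60.0))
    rec = srm.simulate(p, i, seed=2)
    return p, i, rec


class TestDesign:
    def test_zero_stimulus_no_spikes(self):
        kb, hvb, _ = mini_bases()
        i = StimulusTrace(np.zeros(10_000), MINI_DT, "pA")
        d = fitting.build_design(i, SpikeTrain(np.array([]), 1000.0), kb, hvb)
        assert np.all(d.X[:, 0] == 1.0)
        assert np.all(d.X[:, 1:] == 0.0)
        assert d.mask.all()

    def test_single_spike_history_columns(self):
        kb, hvb, _ = mini_bases()
        i = StimulusTrace(np.zeros(10_000), MINI_DT, "pA")
        t0 = 200.0
        d = fitting.build_design(i, SpikeTrain(np.array([t0]), 1000.0), kb, hvb)
        idx0 = int(t0 / MINI_DT)
        edges = np.round(hvb.edges / MINI_DT).astype(int)
        for l in range(hvb.n_bins):
            col = d.X[:, 1 + kb.n_bins + l]
            expected = np.zeros(10_000)
            lo, hi = max(edges[l], 1), edges[l + 1]
            expected[idx0 + lo: min(idx0 + hi, 10_000)] = 1.0
            np.testing.assert_array_equal(col, expected)

    def test_matches_double_loop_oracle(self):
        kb, hvb, _ = mini_bases()
        rng = np.random.default_rng(3)
        n = 10_000  # 1 s
        i = StimulusTrace(rng.standard_normal(n), MINI_DT, "pA")
        spikes = SpikeTrain(np.sort(rng.uniform(0, 1000.0, 5)), 1000.0)
        d = fitting.build_design(i, spikes, kb, hvb)
        ke = np.round(kb.edges / MINI_DT).astype(int)
        spike_idx = np.floor(spikes.times / MINI_DT + 1e-9).astype(int)
        he = np.round(hvb.edges / MINI_DT).astype(int)
        check_rows = rng.integers(0, n, 60)
        for t in check_rows:
            for j in range(kb.n_bins):
                s = sum(i.values[t - u] for u in range(ke[j], ke[j + 1])
                        if 0 <= t - u)
                assert d.X[t, 1 + j] == pytest.approx(s, abs=1e-12)
            for l in range(hvb.n_bins):
                s = sum(1 for ts in spike_idx
                        if max(he[l], 1) <= t - ts < he[l + 1])
                assert d.X[t, 1 + kb.n_bins + l] == s

    def test_basis_exceeding_trace_rejected(self):
        kb, hvb, _ = mini_bases()
        i = StimulusTrace(np.zeros(100), MINI_DT, "pA")
        with pytest.raises(ValueError, match="support"):
            fitting.build_design(i, SpikeTrain(np.array([]), 10.0), kb, hvb)


class TestSubthresholdFit:
    def test_noiseless_recovery_to_ten_digits(self, mini_recording):
        p, i, rec = mini_recording
        d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
        theta = fitting.fit_subthreshold(rec.voltage, d)
        truth = np.concatenate([[p.v_b], p.k_coefs, p.hv_coefs])
        np.testing.assert_allclose(theta, truth, rtol=1e-10)

    def test_constant_voltage_gives_bias_only(self):
        kb, hvb, _ = mini_bases()
        i = StimulusTrace(np.zeros(10_000), MINI_DT, "pA")
        d = fitting.build_design(i, SpikeTrain(np.array([]), 1000.0), kb, hvb)
        theta = fitting.fit_subthreshold(np.full(10_000, -63.2), d)
        assert theta[0] == pytest.approx(-63.2)
        np.testing.assert_array_equal(theta[1:], 0.0)

    def test_masked_rows_do_not_influence_fit(self, mini_recording):
        p, i, rec = mini_recording
        d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
        theta0 = fitting.fit_subthreshold(rec.voltage, d)
        poisoned = rec.voltage.copy()
        poisoned[~d.mask] = 1e6  # sentinel values on masked bins
        theta1 = fitting.fit_subthreshold(poisoned, d)
        np.testing.assert_array_equal(theta0, theta1)

    def test_noisy_recovery_within_monte_carlo_error(self):
        p = make_mini_params()
        errs = []
        for seed in range(8):
            eta = sample_ou(OUSpec(3.0, MINI_DT, 30_000.0, seed=100 + seed))
            i = scale(eta, ScalingSpec(120.0, 60.0))
            rec = srm.simulate(p, i, seed=seed)
            rng = np.random.default_rng(seed)
            noisy = rec.voltage + rng.normal(0, 0.5, rec.voltage.size)
            d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
            errs.append(fitting.fit_subthreshold(noisy, d)
                        - np.concatenate([[p.v_b], p.k_coefs, p.hv_coefs]))
        errs = np.asarray(errs)
        se = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
        assert np.all(np.abs(errs.mean(axis=0)) < 3.5 * se + 1e-9)


@pytest.fixture(scope="module")
def small_problem(mini_recording):
    p, i, rec = mini_recording
    n = 10_000  # 1 s slice
    spikes = SpikeTrain(rec.spikes.times[rec.spikes.times < 1000.0], 1000.0)
    d = fitting.build_design(StimulusTrace(i.values[:n], MINI_DT, "pA"),
                             spikes, p.k_basis, p.hv_basis)
    theta_sub = np.concatenate([[p.v_b], p.k_coefs, p.hv_coefs])
    Y, counts = fitting.build_threshold_design(d.X @ theta_sub, spikes,
                                               p.hth_basis, MINI_DT)
    return Y, counts


class TestLoglik:
    def test_no_spike_limit(self, small_problem):
        Y, _ = small_problem
        counts = np.zeros(Y.shape[0])
        theta = np.concatenate([[1.0, -55.0], np.zeros(Y.shape[1] - 2)])
        ll, _, _ = fitting.loglik(theta, Y, counts, MINI_DT)
        expected = -MINI_DT * np.exp(np.minimum(Y @ theta, 50.0)).sum()
        assert ll == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self, small_problem):
        Y, counts = small_problem
        rng = np.random.default_rng(0)
        theta = np.concatenate([[0.8, -50.0], rng.normal(0, 1, Y.shape[1] - 2)])
        ll, grad, _ = fitting.loglik(theta, Y, counts, MINI_DT, alpha=0.7)
        h = 1e-6
        for j in range(theta.size):
            e = np.zeros_like(theta)
            e[j] = h
            lp = fitting.loglik(theta + e, Y, counts, MINI_DT, alpha=0.7)[0]
            lm = fitting.loglik(theta - e, Y, counts, MINI_DT, alpha=0.7)[0]
            fd = (lp - lm) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-6 * max(1.0, abs(grad[j])))

    def test_hessian_negative_semidefinite(self, small_problem):
        Y, counts = small_problem
        rng = np.random.default_rng(1)
        for _ in range(5):
            theta = np.concatenate([[abs(rng.normal(1, 0.3)), -50.0],
                                    rng.normal(0, 2, Y.shape[1] - 2)])
            _, _, hess = fitting.loglik(theta, Y, counts, MINI_DT, alpha=0.3)
            eigs = np.linalg.eigvalsh(hess)
            assert eigs.max() < 1e-8

    def test_hessian_matches_finite_difference_gradient(self, small_problem):
        Y, counts = small_problem
        theta = np.concatenate([[1.0, -52.0], np.zeros(Y.shape[1] - 2)])
        _, grad0, hess = fitting.loglik(theta, Y, counts, MINI_DT)
        h = 1e-6
        for j in range(0, theta.size, 3):
            e = np.zeros_like(theta)
            e[j] = h
            gp = fitting.loglik(theta + e, Y, counts, MINI_DT)[1]
            gm = fitting.loglik(theta - e, Y, counts, MINI_DT)[1]
            np.testing.assert_allclose(hess[:, j], (gp - gm) / (2 * h),
                                       atol=1e-4, rtol=1e-4)


class TestThresholdFit:
    def test_generative_recovery_multi_seed(self):
        """dv and v_th within 5%; h_th pointwise within 3 SE over seeds."""
        p = make_mini_params(hth1=5.0)
        fits = []
        for seed in range(5):
            eta = sample_ou(OUSpec(3.0, MINI_DT, 60_000.0, seed=200 + seed))
            i = scale(eta, ScalingSpec(120.0, 60.0))
            rec = srm.simulate(p, i, seed=seed)
            d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
            theta_sub = fitting.fit_subthreshold(rec.voltage, d)
            theta_th, _, _ = fitting.fit_threshold(
                d.X @ theta_sub, rec.spikes, p.hth_basis, MINI_DT,
                fitting.FitConfig(alpha_grid=(0.0,)))
            fits.append(fitting.unpack_threshold(theta_th))
        dvs = np.array([f[0] for f in fits])
        vths = np.array([f[1] for f in fits])
        cs = np.array([f[2] for f in fits])
        assert abs(dvs.mean() - p.delta_v) / p.delta_v < 0.05
        assert abs(vths.mean() - p.v_th) / abs(p.v_th) < 0.05
        se = cs.std(axis=0, ddof=1) / np.sqrt(cs.shape[0])
        assert np.all(np.abs(cs.mean(axis=0) - p.hth_coefs) < 3.0 * se + 0.05)

    def test_large_alpha_flattens_filter(self, mini_recording):
        p, i, rec = mini_recording
        d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
        v_hat = d.X @ fitting.fit_subthreshold(rec.voltage, d)
        theta_flat, _, _ = fitting.fit_threshold(
            v_hat, rec.spikes, p.hth_basis, MINI_DT,
            fitting.FitConfig(alpha_grid=(1e7,)))
        c = fitting.unpack_threshold(theta_flat)[2]
        assert np.abs(np.diff(c)).max() < 0.02

    def test_newton_initialization_independent(self, mini_recording):
        p, i, rec = mini_recording
        n = 100_000
        d = fitting.build_design(
            StimulusTrace(i.values[:n], MINI_DT, "pA"),
            SpikeTrain(rec.spikes.times[rec.spikes.times < 10_000.0], 10_000.0),
            p.k_basis, p.hv_basis)
        theta_sub = np.concatenate([[p.v_b], p.k_coefs, p.hv_coefs])
        Y, counts = fitting.build_threshold_design(
            d.X @ theta_sub,
            SpikeTrain(rec.spikes.times[rec.spikes.times < 10_000.0], 10_000.0),
            p.hth_basis, MINI_DT)
        f = lambda th: fitting.loglik(th, Y, counts, MINI_DT)
        init1 = np.concatenate([[1.0, -50.0], np.zeros(Y.shape[1] - 2)])
        init2 = np.concatenate([[0.4, -70.0], 0.5 * np.ones(Y.shape[1] - 2)])
        t1, _ = fitting.newton_ascent(f, init1, tol=1e-8)
        t2, _ = fitting.newton_ascent(f, init2, tol=1e-8)
        np.testing.assert_allclose(t1, t2, atol=1e-6)

    def test_alpha_selected_on_validation(self, mini_recording):
        p, i, rec = mini_recording
        d = fitting.build_design(i, rec.spikes, p.k_basis, p.hv_basis)
        theta_sub = fitting.fit_subthreshold(rec.voltage, d)
        v_hat = d.X @ theta_sub
        eta_v = sample_ou(OUSpec(3.0, MINI_DT, 10_000.0, seed=31))
        i_v = scale(eta_v, ScalingSpec(120.0, 60.0))
        vals = []
        for s in range(3):
            rv = srm.simulate(p, i_v, seed=40 + s)
            dv = fitting.build_design(i_v, rv.spikes, p.k_basis, p.hv_basis)
            vals.append((dv.X @ theta_sub, rv.spikes))
        theta_th, alpha, info = fitting.fit_threshold(
            v_hat, rec.spikes, p.hth_basis, MINI_DT,
            fitting.FitConfig(alpha_grid=(0.0, 1.0, 100.0)), validation=vals)
        assert alpha in (0.0, 1.0, 100.0)
        assert np.isfinite(info["validation_score"])


class TestNormalizedLoglik:
    def test_homogeneous_poisson_model_is_zero(self):
        rng = np.random.default_rng(5)
        n = 50_000
        counts = (rng.random(n) < 0.0005).astype(float)
        lam_bar = counts.sum() / (n * MINI_DT)
        # model that IS the homogeneous Poisson at the empirical rate
        Y = np.column_stack([np.zeros(n), -np.ones(n)])
        theta = np.array([1.0, -np.log(lam_bar)])
        assert fitting.normalized_loglik(theta, Y, counts, MINI_DT) == \
            pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_three_spike_example(self):
        dt = 1.0
        n = 10
        counts = np.zeros(n)
        counts[[2, 5, 8]] = 1.0
        v_hat = np.linspace(-1.0, 1.0, n)
        Y = np.column_stack([v_hat, -np.ones(n)])
        theta = np.array([2.0, 0.5])
        z = Y @ theta
        ll_model = z[2] + z[5] + z[8] - dt * np.exp(z).sum()
        lam_bar = 3.0 / (n * dt)
        ll_pois = 3.0 * np.log(lam_bar) - lam_bar * n * dt
        expected = (ll_model - ll_pois) / (3.0 * np.log(2.0))
        assert fitting.normalized_loglik(theta, Y, counts, dt) == \
            pytest.approx(expected, rel=1e-12)

    def test_structured_model_beats_poisson(self, mini_recording):
        p, i, rec = mini_recording
        theta_th = np.concatenate([[1.0, p.v_th], p.hth_coefs]) / p.delta_v
        v_hat = srm.subthreshold_voltage(p, i, rec.spikes)
        Y, counts = fitting.build_threshold_design(v_hat, rec.spikes,
                                                   p.hth_basis, MINI_DT)
        assert fitting.normalized_loglik(theta_th, Y, counts, MINI_DT) > 0.5

    def test_empty_train_rejected(self):
        Y = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fitting.normalized_loglik(np.array([1.0, 0.0]), Y, np.zeros(10), 0.1)


class TestFilterSummary:
    def test_pure_exponential_closed_form(self):
        basis = srm.BasisSpec(0.0, 8.0, 44)
        dt = 0.1
        A_mohm_ms, tau = 10.0, 40.0  # R = 400 MOhm
        coefs = A_mohm_ms * np.exp(-basis.centers / tau) * dt * 1e-3
        out = fitting.filter_summary(coefs, basis, dt, skip_bins=0)
        assert out.tau == pytest.approx(40.0, rel=1e-6)
        assert out.resistance == pytest.approx(400.0, rel=1e-6)

    def test_two_exponential_tail(self):
        basis = srm.BasisSpec(0.0, 8.0, 44)
        dt = 0.1
        slow = 5.0 * np.exp(-basis.centers / 40.0)
        fast = 50.0 * np.exp(-basis.centers / 1.0)
        coefs = (slow + fast) * dt * 1e-3
        out = fitting.filter_summary(coefs, basis, dt, skip_bins=2)
        assert out.tau == pytest.approx(40.0, rel=0.05)

    def test_noisy_coefficients(self):
        basis = srm.BasisSpec(0.0, 8.0, 44)
        dt = 0.1
        rng = np.random.default_rng(4)
        clean = 10.0 * np.exp(-basis.centers / 40.0)
        coefs = (clean * (1 + rng.normal(0, 0.03, 44))) * dt * 1e-3
        out = fitting.filter_summary(coefs, basis, dt, skip_bins=0)
        assert out.tau == pytest.approx(40.0, rel=0.10)
        assert out.resistance == pytest.approx(400.0, rel=0.10)


class TestValidate:
    def test_self_simulation_metrics(self):
        p = make_mini_params()
        eta = sample_ou(OUSpec(3.0, MINI_DT, 10_000.0, seed=7))
        i = scale(eta, ScalingSpec(120.0, 60.0))
        recs = [srm.simulate(p, i, seed=60 + s, trial_id=s) for s in range(9)]
        out = fitting.validate(p, recs, seed=3)
        assert out["rmse_sub"] == pytest.approx(0.0, abs=1e-9)
        assert out["norm_loglik"] > 0.0
        assert 0.6 < out["md_score"] < 1.5
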