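"""Subject-level estimation tests.

The likelihood is pinned to an independent brute-force joint-Gaussian
oracle (dense block-Toeplitz covariance assembly); the optimizer, the
Laplace curvature and the evidence approximation are checked on data
simulated from the model itself.
"""

import numpy as np
import pytest
from scipy import linalg as sla
from scipy.stats import multivariate_normal, pearsonr

from viscereb.ecfit import (
    InvertOptions,
    ParamVector,
    PriorSpec,
    build_state_space,
    invert_subject,
    loglik_smooth,
    whittle_fisher,
    _neg_log_joint,
    _hyper_init,
)
from viscereb.hemo import fir_taps, kernel_integral
from viscereb.regions import param_index, vector_to_matrix
from viscereb.synthcohort import make_connectivity


def bruteforce_loglik(y, theta, q, r, tr, n_taps):
    """Independent oracle: assemble the full (T*4) x (T*4) covariance of
    the observed process from its block-Toeplitz autocovariance and
    evaluate the joint Gaussian density directly."""
    t_len = y.shape[0]
    a = vector_to_matrix(theta)
    phi = sla.expm(a * tr)
    sig_c = sla.solve_lyapunov(a, -q * np.eye(4))
    taps = fir_taps(tr, n_taps)
    gam = [sig_c]
    for _ in range(t_len + n_taps + 1):
        gam.append(phi @ gam[-1])

    def gx(m):
        return gam[m] if m >= 0 else gam[-m].T

    def gy(m):
        out = np.zeros((4, 4))
        for k in range(n_taps):
            for l in range(n_taps):
                out += taps[k] * taps[l] * gx(m - k + l)
        return out

    blocks = {m: gy(m) for m in range(-(t_len - 1), t_len)}
    cov = np.zeros((4 * t_len, 4 * t_len))
    for i in range(t_len):
        for j in range(t_len):
            cov[4 * i:4 * i + 4, 4 * j:4 * j + 4] = blocks[i - j]
    cov += r * np.eye(4 * t_len)
    return multivariate_normal(np.zeros(4 * t_len), cov).logpdf(y.ravel())


def simulate_from_model(theta, t_len, q, r, seed, tr=2.0, n_taps=16):
    """Draw data exactly from the discrete state-space model."""
    ss = build_state_space(theta, tr, q=q, n_taps=n_taps)
    rng = np.random.default_rng(seed)
    a = vector_to_matrix(theta)
    sig_c = sla.solve_lyapunov(a, -q * np.eye(4))
    chol_q = np.linalg.cholesky(ss.process_noise + 1e-12 * np.eye(4))
    xs = np.zeros((t_len + n_taps, 4))
    xs[0] = rng.multivariate_normal(np.zeros(4), sig_c)
    for t in range(1, t_len + n_taps):
        xs[t] = ss.transition @ xs[t - 1] + chol_q @ rng.standard_normal(4)
    y = np.zeros((t_len, 4))
    for t in range(t_len):
        for k in range(n_taps):
            y[t] += ss.taps[k] * xs[t + n_taps - 1 - k]
    return y + np.sqrt(r) * rng.standard_normal((t_len, 4))


class TestStateSpace:
    def test_decoupled_transition_is_scalar_exponential(self):
        theta = np.zeros(16)  # off-diagonals 0, a_ii = -0.5
        ss = build_state_space(theta, tr_seconds=2.0)
        np.testing.assert_allclose(ss.transition,
                                   np.exp(-1.0) * np.eye(4), atol=1e-12)

    def test_transition_spectral_radius_below_one(self):
        for seed in range(10):
            p = make_connectivity("patient", 0.12, seed)
            ss = build_state_space(p.vector)
            assert np.max(np.abs(np.linalg.eigvals(ss.transition))) < 1.0

    def test_fir_weights_integrate_the_kernel(self):
        ss = build_state_space(np.zeros(16))
        assert ss.taps.sum() == pytest.approx(kernel_integral(), abs=1e-6)

    def test_unstable_matrix_rejected(self):
        theta = np.zeros(16)
        theta[:12] = 0.6
        with pytest.raises(ValueError):
            build_state_space(theta)


class TestLikelihood:
    @pytest.mark.parametrize("t_len,q,r", [(12, 1.0, 0.2), (40, 1.6, 0.05)])
    def test_matches_bruteforce_joint_gaussian(self, t_len, q, r):
        rng = np.random.default_rng(1)
        theta = make_connectivity("patient", 0.1, 3).vector
        y = rng.standard_normal((t_len, 4))
        ll, _ = loglik_smooth(y, theta, (q, r), tr_seconds=2.0)
        oracle = bruteforce_loglik(y, theta, q, r, 2.0, 16)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_zero_length_series_rejected(self):
        with pytest.raises(ValueError):
            loglik_smooth(np.zeros((0, 4)), np.zeros(16), (1.0, 0.1))

    def test_smoothed_states_track_latent_signal(self):
        theta = make_connectivity("patient", 0.0, 0).vector
        y = simulate_from_model(theta, 170, 1.0, 0.01, seed=2)
        ll, means = loglik_smooth(y, theta, (1.0, 0.01))
        assert means.shape == (170, 4)
        assert np.all(np.isfinite(means))

    def test_truth_dominates_perturbed_parameters(self):
        # At the true parameters the likelihood beats a +/-0.2 perturbation
        # of one coupling.  For Gaussian models the log-likelihood ratio at
        # the truth has mean ~ KL and variance ~ 2 KL, so with the Fisher
        # information of this design (SE ~ 0.1 per coupling, KL ~ 2) the
        # per-realization win probability is ~ Phi(sqrt(KL/2)) ~ 0.93; the
        # dominance must hold on average and in the large majority of runs.
        theta = make_connectivity("patient", 0.0, 0).vector
        taps = fir_taps(2.0, 16)
        prior = PriorSpec()
        diffs = []
        n_rep = 60
        j = param_index("PV->SV_L")
        for s in range(n_rep):
            y = simulate_from_model(theta, 170, 1.0, 0.05, seed=500 + s)
            y = np.ascontiguousarray(y)
            hyper = np.array([0.0, np.log(0.05)])
            pt = np.concatenate([theta, hyper])
            pp = pt.copy()
            pp[j] += 0.2 if s % 2 == 0 else -0.2
            f_true = _neg_log_joint(pt, y, 2.0, taps, prior, hyper, 2.0)
            f_pert = _neg_log_joint(pp, y, 2.0, taps, prior, hyper, 2.0)
            # compare likelihood-only terms (equal hyperprior, prior differs)
            lp_t = -0.5 * np.sum((pt[:16] - prior.mean) ** 2 / prior.variance)
            lp_p = -0.5 * np.sum((pp[:16] - prior.mean) ** 2 / prior.variance)
            diffs.append((-f_true - lp_t) - (-f_pert - lp_p))
        diffs = np.array(diffs)
        assert diffs.mean() > 2.0                      # strong average dominance
        assert np.mean(diffs >= 0) >= 0.93 - 3 * np.sqrt(0.93 * 0.07 / n_rep)

    def test_iid_noise_limit_matches_closed_form(self):
        # strongly damped dynamics + tiny innovation: data are ~ iid
        # Gaussian, so doubling the noise variance changes the likelihood
        # by the analytic amount
        theta = np.zeros(16)
        theta[12:] = 1.8  # a_ii ~ -3.0, heavily damped
        rng = np.random.default_rng(3)
        t_len, r = 120, 0.5
        y = np.sqrt(r) * rng.standard_normal((t_len, 4))
        ll1, _ = loglik_smooth(y, theta, (1e-8, r))
        ll2, _ = loglik_smooth(y, theta, (1e-8, 2 * r))
        n = y.size
        ss = float(np.sum(y ** 2))
        expected = (-0.5 * n * np.log(2.0) + 0.5 * ss / r - 0.5 * ss / (2 * r))
        assert (ll2 - ll1) == pytest.approx(expected, rel=1e-4)


class TestInversion:
    def test_recovery_on_model_simulated_subjects(self):
        # pooled correlation between true and estimated couplings across a
        # handful of subjects drawn from the generator's parameter spread
        tru, est = [], []
        for s in range(6):
            p = make_connectivity("patient", 0.16, 40 + s)
            y = simulate_from_model(p.vector, 170, 1.0, 0.015, seed=70 + s)
            y = (y - y.mean(0)) / y.std(0, ddof=1)
            post = invert_subject(y, tr_seconds=2.0)
            tru.append(p.vector[:12])
            est.append(post.mean.values[:12])
        r, _ = pearsonr(np.concatenate(tru), np.concatenate(est))
        assert r > 0.6

    def test_objective_monotone_over_accepted_steps(self):
        p = make_connectivity("patient", 0.1, 5)
        y = simulate_from_model(p.vector, 120, 1.0, 0.05, seed=6)
        y = np.ascontiguousarray((y - y.mean(0)) / y.std(0, ddof=1))
        taps = fir_taps(2.0, 16)
        prior = PriorSpec()
        hyper0 = _hyper_init(y, 2.0, prior.mean, taps)
        from scipy import optimize
        values = []
        args = (y, 2.0, taps, prior, hyper0, 2.0)
        optimize.minimize(
            _neg_log_joint, np.concatenate([prior.mean, hyper0]), args=args,
            method="L-BFGS-B",
            callback=lambda xk: values.append(_neg_log_joint(xk, *args)),
            options={"maxiter": 25, "eps": 1e-5},
        )
        diffs = np.diff(values)
        assert np.all(diffs <= 1e-6)

    def test_white_noise_shrinks_to_prior(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((170, 4))
        tight = PriorSpec(variance=np.full(16, 1e-4))
        post = invert_subject(y, prior=tight, tr_seconds=2.0)
        z = np.abs(post.mean.values - tight.mean) / np.sqrt(tight.variance)
        assert np.all(z < 2.0)

    def test_posterior_covariance_is_spd_and_self_rates_negative(self):
        p = make_connectivity("patient", 0.1, 9)
        y = simulate_from_model(p.vector, 100, 1.0, 0.05, seed=9)
        y = (y - y.mean(0)) / y.std(0, ddof=1)
        post = invert_subject(y, tr_seconds=2.0)
        vals = np.linalg.eigvalsh(post.covariance)
        assert vals.min() > 0
        assert np.all(np.diag(post.mean.matrix) < 0)
        assert np.isfinite(post.free_energy)

    def test_fisher_curvature_tracks_finite_difference_hessian(self):
        # The spectral Fisher information is the EXPECTED negative Hessian
        # of the exact log-likelihood; single realizations scatter around
        # it, so compare against the finite-difference Hessian averaged
        # over several independent datasets.
        from viscereb.ecfit import loglik_smooth
        theta = make_connectivity("patient", 0.0, 0).vector
        t_len, q, r = 170, 1.0, 0.05
        taps = fir_taps(2.0, 16)
        idx = [param_index("PV->SV_L"), param_index("SV_L->C")]
        eps = 5e-3
        fish = whittle_fisher(theta, np.log(q), np.log(r), t_len, 2.0, taps)
        n_rep = 10
        h_acc = {j: 0.0 for j in idx}
        for s in range(n_rep):
            y = np.ascontiguousarray(
                simulate_from_model(theta, t_len, q, r, seed=600 + s))

            def ll_of(th):
                return loglik_smooth(y, th, (q, r))[0]

            for j in idx:
                tp, tm = theta.copy(), theta.copy()
                tp[j] += eps
                tm[j] -= eps
                h_acc[j] += -(ll_of(tp) - 2 * ll_of(theta)
                              + ll_of(tm)) / eps ** 2
        for j in idx:
            assert fish[j, j] == pytest.approx(h_acc[j] / n_rep, rel=0.25)

    def test_evidence_drops_when_a_coupling_is_clamped_wrong(self):
        # refitting with one coupling fixed 0.3 away from truth should
        # lower the Laplace evidence in most realizations
        theta = make_connectivity("patient", 0.0, 0).vector
        j = param_index("PV->SV_L")
        opts = InvertOptions(max_iter=30, spectral_max_iter=100)
        wins, n_rep = 0, 8
        for s in range(n_rep):
            y = simulate_from_model(theta, 120, 1.0, 0.03, seed=300 + s)
            y = (y - y.mean(0)) / y.std(0, ddof=1)
            free = invert_subject(y, opts=opts, tr_seconds=2.0)
            wrong_mean = np.zeros(16)
            wrong_mean[j] = theta[j] + 0.3
            wrong_var = PriorSpec().variance.copy()
            wrong_var[j] = 1e-6  # clamp the coupling at the wrong value
            clamped = invert_subject(
                y, prior=PriorSpec(mean=wrong_mean, variance=wrong_var),
                opts=opts, tr_seconds=2.0)
            if clamped.free_energy < free.free_energy:
                wins += 1
        assert wins >= 0.9 * n_rep
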