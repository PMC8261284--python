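"""Group-level tests: closed-form reduction against a conjugate oracle,
precision-weighted fusion, pruning vs exhaustive search, posterior
probabilities, Welch contrasts and correlations."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from viscereb.ecfit import ParamVector, PriorSpec, SubjectPosterior
from viscereb.groupbayes import (
    GroupDesign,
    GroupModel,
    bmr,
    clinical_correlate,
    evidence_of_mask,
    greedy_prune,
    group_ttest,
    peb_fit,
    posterior_probability,
)
from viscereb.regions import N_PARAMS, PARAM_NAMES, param_index


def _posterior(mean, var, rng=None):
    mean = np.asarray(mean, float)
    cov = np.diag(np.asarray(var, float))
    return SubjectPosterior(ParamVector(mean), cov, 0.0, {})


def _group_model(beta, post_var, prior=PriorSpec(), n=10, between=0.01):
    beta = np.asarray(beta, float).reshape(1, N_PARAMS)
    return GroupModel(
        beta_mean=beta, beta_cov=np.diag(np.full(N_PARAMS, post_var)),
        free_energy=0.0, between_subject_var=np.full(N_PARAMS, between),
        design=GroupDesign.intercept_only(n),
        prior_mean=prior.mean.copy(), prior_var=prior.variance.copy(),
        n_subjects=n,
    )


class TestBmr:
    def test_identity_reduction_changes_nothing(self):
        rng = np.random.default_rng(0)
        m0, s0 = rng.standard_normal(4), np.diag(rng.uniform(0.5, 2, 4))
        m, s = rng.standard_normal(4), np.diag(rng.uniform(0.05, 0.2, 4))
        df, mr, sr = bmr(m0, s0, m, s, m0, s0)
        assert abs(df) < 1e-10
        np.testing.assert_allclose(mr, m, atol=1e-10)
        np.testing.assert_allclose(sr, s, atol=1e-10)

    def test_matches_conjugate_linear_model_evidence(self):
        # oracle: Bayesian linear regression where the marginal likelihood
        # has a closed form; reducing a prior must change the evidence by
        # exactly the marginal-likelihood ratio
        rng = np.random.default_rng(1)
        n, p = 15, 3
        x_mat = rng.standard_normal((n, p))
        s2 = 0.4
        y = x_mat @ np.array([1.0, -0.6, 0.0]) + np.sqrt(s2) * rng.standard_normal(n)
        s0 = np.diag([1.0, 0.7, 1.3])
        m0 = np.zeros(p)

        def log_evidence(s0_, m0_):
            c = x_mat @ s0_ @ x_mat.T + s2 * np.eye(n)
            return multivariate_normal(x_mat @ m0_, c).logpdf(y)

        p0 = np.linalg.inv(s0)
        post_prec = p0 + x_mat.T @ x_mat / s2
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (p0 @ m0 + x_mat.T @ y / s2)
        s0r = np.diag([1.0, 0.7, 1e-8])
        df, _, _ = bmr(m0, s0, post_mean, post_cov, np.zeros(p), s0r)
        oracle = log_evidence(s0r, np.zeros(p)) - log_evidence(s0, m0)
        assert df == pytest.approx(oracle, abs=1e-6)

    def test_switching_off_a_strong_parameter_is_penalized(self):
        # posterior 5 SDs from zero: removing the parameter must lower
        # the evidence
        m0, s0 = np.zeros(2), np.diag([1.0, 1.0])
        m, s = np.array([0.5, 0.0]), np.diag([0.01, 0.5])
        s0r = np.diag([1e-8, 1.0])
        df, _, _ = bmr(m0, s0, m, s, np.zeros(2), s0r)
        assert df < 0

    def test_non_spd_input_rejected(self):
        with pytest.raises(ValueError):
            bmr(np.zeros(2), np.diag([1.0, -1.0]), np.zeros(2),
                np.eye(2), np.zeros(2), np.eye(2))


class TestPebFit:
    def test_identical_subjects_recover_shared_mean(self):
        mean = np.linspace(-0.2, 0.4, N_PARAMS)
        posts = [_posterior(mean, np.full(N_PARAMS, 0.02)) for _ in range(5)]
        gm = peb_fit(posts, GroupDesign.intercept_only(5), group_prior="flat")
        np.testing.assert_allclose(gm.beta_mean[0], mean, atol=1e-8)

    def test_zero_between_variance_gives_precision_weighted_fusion(self):
        rng = np.random.default_rng(3)
        m1, m2 = rng.standard_normal(N_PARAMS), rng.standard_normal(N_PARAMS)
        v1, v2 = 0.04, 0.01
        posts = [_posterior(m1, np.full(N_PARAMS, v1)),
                 _posterior(m2, np.full(N_PARAMS, v2))]
        gm = peb_fit(posts, GroupDesign.intercept_only(2),
                     group_prior="flat", fix_between_var=0.0)
        expected = (m1 / v1 + m2 / v2) / (1 / v1 + 1 / v2)
        np.testing.assert_allclose(gm.beta_mean[0], expected, atol=1e-10)

    def test_group_difference_column_recovers_planted_effect(self):
        rng = np.random.default_rng(4)
        j = param_index("C->SV_L")
        effect = 0.15
        posts = []
        for s in range(30):
            is_pat = s < 20
            true = np.zeros(N_PARAMS)
            true[j] = 0.1 + (effect if is_pat else 0.0)
            noisy = true + 0.05 * rng.standard_normal(N_PARAMS)
            posts.append(_posterior(noisy, np.full(N_PARAMS, 0.0025)))
        design = GroupDesign.two_group(20, 10)
        gm = peb_fit(posts, design, group_prior="flat")
        # column 2 codes controls, so the patient-minus-control effect is
        # minus the group coefficient
        est = -gm.beta_mean[1, j]
        assert est == pytest.approx(effect, rel=0.30)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(np.ones((4, 2)), ("a", "b"))


class TestPruning:
    def test_greedy_matches_exhaustive_enumeration(self):
        # restricted 8-parameter search space: greedy pruning should find
        # the exhaustive-best mask in nearly all random instances
        rng = np.random.default_rng(5)
        n_inst, agree = 40, 0
        free = list(range(8))
        for _ in range(n_inst):
            beta = np.zeros(N_PARAMS)
            beta[free] = np.where(rng.random(8) < 0.5, 0.0,
                                  rng.uniform(0.15, 0.4, 8) * rng.choice([-1, 1], 8))
            gm = _group_model(beta + 0.02 * rng.standard_normal(N_PARAMS),
                              post_var=0.0036)
            rm = greedy_prune(gm)
            # exhaustive search over the 8 free parameters (others on)
            best_f, best_mask = -np.inf, None
            for code in range(256):
                off = np.zeros(N_PARAMS, dtype=bool)
                for b in range(8):
                    if code >> b & 1:
                        off[free[b]] = True
                f = evidence_of_mask(gm, off)
                if f > best_f:
                    best_f, best_mask = f, ~off
            if np.array_equal(rm.mask[free], best_mask[free]):
                agree += 1
        assert agree >= 0.95 * n_inst

    def test_nothing_pruned_when_all_parameters_strong(self):
        rng = np.random.default_rng(6)
        beta = rng.uniform(0.3, 0.5, N_PARAMS) * rng.choice([-1, 1], N_PARAMS)
        gm = _group_model(beta, post_var=0.001)  # >= 5 posterior SDs
        rm = greedy_prune(gm)
        assert rm.mask.all()

    def test_mask_is_monotone_and_terminates(self):
        rng = np.random.default_rng(7)
        beta = np.concatenate([np.zeros(8), rng.uniform(0.2, 0.4, 8)])
        gm = _group_model(beta, post_var=0.004)
        rm = greedy_prune(gm)
        assert rm.mask.shape == (N_PARAMS,)
        # zero-valued parameters pruned, strong ones retained
        assert rm.mask[8:].all()
        assert (~rm.mask[:8]).sum() >= 6


class TestPosteriorProbability:
    def test_prior_equals_posterior_gives_half(self):
        prior = PriorSpec()
        gm = _group_model(np.zeros(N_PARAMS), post_var=1.0)
        gm.beta_cov = np.diag(prior.variance.copy())
        assert posterior_probability(gm, "C->SV_L") == pytest.approx(0.5, abs=1e-9)

    def test_far_from_zero_is_certain(self):
        beta = np.zeros(N_PARAMS)
        beta[param_index("C->SV_L")] = 0.3
        gm = _group_model(beta, post_var=0.0009)  # 10 SDs
        assert posterior_probability(gm, "C->SV_L") > 0.999

    def test_monotone_in_posterior_mean(self):
        pps = []
        for mean in [0.0, 0.02, 0.05, 0.1, 0.2, 0.4]:
            beta = np.zeros(N_PARAMS)
            beta[param_index("SV_L->C")] = mean
            gm = _group_model(beta, post_var=0.0025)
            pps.append(posterior_probability(gm, "SV_L->C"))
        assert np.all(np.diff(pps) > 0)

    def test_unknown_name_rejected(self):
        gm = _group_model(np.zeros(N_PARAMS), post_var=0.01)
        with pytest.raises(KeyError):
            posterior_probability(gm, "C->XX")


class TestGroupTtest:
    def test_identical_groups_give_zero_t(self):
        x = np.tile(np.linspace(0, 1, 16), (5, 1))
        x = x + np.random.default_rng(0).standard_normal((5, 16)) * 1e-9
        tab = group_ttest(np.vstack([x, x]), np.vstack([x, x]))
        assert np.allclose(tab["t"].abs(), 0.0, atol=1e-4)
        assert np.all(tab["p"] > 0.99)

    def test_matches_hand_computed_welch_formula(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[2.0], [3.0], [4.0]])
        tab = group_ttest(np.repeat(a, 16, 1), np.repeat(b, 16, 1))
        # textbook Welch: means 2 and 3, variances 1, n = 3 each
        t_hand = (2.0 - 3.0) / np.sqrt(1 / 3 + 1 / 3)
        assert tab["t"].iloc[0] == pytest.approx(t_hand, abs=1e-10)
        assert tab["df"].iloc[0] == pytest.approx(4.0, abs=1e-10)

    def test_welch_detects_planted_group_difference(self):
        # generator-level power: patient vs control difference on C<->SV_L
        from viscereb.synthcohort import GeneratorConfig, make_connectivity
        cfg = GeneratorConfig()
        j = param_index("C->SV_L")
        detected = 0
        n_cohorts = 25
        for rep in range(n_cohorts):
            pats = np.array([
                make_connectivity("patient", cfg.jitter_sd,
                                  50_000 + rep * 100 + s, cfg).vector
                for s in range(27)])
            cons = np.array([
                make_connectivity("control", cfg.jitter_sd,
                                  60_000 + rep * 100 + s, cfg).vector
                for s in range(11)])
            tab = group_ttest(pats, cons)
            if tab["p"].iloc[j] < 0.05:
                detected += 1
        assert detected >= 0.8 * n_cohorts


class TestClinicalCorrelate:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = clinical_correlate(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = clinical_correlate(x, y)
        assert abs(res["r"]) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            clinical_correlate(np.ones(5), np.arange(5.0))

    def test_planted_link_recovered_at_high_inversion_snr(self):
        # noise-free clinical link + accurate posteriors: the correlation
        # between estimated coupling and recovery must be strong
        from viscereb.synthcohort import (ClinicalLinkConfig, GeneratorConfig,
                                          make_clinical, make_connectivity)
        cfg = GeneratorConfig(clinical=ClinicalLinkConfig(recovery_r2=1.0))
        rng = np.random.default_rng(8)
        j = param_index("C->SV_L")
        est, rec = [], []
        for s in range(27):
            p = make_connectivity("patient", cfg.jitter_sd, 700 + s, cfg)
            r = make_clinical(p, cfg.clinical, seed=800 + s, config=cfg)
            # high-SNR inversion surrogate: small estimation noise
            est.append(p.vector[j] + 0.02 * rng.standard_normal())
            rec.append(r.recovery_os)
        res = clinical_correlate(np.array(est), np.array(rec))
        assert res["r"] >= 0.6
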