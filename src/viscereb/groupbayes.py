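"""Group-level empirical Bayes over subject posteriors, closed-form
Bayesian model reduction, greedy pruning, posterior-probability calls,
frequentist group contrasts and clinical correlations.

The hierarchical model: each subject's 16 coupling parameters are drawn
from ``Normal(design_row . beta, diag(between_subject_var))`` and observed
through that subject's Gaussian posterior (mean + covariance) from the
subject-level inversion.  The group coefficients ``beta`` carry a Gaussian
prior; the between-subject variances are estimated by expectation-
maximization with a weak scaled-identity hyperprior.  Model reduction
(switching couplings off by collapsing their group-level prior variance)
is computed in closed form from the full model's prior and posterior - no
re-visit of the data - and greedy pruning removes couplings while the
group evidence keeps improving.  A coupling's posterior probability is the
evidence-based on/off comparison; the significance rule is Pp > 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ecfit import PriorSpec, SubjectPosterior
from .regions import N_PARAMS, PARAM_NAMES, param_index

_LOG2PI = float(np.log(2.0 * np.pi))
_OFF_FLOOR = 1e-8  # reduced prior variance of a switched-off parameter


@dataclass
class GroupDesign:
    """Subjects x K design matrix; column 1 is the intercept / group mean."""

    matrix: np.ndarray
    column_names: tuple[str, ...] = ("mean",)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names must match design columns")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def intercept_only(cls, n_subjects: int) -> "GroupDesign":
        return cls(np.ones((n_subjects, 1)), ("mean",))

    @classmethod
    def two_group(cls, n_a: int, n_b: int) -> "GroupDesign":
        x = np.column_stack([
            np.ones(n_a + n_b),
            np.concatenate([np.zeros(n_a), np.ones(n_b)]),
        ])
        return cls(x, ("mean", "group"))


@dataclass
class GroupModel:
    beta_mean: np.ndarray            # K x 16
    beta_cov: np.ndarray             # (K*16) x (K*16)
    free_energy: float
    between_subject_var: np.ndarray  # 16
    design: GroupDesign
    prior_mean: np.ndarray           # K*16, group-level prior over beta
    prior_var: np.ndarray            # K*16
    n_subjects: int
    param_names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        k = self.design.matrix.shape[1]
        if self.beta_mean.shape != (k, N_PARAMS):
            raise ValueError("beta_mean must be K x 16")
        if self.beta_cov.shape != (k * N_PARAMS, k * N_PARAMS):
            raise ValueError("beta_cov must be (K*16) x (K*16)")
        if not np.isfinite(self.free_energy):
            raise ValueError("free_energy must be finite")


@dataclass
class ReducedModel:
    mask: np.ndarray                  # 16 booleans per pruned design column
    delta_f: float                    # evidence gain of the final reduction
    reduced_mean: np.ndarray          # K*16
    reduced_cov: np.ndarray           # (K*16) x (K*16)
    column: int
    bma_mean: np.ndarray              # model average over visited reductions
    pp: np.ndarray | None = None      # per-parameter posterior probabilities


def _flat_prior(group: GroupModel) -> tuple[np.ndarray, np.ndarray]:
    return group.prior_mean, np.diag(group.prior_var)


def peb_fit(posteriors: list[SubjectPosterior], design: GroupDesign,
            group_prior: PriorSpec | str | None = None,
            fix_between_var: float | None = None,
            n_em: int = 64, tol: float = 1e-6,
            hyper_nu: float = 2.0, hyper_scale: float = 1 / 16) -> GroupModel:
    """Hierarchical Gaussian fusion of subject posteriors.

    ``beta`` and the diagonal between-subject variances are estimated by
    EM on the marginal likelihood of the subject posterior means (each with
    its own posterior covariance as observation noise).  A weak scaled-
    identity hyperprior (strength ``hyper_nu`` pseudo-subjects at scale
    ``hyper_scale``) keeps the variance estimates away from zero at small
    n.  With ``fix_between_var=0`` the fit collapses to exact
    precision-weighted fusion of the subject posteriors.

    ``group_prior=None`` applies the package's default Gaussian prior over
    beta; pass ``"flat"`` for an improper flat prior (pure GLS point
    estimate, used e.g. to recover precision-weighted fusion exactly).
    """
    n = len(posteriors)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    x = design.matrix
    if x.shape[0] != n:
        raise ValueError("design rows must match number of posteriors")
    k = x.shape[1]
    mus = np.array([p.mean.values for p in posteriors])          # n x 16
    sigmas = np.array([p.covariance for p in posteriors])        # n x 16 x 16
    for i, s in enumerate(sigmas):
        vals = np.linalg.eigvalsh(0.5 * (s + s.T))
        if vals.min() <= 0:
            raise ValueError(f"subject {i} posterior covariance is not SPD")

    if group_prior is None:
        group_prior = PriorSpec()
    if isinstance(group_prior, str):
        if group_prior != "flat":
            raise ValueError("group_prior must be a PriorSpec, 'flat' or None")
        prior_mean = np.zeros(k * N_PARAMS)
        prior_prec = np.zeros(k * N_PARAMS)
    else:
        prior_mean = np.tile(group_prior.mean, k)
        prior_prec = 1.0 / np.tile(group_prior.variance, k)

    d = np.full(N_PARAMS, hyper_scale if fix_between_var is None else fix_between_var)
    d = np.maximum(d, 1e-12)
    xt_kron = [np.kron(x[s], np.eye(N_PARAMS)) for s in range(n)]  # 16 x (K*16)

    beta = np.zeros(k * N_PARAMS)
    f_old = -np.inf
    free_energy = np.nan
    for _ in range(n_em):
        # E/GLS step: posterior over beta given D
        prec = np.diag(prior_prec).astype(float)
        rhs = prior_prec * prior_mean
        vs_inv = []
        for s in range(n):
            v = sigmas[s] + np.diag(d)
            vi = np.linalg.inv(v)
            vs_inv.append(vi)
            xs = xt_kron[s]
            prec += xs.T @ vi @ xs
            rhs += xs.T @ vi @ mus[s]
        beta_cov = np.linalg.inv(prec)
        beta = beta_cov @ rhs

        # free energy: Gaussian marginal of the subject means + hyperprior
        f = 0.0
        for s in range(n):
            v = sigmas[s] + np.diag(d)
            resid = mus[s] - xt_kron[s] @ beta
            sign, logdet = np.linalg.slogdet(v)
            f += -0.5 * (N_PARAMS * _LOG2PI + logdet + resid @ vs_inv[s] @ resid)
        # beta prior and Occam terms (skipped for a flat prior)
        if np.any(prior_prec > 0):
            dbeta = beta - prior_mean
            f += -0.5 * float(np.sum(prior_prec * dbeta ** 2))
            f += 0.5 * float(np.linalg.slogdet(beta_cov)[1])
            f += 0.5 * float(np.sum(np.log(prior_prec)))
        f += float(np.sum(-hyper_nu * d / (2 * hyper_scale)))  # exponential hyperprior

        if fix_between_var is None:
            # M step for the between-subject variances (diagonal)
            acc = np.zeros(N_PARAMS)
            for s in range(n):
                v = sigmas[s] + np.diag(d)
                vi = vs_inv[s]
                resid = mus[s] - xt_kron[s] @ beta
                # posterior of the subject-level parameters
                gain = np.diag(d) @ vi
                m_s = xt_kron[s] @ beta + gain @ resid
                c_s = np.diag(d) - gain @ np.diag(d)
                dev = m_s - xt_kron[s] @ beta
                acc += dev ** 2 + np.diag(c_s)
                acc += np.diag(xt_kron[s] @ beta_cov @ xt_kron[s].T)
            d = (acc + hyper_nu * hyper_scale) / (n + hyper_nu)
            d = np.maximum(d, 1e-10)
        if abs(f - f_old) < tol:
            free_energy = f
            break
        f_old = f
        free_energy = f

    return GroupModel(
        beta_mean=beta.reshape(k, N_PARAMS),
        beta_cov=0.5 * (beta_cov + beta_cov.T),
        free_energy=float(free_energy),
        between_subject_var=d.copy(),
        design=design,
        prior_mean=prior_mean,
        prior_var=np.where(prior_prec > 0, 1.0 / np.maximum(prior_prec, 1e-300), np.inf),
        n_subjects=n,
    )


def bmr(full_prior_mean: np.ndarray, full_prior_cov: np.ndarray,
        post_mean: np.ndarray, post_cov: np.ndarray,
        red_prior_mean: np.ndarray, red_prior_cov: np.ndarray,
        ) -> tuple[float, np.ndarray, np.ndarray]:
    """Closed-form Bayesian model reduction for Gaussian prior/posterior.

    Given the full model's prior N(m0, S0) and posterior N(m, S), and a
    reduced prior N(m0r, S0r), returns the log-evidence difference
    ``delta_F = log Z_reduced - log Z_full`` and the reduced posterior,
    using the precision-space identity
    ``delta_F = log int q(t) p0r(t)/p0(t) dt`` - no data re-visit.
    """
    def as_cov(c):
        c = np.asarray(c, dtype=float)
        return np.diag(c) if c.ndim == 1 else c

    s0, s, s0r = as_cov(full_prior_cov), as_cov(post_cov), as_cov(red_prior_cov)
    s0r = s0r + np.eye(s0r.shape[0]) * 0.0
    for mat, name in ((s0, "full prior"), (s, "posterior"), (s0r, "reduced prior")):
        if np.linalg.eigvalsh(0.5 * (mat + mat.T)).min() <= 0:
            raise ValueError(f"{name} covariance is not SPD")
    m0 = np.asarray(full_prior_mean, float)
    m = np.asarray(post_mean, float)
    m0r = np.asarray(red_prior_mean, float)

    p0 = np.linalg.inv(s0)
    p = np.linalg.inv(s)
    p0r = np.linalg.inv(s0r)
    pr = p + p0r - p0
    vals = np.linalg.eigvalsh(0.5 * (pr + pr.T))
    if vals.min() <= 0:
        raise ValueError("reduced posterior precision is not SPD")
    br = p @ m + p0r @ m0r - p0 @ m0
    sr = np.linalg.inv(pr)
    mr = sr @ br

    logdets = (np.linalg.slogdet(p)[1] + np.linalg.slogdet(p0r)[1]
               - np.linalg.slogdet(p0)[1] - np.linalg.slogdet(pr)[1])
    quad = (br @ sr @ br - m @ p @ m - m0r @ p0r @ m0r + m0 @ p0 @ m0)
    delta_f = 0.5 * (logdets + quad)
    return float(delta_f), mr, 0.5 * (sr + sr.T)


def _reduced_prior(group: GroupModel, off: np.ndarray, column: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Group-level prior with the masked-off parameters of one design
    column collapsed to (0, _OFF_FLOOR)."""
    mean = group.prior_mean.copy()
    var = group.prior_var.copy()
    var = np.where(np.isinf(var), 1e6, var)  # flat prior approximated when reducing
    idx = column * N_PARAMS + np.flatnonzero(off)
    mean[idx] = 0.0
    var[idx] = _OFF_FLOOR
    return mean, var


def _full_prior_arrays(group: GroupModel) -> tuple[np.ndarray, np.ndarray]:
    var = np.where(np.isinf(group.prior_var), 1e6, group.prior_var)
    return group.prior_mean, var


def evidence_of_mask(group: GroupModel, off: np.ndarray, column: int = 0) -> float:
    """delta_F (vs the full model) of switching off a set of parameters."""
    m0, v0 = _full_prior_arrays(group)
    m0r, v0r = _reduced_prior(group, off, column)
    df, _, _ = bmr(m0, v0, group.beta_mean.ravel(), group.beta_cov, m0r, np.diag(v0r))
    return df


def greedy_prune(group: GroupModel, column: int = 0,
                 stop_threshold: float = 0.0) -> ReducedModel:
    """Remove parameters one at a time while the evidence improves.

    Each iteration evaluates every single additional switch-off via
    closed-form reduction, accepts the best if its evidence gain exceeds
    ``stop_threshold``, and repeats; a parameter once removed is never
    re-admitted.  Also records a Bayesian model average over all visited
    reductions (softmax of their evidence).
    """
    m0, v0 = _full_prior_arrays(group)
    post_mean = group.beta_mean.ravel()
    off = np.zeros(N_PARAMS, dtype=bool)
    current_f = 0.0
    visited: list[tuple[float, np.ndarray]] = []

    _, full_red_mean, _ = bmr(m0, v0, post_mean, group.beta_cov, m0, np.diag(v0))
    visited.append((0.0, full_red_mean))
    for _ in range(N_PARAMS):
        best_gain, best_j, best_f = -np.inf, -1, None
        for j in np.flatnonzero(~off):
            cand = off.copy()
            cand[j] = True
            f_cand = evidence_of_mask(group, cand, column)
            if f_cand - current_f > best_gain:
                best_gain, best_j, best_f = f_cand - current_f, j, f_cand
        if best_j < 0 or best_gain <= stop_threshold:
            break
        off[best_j] = True
        current_f = best_f
        m0r, v0r = _reduced_prior(group, off, column)
        _, mr, _ = bmr(m0, v0, post_mean, group.beta_cov, m0r, np.diag(v0r))
        visited.append((current_f, mr))

    m0r, v0r = _reduced_prior(group, off, column)
    _, red_mean, red_cov = bmr(m0, v0, post_mean, group.beta_cov, m0r, np.diag(v0r))
    weights = np.exp([f - max(v[0] for v in visited) for f, _ in visited])
    weights /= weights.sum()
    bma = np.sum([w * m for w, (_, m) in zip(weights, visited)], axis=0)
    pp = np.array([posterior_probability(group, name, column)
                   for name in group.param_names])
    return ReducedModel(mask=~off, delta_f=float(current_f), reduced_mean=red_mean,
                        reduced_cov=red_cov, column=column, bma_mean=bma, pp=pp)


def posterior_probability(group: GroupModel, param_name: str, column: int = 0) -> float:
    """Probability that a coupling is present, from the evidence difference
    between the model with the parameter free and with it switched off:
    ``Pp = 1 / (1 + exp(-(F_with - F_without)))``."""
    j = param_index(param_name)
    off = np.zeros(N_PARAMS, dtype=bool)
    off[j] = True
    delta_keep = -evidence_of_mask(group, off, column)
    # logistic of the evidence difference, numerically clipped
    return float(1.0 / (1.0 + np.exp(-np.clip(delta_keep, -700, 700))))


def group_ttest(patient_means: np.ndarray, control_means: np.ndarray,
                correct: str | None = None) -> pd.DataFrame:
    """Welch (unequal-variance) two-sample t-test per coupling parameter.

    Input rows are subjects, columns the 16 parameters.  Returns a table
    with t, two-sided p and Welch degrees of freedom; optional
    Benjamini-Hochberg adjusted p-values with ``correct='bh'``.
    """
    a = np.atleast_2d(np.asarray(patient_means, float))
    b = np.atleast_2d(np.asarray(control_means, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on parameter count")
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if np.any((va == 0) & (vb == 0)):
        raise ValueError("degenerate (zero) variance in both groups")
    na, nb = a.shape[0], b.shape[0]
    df_num = (va / na + vb / nb) ** 2
    df_den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    table = pd.DataFrame({
        "parameter": list(PARAM_NAMES[:a.shape[1]]),
        "t": np.asarray(res.statistic),
        "p": np.asarray(res.pvalue),
        "df": df_num / np.maximum(df_den, 1e-300),
        "mean_patient": a.mean(axis=0),
        "mean_control": b.mean(axis=0),
    })
    if correct == "bh":
        table["p_adj"] = stats.false_discovery_control(table["p"], method="bh")
    return table


def clinical_correlate(subject_param: np.ndarray, clinical_measure: np.ndarray,
                       ) -> dict:
    """Pearson correlation between one coupling (across subjects) and one
    clinical measure, with scatter-plot data for the figure analogue."""
    x = np.asarray(subject_param, float)
    y = np.asarray(clinical_measure, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation inputs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "r": float(r), "p": float(p), "n": int(len(x)),
        "scatter": {"x": x.tolist(), "y": y.tolist()},
        "fit": {"slope": float(slope), "intercept": float(intercept)},
    }
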