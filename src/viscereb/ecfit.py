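"""Subject-level Bayesian estimation of the 4x4 directed coupling matrix.

This is a deliberately simplified linear-Gaussian surrogate for a full
variational stochastic model inversion: latent neural dynamics follow the
continuous-time linear system ``dx/dt = A x + w`` discretized exactly at
the scan TR (matrix-exponential propagator, Lyapunov-increment process
noise) and observed through a fixed FIR hemodynamic kernel with additive
white noise.  The likelihood is the exact Gaussian state-space likelihood
(Kalman filter, numba-compiled); optimization runs in two stages - a fast
spectral (Whittle) approximation with analytic gradients to get near the
mode, then quasi-Newton polish on the exact likelihood.  The posterior over
the 16 vectorized couplings is a Laplace approximation whose curvature is
the spectral Fisher information plus the prior precision (the expected
Hessian), marginalized over the two noise hyperparameters.

Estimated per subject: posterior mean and 16x16 covariance over the
couplings, a Laplace free-energy (log-evidence) approximation, and point
estimates of the innovation/observation noise variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from ._kalman import kalman_filter_store, kalman_loglik, rts_smoother
from .hemo import HrfParams, fir_taps
from .regions import (
    N_PARAMS,
    OFFDIAG_PAIRS,
    PARAM_NAMES,
    is_stable,
    vector_to_matrix,
)
from .signals import RoiTimeSeries

_N = 4
_UNSTABLE_PENALTY = 1.0e7


@dataclass
class ParamVector:
    """The 16 coupling parameters with the package-wide name <-> index map."""

    values: np.ndarray
    index_map: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PARAMS,):
            raise ValueError("ParamVector requires 16 values")
        if tuple(self.index_map) != PARAM_NAMES:
            raise ValueError("index_map must equal the canonical PARAM_NAMES order")

    def __getitem__(self, name: str) -> float:
        from .regions import param_index
        return float(self.values[param_index(name)])

    @property
    def matrix(self) -> np.ndarray:
        return vector_to_matrix(self.values)


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors: zero-mean couplings with variance 1/16
    on the off-diagonals and 1/64 on the self log-scalings."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))
    variance: np.ndarray = field(
        default_factory=lambda: np.concatenate([np.full(12, 1 / 16), np.full(4, 1 / 64)])
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "variance", np.asarray(self.variance, dtype=float))
        if self.mean.shape != (N_PARAMS,) or self.variance.shape != (N_PARAMS,):
            raise ValueError("prior mean/variance must have length 16")
        if np.any(self.variance <= 0):
            raise ValueError("prior variances must be positive")


@dataclass
class SubjectPosterior:
    mean: ParamVector
    covariance: np.ndarray
    free_energy: float
    fit_diagnostics: dict

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (N_PARAMS, N_PARAMS):
            raise ValueError("covariance must be 16x16")
        if not np.isfinite(self.free_energy):
            raise ValueError("free_energy must be finite")


@dataclass(frozen=True)
class InvertOptions:
    n_starts: int = 1          # extra starts jitter the prior-mean start
    max_iter: int = 80         # exact-likelihood polish iterations
    spectral_max_iter: int = 200
    ftol: float = 1e-9
    gtol: float = 2e-4
    fd_step: float = 1e-5
    n_taps: int = 16
    hyper_log_sd: float = 2.0  # weak log-normal hyperprior on q and r
    seed: int = 0


@dataclass
class StateSpace:
    """Discrete-time operators of the surrogate model at one parameter point."""

    transition: np.ndarray          # 4x4 propagator expm(A*TR)
    process_noise: np.ndarray       # 4x4 integrated innovation covariance
    taps: np.ndarray                # FIR observation weights (per lag block)
    stationary_aug_cov: np.ndarray  # (4L, 4L) stationary augmented covariance


def build_state_space(params: np.ndarray | ParamVector, tr_seconds: float = 2.0,
                      hrf_params: HrfParams = HrfParams(),
                      q: float = 1.0, n_taps: int = 16) -> StateSpace:
    """Exact discretization of the continuous model at the scan TR.

    The propagator is ``expm(A*TR)``; the process noise integrates the
    white innovation over one TR via the stationary Lyapunov solution
    ``Qd = S - Phi S Phi'`` with ``A S + S A' + q I = 0``.
    """
    theta = params.values if isinstance(params, ParamVector) else np.asarray(params, float)
    a = vector_to_matrix(theta)
    if not is_stable(a):
        raise ValueError("unstable coupling matrix")
    phi = sla.expm(a * tr_seconds)
    sig_c = sla.solve_lyapunov(a, -q * np.eye(_N))
    qd = sig_c - phi @ sig_c @ phi.T
    taps = fir_taps(tr_seconds, n_taps, hrf_params)
    p0 = _stationary_aug_cov(phi, sig_c, n_taps)
    return StateSpace(phi, 0.5 * (qd + qd.T), taps, p0)


def _stationary_aug_cov(phi: np.ndarray, sig_c: np.ndarray, l_taps: int) -> np.ndarray:
    """Block (i,j) is Cov(x_{t-i}, x_{t-j}) = Gamma(j-i), Gamma(m>=0) = Phi^m S."""
    gam = np.empty((l_taps, _N, _N))
    gam[0] = sig_c
    for m in range(1, l_taps):
        gam[m] = phi @ gam[m - 1]
    d = np.arange(l_taps)[None, :] - np.arange(l_taps)[:, None]  # j - i
    blocks = gam[np.abs(d)]
    blocks = np.where((d < 0)[:, :, None, None], blocks.transpose(0, 1, 3, 2), blocks)
    return np.ascontiguousarray(
        blocks.transpose(0, 2, 1, 3).reshape(l_taps * _N, l_taps * _N))


def _phi_sig_fast(a: np.ndarray, tr: float, q: float,
                  lam: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Propagator and stationary covariance via A's eigenbasis (with a
    dense fallback for ill-conditioned decompositions)."""
    try:
        if lam is None:
            lam, vec = np.linalg.eig(a)
        else:
            _, vec = np.linalg.eig(a)
        vinv = np.linalg.inv(vec)
        if (np.linalg.cond(vec) < 1e8
                and np.min(np.abs(lam[:, None] + lam[None, :])) > 1e-10):
            phi = ((vec * np.exp(lam * tr)) @ vinv).real
            m_lyap = -1.0 / (lam[:, None] + lam[None, :])
            c_tilde = vinv @ (q * np.eye(_N)) @ vinv.T
            sig_c = (vec @ (c_tilde * m_lyap) @ vec.T).real
            return phi, 0.5 * (sig_c + sig_c.T)
    except np.linalg.LinAlgError:
        pass
    phi = sla.expm(a * tr)
    sig_c = sla.solve_lyapunov(a, -q * np.eye(_N))
    return phi, 0.5 * (sig_c + sig_c.T)


def loglik_smooth(roi_ts: RoiTimeSeries | np.ndarray, params: np.ndarray | ParamVector,
                  noise_vars: tuple[float, float],
                  tr_seconds: float | None = None,
                  hrf_params: HrfParams = HrfParams(), n_taps: int = 16,
                  return_covariances: bool = False):
    """Exact log-likelihood plus smoothed latent neural states.

    ``noise_vars`` is (innovation variance q, observation noise variance r).
    Returns ``(loglik, smoothed_means)`` with means of shape (T, 4), or
    ``(loglik, means, covariances)`` when requested.
    """
    y, tr = _extract_data(roi_ts, tr_seconds)
    q, r = float(noise_vars[0]), float(noise_vars[1])
    if q <= 0 or r <= 0:
        raise ValueError("noise variances must be positive")
    if y.shape[0] == 0:
        raise ValueError("zero-length series")
    ss = build_state_space(params, tr, hrf_params, q=q, n_taps=n_taps)
    ll, m_pred, p_pred, m_filt, p_filt = kalman_filter_store(
        y, ss.transition, ss.process_noise, ss.taps, r, ss.stationary_aug_cov
    )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood (numerical blow-up)")
    m_s, p_s = rts_smoother(ss.transition, m_pred, p_pred, m_filt, p_filt)
    means = m_s[:, :_N]
    if return_covariances:
        return float(ll), means, p_s[:, :_N, :_N]
    return float(ll), means


def _extract_data(roi_ts, tr_seconds):
    if isinstance(roi_ts, RoiTimeSeries):
        return np.ascontiguousarray(roi_ts.data), roi_ts.tr_seconds
    y = np.ascontiguousarray(np.asarray(roi_ts, dtype=float))
    if y.ndim != 2 or y.shape[1] != _N:
        raise ValueError("data must be (T, 4)")
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite values")
    return y, (2.0 if tr_seconds is None else tr_seconds)


# ---------------------------------------------------------------------------
# exact-likelihood objective (Kalman)
# ---------------------------------------------------------------------------

def _neg_log_joint(p_full: np.ndarray, y: np.ndarray, tr: float, taps: np.ndarray,
                   prior: PriorSpec, hyper_mu: np.ndarray, hyper_sd: float) -> float:
    theta, log_q, log_r = p_full[:N_PARAMS], p_full[16], p_full[17]
    a = vector_to_matrix(theta)
    lam = np.linalg.eigvals(a)
    max_re = float(np.max(lam.real))
    if max_re > -1e-4:
        return _UNSTABLE_PENALTY * (1.0 + max_re)
    q, r = np.exp(log_q), np.exp(log_r)
    phi, sig_c = _phi_sig_fast(a, tr, q, lam)
    qd = sig_c - phi @ sig_c @ phi.T
    qd = 0.5 * (qd + qd.T)
    p0 = _stationary_aug_cov(phi, sig_c, taps.shape[0])
    ll = kalman_loglik(y, phi, qd, taps, r, p0)
    if not np.isfinite(ll):
        return _UNSTABLE_PENALTY
    logprior = -0.5 * np.sum((theta - prior.mean) ** 2 / prior.variance)
    loghyper = -0.5 * ((log_q - hyper_mu[0]) ** 2 + (log_r - hyper_mu[1]) ** 2) / hyper_sd ** 2
    return -(ll + logprior + loghyper)


# ---------------------------------------------------------------------------
# spectral (Whittle) machinery: model cross-spectrum, derivatives, Fisher
# ---------------------------------------------------------------------------

def _coupling_basis(theta: np.ndarray) -> np.ndarray:
    """dA/dtheta_p for the 16 parameters, stacked (16, 4, 4)."""
    das = np.zeros((N_PARAMS, _N, _N))
    for p in range(12):
        i, j = OFFDIAG_PAIRS[p]
        das[p, i, j] = 1.0
    for s in range(_N):
        das[12 + s, s, s] = -0.5 * np.exp(theta[12 + s])
    return das


def _spectral_model(theta: np.ndarray, log_q: float, log_r: float, t_len: int,
                    tr_seconds: float, taps: np.ndarray, want_derivs: bool = True):
    """Model cross-spectral density S_y(w_j) on the Fourier grid of a
    length-``t_len`` series, and optionally its derivatives with respect to
    the 18 parameters (16 couplings, log q, log r).

    All matrix functions of A (propagator, stationary covariance, their
    Frechet derivatives) are evaluated in A's eigenbasis, which batches the
    16 coupling derivatives into a handful of einsums; the rare
    ill-conditioned eigendecomposition falls back to the dense routines.
    """
    q, r = np.exp(log_q), np.exp(log_r)
    a = vector_to_matrix(theta)
    tr = tr_seconds

    lam, vec = np.linalg.eig(a)
    try:
        vinv = np.linalg.inv(vec)
        well_conditioned = (np.linalg.cond(vec) < 1e8
                            and np.min(np.abs(lam[:, None] + lam[None, :])) > 1e-10
                            )
    except np.linalg.LinAlgError:
        well_conditioned = False

    if well_conditioned:
        mu = np.exp(lam * tr)
        phi = ((vec * mu) @ vinv).real
        # Lyapunov in the eigenbasis: X = V [ (V^-1 C V^-T) o M ] V^T
        m_lyap = -1.0 / (lam[:, None] + lam[None, :])
        c_tilde = vinv @ (q * np.eye(_N)) @ vinv.T
        sig_c = (vec @ (c_tilde * m_lyap) @ vec.T).real
    else:
        phi = sla.expm(a * tr)
        sig_c = sla.solve_lyapunov(a, -q * np.eye(_N))
    qd = sig_c - phi @ sig_c @ phi.T

    m_freq = (t_len - 1) // 2
    omega = 2.0 * np.pi * np.arange(1, m_freq + 1) / t_len
    e = np.exp(-1j * omega)
    eye = np.eye(_N)
    b = np.linalg.inv(eye[None] - phi[None] * e[:, None, None])
    bh = b.conj().transpose(0, 2, 1)
    sx = b @ qd @ bh
    ks = np.arange(taps.shape[0])
    h_tilde = (taps[None, :] * np.exp(-1j * omega[:, None] * ks[None, :])).sum(axis=1)
    g = np.abs(h_tilde) ** 2
    sy = g[:, None, None] * sx + r * eye[None]
    if not want_derivs:
        return sy, None

    das = _coupling_basis(theta)
    if well_conditioned:
        # Frechet derivative of expm: dPhi = V [ (V^-1 dA V) o F ] V^-1
        dl = lam[:, None] - lam[None, :]
        small = np.abs(dl) < 1e-9
        limit = np.broadcast_to((tr * np.exp(lam * tr))[:, None], (_N, _N))
        f_mat = np.where(small, limit,
                         (np.exp(lam * tr)[:, None] - np.exp(lam * tr)[None, :])
                         / np.where(small, 1.0, dl))
        da_tilde = np.einsum("ij,pjk,kl->pil", vinv, das, vec)
        d_phi = np.einsum("ij,pjk,kl->pil", vec, da_tilde * f_mat, vinv).real
        # Lyapunov sensitivity: A dS + dS A' = -(dA S + S dA')
        rhs = np.einsum("pij,jk->pik", das, sig_c)
        rhs = rhs + rhs.transpose(0, 2, 1)
        rhs_tilde = np.einsum("ij,pjk,lk->pil", vinv, rhs, vinv)
        d_sig = np.einsum("ij,pjk,lk->pil", vec, rhs_tilde * m_lyap, vec).real
    else:
        d_phi = np.empty((N_PARAMS, _N, _N))
        d_sig = np.empty((N_PARAMS, _N, _N))
        for p in range(N_PARAMS):
            d_phi[p] = sla.expm_frechet(a * tr, das[p] * tr, compute_expm=False)
            d_sig[p] = sla.solve_lyapunov(a, -(das[p] @ sig_c + sig_c @ das[p].T))

    tmp = np.einsum("pij,jk,lk->pil", d_phi, sig_c, phi)
    d_qd = d_sig - np.einsum("ij,pjk,lk->pil", phi, d_sig, phi) - tmp - tmp.transpose(0, 2, 1)

    # dS_x = (e B dPhi) S_x + S_x (e B dPhi)^H + B dQd B^H, batched over freq
    bd = np.einsum("fij,pjk->pfik", b, d_phi) * e[None, :, None, None]
    d_sx = (np.einsum("pfij,fjk->pfik", bd, sx)
            + np.einsum("fij,pfkj->pfik", sx, bd.conj())
            + np.einsum("fij,pjk,flk->pfil", b, d_qd, b.conj()))
    n_par = N_PARAMS + 2
    d_sy = np.empty((n_par, m_freq, _N, _N), dtype=complex)
    d_sy[:N_PARAMS] = g[None, :, None, None] * d_sx
    d_sy[N_PARAMS] = g[:, None, None] * sx        # d/d log q (S_x linear in q)
    d_sy[N_PARAMS + 1] = r * eye[None]            # d/d log r
    return sy, d_sy


def periodogram(y: np.ndarray) -> np.ndarray:
    """Cross-periodogram matrices I(w_j), j = 1..(T-1)//2, normalized so
    that E[I] approximates the model spectral density used here."""
    t_len = y.shape[0]
    m_freq = (t_len - 1) // 2
    fy = np.fft.fft(y - y.mean(axis=0), axis=0)[1:m_freq + 1]
    return np.einsum("fi,fj->fij", fy, fy.conj()) / t_len


def _whittle_neg_map(p_full: np.ndarray, pgram: np.ndarray, t_len: int, tr: float,
                     taps: np.ndarray, prior: PriorSpec, hyper_mu: np.ndarray,
                     hyper_sd: float) -> tuple[float, np.ndarray]:
    """Whittle approximation to the negative log-joint, with its analytic
    gradient; used only to initialize the exact-likelihood polish."""
    theta, log_q, log_r = p_full[:N_PARAMS], p_full[16], p_full[17]
    a = vector_to_matrix(theta)
    max_re = float(np.max(np.linalg.eigvals(a).real))
    if max_re > -1e-4:
        return _UNSTABLE_PENALTY * (1.0 + max_re), np.zeros_like(p_full)
    sy, d_sy = _spectral_model(theta, log_q, log_r, t_len, tr, taps)
    sy_inv = np.linalg.inv(sy)
    sign, logdet = np.linalg.slogdet(sy)
    quad = np.einsum("fij,fji->f", sy_inv, pgram).real
    ll = -float(np.sum(logdet.real + quad))
    w = np.einsum("fij,pfjk->pfik", sy_inv, d_sy)
    # d/dp [logdet S + tr(S^-1 I)] = tr(S^-1 dS) - tr(S^-1 dS S^-1 I)
    term1 = np.einsum("pfii->p", w).real
    term2 = np.einsum("pfik,fkj,fji->p", w, sy_inv, pgram).real
    d_ll = -(term1 - term2)
    logprior = -0.5 * np.sum((theta - prior.mean) ** 2 / prior.variance)
    loghyper = -0.5 * ((log_q - hyper_mu[0]) ** 2 + (log_r - hyper_mu[1]) ** 2) / hyper_sd ** 2
    grad = np.empty_like(p_full)
    grad[:N_PARAMS] = -d_ll[:N_PARAMS] + (theta - prior.mean) / prior.variance
    grad[16] = -d_ll[16] + (log_q - hyper_mu[0]) / hyper_sd ** 2
    grad[17] = -d_ll[17] + (log_r - hyper_mu[1]) / hyper_sd ** 2
    return -(ll + logprior + loghyper), grad


def whittle_fisher(theta: np.ndarray, log_q: float, log_r: float, t_len: int,
                   tr_seconds: float, taps: np.ndarray) -> np.ndarray:
    """Spectral Fisher information over the 18 parameters; asymptotically
    the expected negative Hessian of the exact Gaussian log-likelihood."""
    sy, d_sy = _spectral_model(theta, log_q, log_r, t_len, tr_seconds, taps)
    sy_inv = np.linalg.inv(sy)
    w = np.einsum("fij,pfjk->pfik", sy_inv, d_sy)
    fisher = np.einsum("pfij,qfji->pq", w, w).real
    return 0.5 * (fisher + fisher.T)


def _hyper_init(y: np.ndarray, tr: float, theta0: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Split the observed variance into a filtered-signal and a noise part
    to start the noise hyperparameters in the right decade."""
    var_y = float(np.mean(np.var(y, axis=0)))
    a = vector_to_matrix(theta0)
    sig_c = sla.solve_lyapunov(a, -np.eye(_N))
    phi = sla.expm(a * tr)
    l_taps = taps.shape[0]
    gam = [sig_c]
    for _ in range(l_taps - 1):
        gam.append(phi @ gam[-1])
    sig_var = 0.0
    for k in range(l_taps):
        for l in range(l_taps):
            d = k - l
            g = gam[d] if d >= 0 else gam[-d].T
            sig_var += taps[k] * taps[l] * np.trace(g) / _N
    sig_var = max(sig_var, 1e-6)
    q0 = max(0.85 * var_y / sig_var, 1e-3)
    r0 = max(0.15 * var_y, 1e-4)
    return np.array([np.log(q0), np.log(r0)])


def _spd_project(mat: np.ndarray, floor_scale: float = 1e-8) -> tuple[np.ndarray, float]:
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    floor = floor_scale * max(np.trace(sym), 1e-6) / mat.shape[0]
    adjusted = float(np.sum(vals < floor))
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, adjusted


_BOUNDS = [(-1.5, 1.5)] * 12 + [(-3.0, 2.0)] * 4 + [(-6.0, 6.0), (-12.0, 4.0)]


def invert_subject(roi_ts: RoiTimeSeries | np.ndarray,
                   prior: PriorSpec | None = None,
                   opts: InvertOptions | None = None,
                   tr_seconds: float | None = None,
                   hrf_params: HrfParams = HrfParams()) -> SubjectPosterior:
    """Maximum-a-posteriori fit with a Laplace posterior over the couplings.

    Stage 1 maximizes the Whittle (spectral) approximation of the log-joint
    with analytic gradients from the prior mean; stage 2 polishes with
    quasi-Newton ascent on the exact Kalman log-likelihood plus log-prior.
    The posterior covariance is the inverse of (spectral Fisher + prior
    precision), marginalized over the noise hyperparameters and floored to
    symmetric positive definite.
    """
    prior = prior or PriorSpec()
    opts = opts or InvertOptions()
    y, tr = _extract_data(roi_ts, tr_seconds)
    if isinstance(roi_ts, RoiTimeSeries) and not roi_ts.provenance:
        import warnings
        warnings.warn("RoiTimeSeries has no preprocessing provenance", stacklevel=2)
    if y.shape[0] < 8:
        raise ValueError("series too short to fit")
    taps = fir_taps(tr, opts.n_taps, hrf_params)
    pgram = periodogram(y)
    hyper0 = _hyper_init(y, tr, prior.mean, taps)

    rng = np.random.default_rng(opts.seed)
    starts = [np.concatenate([prior.mean, hyper0])]
    for _ in range(max(0, opts.n_starts - 1)):
        starts.append(np.concatenate(
            [prior.mean + 0.05 * rng.standard_normal(N_PARAMS), hyper0]))

    exact_args = (y, tr, taps, prior, hyper0, opts.hyper_log_sd)
    spec_args = (pgram, y.shape[0], tr, taps, prior, hyper0, opts.hyper_log_sd)
    best = None
    total_nfev = 0
    for p_init in starts:
        res_w = optimize.minimize(
            _whittle_neg_map, p_init, args=spec_args, method="L-BFGS-B", jac=True,
            bounds=_BOUNDS, options={"maxiter": opts.spectral_max_iter, "ftol": 1e-10},
        )
        res = optimize.minimize(
            _neg_log_joint, res_w.x, args=exact_args, method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"maxiter": opts.max_iter, "ftol": opts.ftol,
                     "gtol": opts.gtol, "eps": opts.fd_step},
        )
        total_nfev += res_w.nfev + res.nfev
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x[:N_PARAMS]
    log_q, log_r = best.x[16], best.x[17]

    fisher = whittle_fisher(theta_hat, log_q, log_r, y.shape[0], tr, taps)
    precision = fisher.copy()
    precision[:N_PARAMS, :N_PARAMS] += np.diag(1.0 / prior.variance)
    precision[16, 16] += 1.0 / opts.hyper_log_sd ** 2
    precision[17, 17] += 1.0 / opts.hyper_log_sd ** 2
    prec_spd, _ = _spd_project(precision)
    cov_full = np.linalg.inv(prec_spd)
    cov_theta, n_floored = _spd_project(cov_full[:N_PARAMS, :N_PARAMS])

    # split the optimum into its likelihood / prior / hyperprior parts:
    # -neg_log_joint = loglik + quadratic prior term + quadratic hyperprior term
    neg = float(best.fun)
    prior_quad = -0.5 * float(np.sum((theta_hat - prior.mean) ** 2 / prior.variance))
    loghyper = -0.5 * ((log_q - hyper0[0]) ** 2
                       + (log_r - hyper0[1]) ** 2) / opts.hyper_log_sd ** 2
    ll_only = -neg - prior_quad - loghyper
    logprior = prior_quad - 0.5 * float(np.sum(np.log(2.0 * np.pi * prior.variance)))
    _, logdet_cov = np.linalg.slogdet(cov_theta)
    # Laplace evidence over the 16 couplings (noise hypers as point estimates)
    free_energy = float(
        ll_only + logprior + 0.5 * N_PARAMS * np.log(2.0 * np.pi) + 0.5 * logdet_cov
    )
    diagnostics = {
        "iterations": int(best.nit),
        "converged": bool(best.success),
        "n_function_evals": int(total_nfev),
        "innovation_variance": float(np.exp(log_q)),
        "noise_variance": float(np.exp(log_r)),
        "neg_log_joint": neg,
        "log_likelihood": float(ll_only),
        "n_cov_eigenvalues_floored": float(n_floored),
        "prior": {"mean": prior.mean.tolist(), "variance": prior.variance.tolist()},
        "n_starts": int(opts.n_starts),
    }
    return SubjectPosterior(
        mean=ParamVector(theta_hat.copy()),
        covariance=cov_theta,
        free_energy=free_energy,
        fit_diagnostics=diagnostics,
    )
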