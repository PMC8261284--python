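"""Numba kernels: Kalman filter/smoother for the HRF-augmented state space.

The latent state is the stack of the last L neural states,
``z_t = [x_t, x_{t-1}, ..., x_{t-L+1}]`` (L = number of FIR taps, state
dimension 4L).  The transition applies the 4x4 discrete propagator to the
leading block and shifts the rest; the observation is the tap-weighted sum
of the lag blocks plus isotropic white noise.

The covariance recursion is data independent, so once the predicted
covariance converges (steady-state Kalman gain) the gain, innovation
covariance and its log-determinant are frozen; the convergence tolerance is
tight enough (1e-12 relative) that the result is numerically
indistinguishable from the full recursion.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from numba.core.errors import NumbaPerformanceWarning

# slice views are typed as non-contiguous at compile time even though the
# arrays are contiguous at run time; the advisory warning is spurious here
warnings.simplefilter("ignore", category=NumbaPerformanceWarning)

LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=False)
def kalman_loglik(y, phi, qd, taps, r, p0):  # pragma: no cover - numba
    """Exact Gaussian log-likelihood of (T,4) data under the model."""
    t_len, n = y.shape
    l_taps = taps.shape[0]
    nz = n * l_taps
    m = np.zeros(nz)
    p = p0.copy()
    p_prev = np.zeros((nz, nz))
    frozen = False
    k_gain = np.zeros((nz, n))
    s_inv = np.zeros((n, n))
    logdet_s = 0.0
    ll = 0.0
    for t in range(t_len):
        if not frozen:
            # innovation covariance from the tap-weighted covariance columns
            c = np.zeros((nz, n))
            for k in range(l_taps):
                w = taps[k]
                if w != 0.0:
                    c += w * p[:, n * k:n * k + n]
            s = np.zeros((n, n))
            for k in range(l_taps):
                w = taps[k]
                if w != 0.0:
                    s += w * c[n * k:n * k + n, :]
            for i in range(n):
                s[i, i] += r
            s = 0.5 * (s + s.T)
            chol = np.linalg.cholesky(s)
            logdet_s = 0.0
            for i in range(n):
                logdet_s += 2.0 * np.log(chol[i, i])
            s_inv = np.linalg.inv(s)
            k_gain = c @ s_inv
            p = p - k_gain @ c.T
            p = 0.5 * (p + p.T)
        # innovation
        v = y[t].copy()
        for k in range(l_taps):
            w = taps[k]
            if w != 0.0:
                v -= w * m[n * k:n * k + n]
        ll -= 0.5 * (n * LOG2PI + logdet_s + v @ s_inv @ v)
        m = m + k_gain @ v
        if t < t_len - 1:
            # predict mean: shift lags, propagate the leading block
            m_new = np.empty(nz)
            m_new[n:] = m[:nz - n]
            m_new[:n] = phi @ m[:n]
            m = m_new
            if not frozen:
                p_new = np.empty((nz, nz))
                p_new[n:, n:] = p[:nz - n, :nz - n]
                top = phi @ p[:n, :]
                p_new[:n, n:] = top[:, :nz - n]
                p_new[n:, :n] = p_new[:n, n:].T
                p_new[:n, :n] = phi @ p[:n, :n] @ phi.T + qd
                scale = 1.0 + np.max(np.abs(p_new))
                if np.max(np.abs(p_new - p_prev)) < 1e-10 * scale:
                    frozen = True
                p_prev = p_new.copy()
                p = p_new
    return ll


@njit(cache=False)
def kalman_filter_store(y, phi, qd, taps, r, p0):  # pragma: no cover - numba
    """Filter pass storing predicted/filtered moments (for smoothing)."""
    t_len, n = y.shape
    l_taps = taps.shape[0]
    nz = n * l_taps
    m_pred = np.zeros((t_len, nz))
    p_pred = np.zeros((t_len, nz, nz))
    m_filt = np.zeros((t_len, nz))
    p_filt = np.zeros((t_len, nz, nz))
    m = np.zeros(nz)
    p = p0.copy()
    ll = 0.0
    for t in range(t_len):
        m_pred[t] = m
        p_pred[t] = p
        c = np.zeros((nz, n))
        for k in range(l_taps):
            w = taps[k]
            if w != 0.0:
                c += w * p[:, n * k:n * k + n]
        s = np.zeros((n, n))
        for k in range(l_taps):
            w = taps[k]
            if w != 0.0:
                s += w * c[n * k:n * k + n, :]
        for i in range(n):
            s[i, i] += r
        s = 0.5 * (s + s.T)
        chol = np.linalg.cholesky(s)
        logdet_s = 0.0
        for i in range(n):
            logdet_s += 2.0 * np.log(chol[i, i])
        s_inv = np.linalg.inv(s)
        v = y[t].copy()
        for k in range(l_taps):
            w = taps[k]
            if w != 0.0:
                v -= w * m[n * k:n * k + n]
        ll -= 0.5 * (n * LOG2PI + logdet_s + v @ s_inv @ v)
        k_gain = c @ s_inv
        m = m + k_gain @ v
        p = p - k_gain @ c.T
        p = 0.5 * (p + p.T)
        m_filt[t] = m
        p_filt[t] = p
        if t < t_len - 1:
            m_new = np.empty(nz)
            m_new[n:] = m[:nz - n]
            m_new[:n] = phi @ m[:n]
            m = m_new
            p_new = np.empty((nz, nz))
            p_new[n:, n:] = p[:nz - n, :nz - n]
            top = phi @ p[:n, :]
            p_new[:n, n:] = top[:, :nz - n]
            p_new[n:, :n] = p_new[:n, n:].T
            p_new[:n, :n] = phi @ p[:n, :n] @ phi.T + qd
            p = 0.5 * (p_new + p_new.T)
    return ll, m_pred, p_pred, m_filt, p_filt


@njit(cache=False)
def rts_smoother(phi, m_pred, p_pred, m_filt, p_filt):  # pragma: no cover
    """Rauch-Tung-Striebel pass; returns smoothed means and covariances of
    the augmented state."""
    t_len, nz = m_filt.shape
    n = phi.shape[0]
    m_s = m_filt.copy()
    p_s = p_filt.copy()
    f = np.zeros((nz, nz))
    for i in range(nz - n):
        f[n + i, i] = 1.0
    f[:n, :n] = phi
    for t in range(t_len - 2, -1, -1):
        # J = P_f[t] F' inv(P_pred[t+1]), via solve on the symmetric predicted cov
        pf_ft = p_filt[t] @ f.T
        j_gain = np.linalg.solve(p_pred[t + 1] + 1e-12 * np.eye(nz), pf_ft.T).T
        m_s[t] = m_filt[t] + j_gain @ (m_s[t + 1] - m_pred[t + 1])
        p_s[t] = p_filt[t] + j_gain @ (p_s[t + 1] - p_pred[t + 1]) @ j_gain.T
        p_s[t] = 0.5 * (p_s[t] + p_s[t].T)
    return m_s, p_s
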