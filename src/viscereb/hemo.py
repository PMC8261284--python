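"""Canonical hemodynamic response kernel and its FIR discretization.

A double-gamma kernel: a positive lobe peaking at ``peak`` seconds minus an
undershoot lobe peaking at ``undershoot`` seconds scaled by ``1/ratio``.
Gamma densities are parameterized so the lobe modes sit exactly at the
requested delays (shape = delay/dispersion + 1, scale = dispersion).

The FIR taps used by the state-space observation model integrate the kernel
over TR-wide bins (via the regularized incomplete gamma function), so the
taps sum to the analytic kernel integral exactly rather than to a Riemann
approximation of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class HrfParams:
    peak: float = 6.0          # s, mode of the positive lobe
    undershoot: float = 16.0   # s, mode of the undershoot lobe
    ratio: float = 6.0         # peak:undershoot amplitude ratio
    dispersion: float = 1.0    # s, scale of the positive lobe
    u_dispersion: float = 1.0  # s, scale of the undershoot lobe
    length: float = 32.0       # s, kernel support


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp(
        (shape - 1.0) * np.log(tp) - tp - special.gammaln(shape)
    ) / scale
    return out


def hrf(t: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Evaluate the kernel at times ``t`` (seconds)."""
    p = params
    a1 = p.peak / p.dispersion + 1.0
    a2 = p.undershoot / p.u_dispersion + 1.0
    h = _gamma_pdf(t, a1, p.dispersion) - _gamma_pdf(t, a2, p.u_dispersion) / p.ratio
    return np.where(np.asarray(t) > p.length, 0.0, h)


def _gamma_cdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return special.gammainc(shape, np.clip(t, 0.0, None) / scale)


def kernel_integral(params: HrfParams = HrfParams()) -> float:
    """Analytic integral of the kernel over its support [0, length]."""
    p = params
    a1 = p.peak / p.dispersion + 1.0
    a2 = p.undershoot / p.u_dispersion + 1.0
    return float(
        _gamma_cdf(np.array(p.length), a1, p.dispersion)
        - _gamma_cdf(np.array(p.length), a2, p.u_dispersion) / p.ratio
    )


def fir_taps(tr_seconds: float = 2.0, n_taps: int = 16,
             params: HrfParams = HrfParams()) -> np.ndarray:
    """Bin-integrated FIR weights: tap k = integral of the kernel over
    [k*TR, (k+1)*TR].  With the defaults (TR = 2 s, 16 taps) the taps cover
    the full 32-s support and sum to :func:`kernel_integral` exactly.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    p = params
    a1 = p.peak / p.dispersion + 1.0
    a2 = p.undershoot / p.u_dispersion + 1.0
    edges = np.arange(n_taps + 1) * tr_seconds
    edges = np.clip(edges, 0.0, p.length)
    c1 = _gamma_cdf(edges, a1, p.dispersion)
    c2 = _gamma_cdf(edges, a2, p.u_dispersion)
    return np.diff(c1) - np.diff(c2) / p.ratio
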