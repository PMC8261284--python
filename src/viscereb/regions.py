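"""Region labels and the fixed 16-parameter index map for the coupling matrix.

The network has four regions in fixed order: primary visual cortex (PV),
left and right secondary visual cortex (SV_L, SV_R) and cerebellum (C).
The directed coupling matrix ``A`` (units 1/s) uses the convention
``A[i, j]`` = influence of region ``j`` on region ``i``.  The 16 free
parameters are vectorized as the 12 off-diagonal entries in row-major
(to-region major) order followed by the 4 self log-scalings, where the
realized self-rate is ``a_ii = -0.5 * exp(self_log_i)`` so that every
self-connection is negative by construction.
"""

from __future__ import annotations

import numpy as np

REGIONS: tuple[str, ...] = ("PV", "SV_L", "SV_R", "C")
N_REGIONS = 4

#: (to, from) index pairs of the off-diagonal couplings, to-region major.
OFFDIAG_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(N_REGIONS) for j in range(N_REGIONS) if i != j
)

#: Canonical parameter names: "SRC->DST" for couplings, "self_R" for the
#: log-scaling of region R's self-connection.
PARAM_NAMES: tuple[str, ...] = tuple(
    f"{REGIONS[j]}->{REGIONS[i]}" for (i, j) in OFFDIAG_PAIRS
) + tuple(f"self_{r}" for r in REGIONS)

N_PARAMS = len(PARAM_NAMES)  # 16

#: name -> position in the 16-vector (bijection, shared across the package)
PARAM_INDEX: dict[str, int] = {name: k for k, name in enumerate(PARAM_NAMES)}


def canonical_name(name: str) -> str:
    """Normalize a parameter name (accepts the unicode arrow)."""
    key = name.strip().replace("→", "->").replace(" ", "")
    if key not in PARAM_INDEX:
        raise KeyError(f"unknown parameter name: {name!r}; known: {PARAM_NAMES}")
    return key


def param_index(name: str) -> int:
    return PARAM_INDEX[canonical_name(name)]


def vector_to_matrix(theta: np.ndarray) -> np.ndarray:
    """Realize the 4x4 coupling matrix A from the 16-vector.

    Off-diagonals are taken as-is (1/s); the diagonal is
    ``-0.5 * exp(theta_self)`` which is always negative.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_PARAMS,):
        raise ValueError(f"expected a length-{N_PARAMS} parameter vector")
    a = np.zeros((N_REGIONS, N_REGIONS))
    for k, (i, j) in enumerate(OFFDIAG_PAIRS):
        a[i, j] = theta[k]
    a[np.diag_indices(N_REGIONS)] = -0.5 * np.exp(theta[12:16])
    return a


def matrix_to_vector(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vector_to_matrix` (requires a negative diagonal)."""
    a = np.asarray(a, dtype=float)
    if a.shape != (N_REGIONS, N_REGIONS):
        raise ValueError("expected a 4x4 matrix")
    d = np.diag(a)
    if np.any(d >= 0):
        raise ValueError("diagonal of A must be negative to map to self_log")
    theta = np.empty(N_PARAMS)
    for k, (i, j) in enumerate(OFFDIAG_PAIRS):
        theta[k] = a[i, j]
    theta[12:16] = np.log(-d / 0.5)
    return theta


def is_stable(a: np.ndarray, margin: float = 0.0) -> bool:
    """True when all eigenvalues of A have real part < -margin."""
    return bool(np.max(np.linalg.eigvals(a).real) < -margin)
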