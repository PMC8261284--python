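"""Multivariate prediction of clinical scores from coupling patterns.

Linear-kernel epsilon-support-vector regression over the 16 coupling
features with within-training-fold feature selection: in each
leave-one-out fold the model is first trained on all features, features
are ranked by |weight| and the top fraction retained, a new model is
trained on the retained set and evaluated on the held-out subject.  The
fraction sweeps 5%..100% in 5% steps (20 models); each fraction's skill is
the Pearson correlation between held-out predictions and true labels.

Significance uses the maximal-statistic permutation scheme: labels are
shuffled once per permutation, the full 20-fraction grid is re-run, and
the maximum |r| across fractions enters the null distribution, so the
per-fraction p-values ``(1 + #{null >= r_obs}) / (n_perm + 1)`` are
family-wise-error corrected by construction.

SVR hyperparameters are pinned (linear kernel, C = 1, epsilon = 0.1, the
conventional defaults) so results do not drift with library versions;
feature counts use k = max(1, round(fraction * 16)) with banker's
rounding, features are z-scored with training-fold statistics only, and
ties in |weight| break toward the lower feature index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._svr import (
    grid_correlations,
    loocv_grid_core,
    permutation_max_null,
    svr_dual_solve,
)
from .regions import PARAM_NAMES

SVR_C = 1.0
SVR_EPSILON = 0.1
# Solver budgets: the LOOCV/permutation grids run the SMO with a fixed,
# deterministic update budget (identical for observed and shuffled labels,
# so the permutation test stays exchangeable); the single-fit API solves to
# tight KKT tolerance for exactness.
_GRID_TOL = 1e-5
_GRID_SWEEPS = 100
_EXACT_TOL = 1e-8
_EXACT_SWEEPS = 2000

#: the 20 retained-feature fractions, 5% .. 100%
FRACTIONS: np.ndarray = np.round(np.arange(1, 21) * 0.05, 2)


def feature_counts(n_features: int, fractions: np.ndarray = FRACTIONS) -> np.ndarray:
    """k = max(1, round(fraction * p)) with round-half-to-even."""
    return np.maximum(1, np.rint(fractions * n_features)).astype(np.int64)


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels (the clinical score)."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=float))
        self.labels = np.ascontiguousarray(np.asarray(self.labels, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be subjects x features")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must align with matrix columns")
        if self.labels.shape != (self.matrix.shape[0],):
            raise ValueError("labels must have one entry per subject")
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.labels))):
            raise ValueError("missing/non-finite values in feature table")


@dataclass
class MvpaResult:
    fractions: np.ndarray
    r_per_fraction: np.ndarray
    null_max_abs_r: np.ndarray
    p_fwe_per_fraction: np.ndarray
    best_fraction: float
    selected_features_final: tuple[str, ...]
    sensitivity_map: dict[str, float]
    n_perm: int
    seed: int | None = None
    fold_records: dict = field(default_factory=dict)

    @property
    def best_r(self) -> float:
        i = int(np.argmin(self.p_fwe_per_fraction))
        return float(self.r_per_fraction[i])

    @property
    def min_p_fwe(self) -> float:
        return float(np.min(self.p_fwe_per_fraction))


def svr_fold(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
             fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One train/select/refit/predict step at a single feature fraction.

    Returns (predictions on test_x, selected feature indices, signed
    weights of the refit model embedded in full feature space).  With
    fraction = 1.0 the selection is the identity and the prediction equals
    the plain no-selection SVR prediction.
    """
    train_x = np.ascontiguousarray(np.asarray(train_x, float))
    train_y = np.ascontiguousarray(np.asarray(train_y, float))
    test_x = np.atleast_2d(np.asarray(test_x, float))
    n, p = train_x.shape
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if n < 2:
        raise ValueError("need at least 2 training rows")
    if np.ptp(train_y) == 0:
        raise ValueError("constant training labels")
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    xs = (train_x - mu) / sd
    xt = (test_x - mu) / sd

    beta = np.zeros(n)
    svr_dual_solve(xs @ xs.T, train_y, SVR_C, SVR_EPSILON, beta, _EXACT_TOL, _EXACT_SWEEPS)
    w_full = xs.T @ beta
    order = np.array(sorted(range(p), key=lambda j: (-abs(w_full[j]), j)))
    k = int(max(1, np.rint(fraction * p)))
    sel = order[:k]

    xsel = np.ascontiguousarray(xs[:, sel])
    beta2 = np.zeros(n)
    b = svr_dual_solve(xsel @ xsel.T, train_y, SVR_C, SVR_EPSILON, beta2,
                       _EXACT_TOL, _EXACT_SWEEPS)
    w_sel = xsel.T @ beta2
    weights = np.zeros(p)
    weights[sel] = w_sel
    preds = xt[:, sel] @ w_sel + b
    return preds, sel, weights


def loocv_grid(table: FeatureTable, fractions: np.ndarray = FRACTIONS,
               ) -> tuple[np.ndarray, dict]:
    """Per-fraction LOOCV correlation between held-out predictions and
    labels; feature ranking and selection happen inside every training
    fold (no leakage).  Also returns per-fold predictions and weights."""
    n = table.matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    ks = feature_counts(table.matrix.shape[1], fractions)
    preds, weights = loocv_grid_core(
        table.matrix, table.labels, ks, SVR_C, SVR_EPSILON, _GRID_TOL, _GRID_SWEEPS, True
    )
    rs = np.array([_safe_pearson(preds[f], table.labels) for f in range(len(ks))])
    records = {"predictions": preds, "weights": weights, "feature_counts": ks}
    return rs, records


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def permutation_fwe(table: FeatureTable, n_perm: int = 1000,
                    seed: int | None = None,
                    fractions: np.ndarray = FRACTIONS) -> MvpaResult:
    """Observed per-fraction correlations plus the max-statistic
    permutation null and FWE-corrected p-values.

    Labels are shuffled once per permutation and shared across all 20
    fraction models, so the maximum-|r| null is valid for the whole model
    family; ``p_fwe = (1 + #{null >= r_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rs, records = loocv_grid(table, fractions)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(table.labels) for _ in range(n_perm)])
    ks = records["feature_counts"]
    null = permutation_max_null(table.matrix, perms, ks, SVR_C, SVR_EPSILON,
                                _GRID_TOL, _GRID_SWEEPS)
    p_fwe = np.array([(1.0 + np.sum(null >= r)) / (n_perm + 1.0) for r in rs])

    best_i = int(np.argmin(p_fwe))
    ties = np.flatnonzero(p_fwe == p_fwe[best_i])
    best_i = int(ties.min())  # sparsest model wins ties
    sens = sensitivity_map(records["weights"][best_i], table.feature_names)
    sel_final = tuple(nm for nm in table.feature_names
                      if abs(sens[nm]) > 0 or _always_selected(records, best_i, nm, table))
    return MvpaResult(
        fractions=np.asarray(fractions, float),
        r_per_fraction=rs,
        null_max_abs_r=null,
        p_fwe_per_fraction=p_fwe,
        best_fraction=float(fractions[best_i]),
        selected_features_final=sel_final,
        sensitivity_map=sens,
        n_perm=int(n_perm),
        seed=seed,
        fold_records=records,
    )


def _always_selected(records, best_i, name, table) -> bool:
    j = table.feature_names.index(name)
    w = records["weights"][best_i][:, j]
    return bool(np.all(w != 0.0))


def sensitivity_map(fold_weights: np.ndarray,
                    feature_names: tuple[str, ...] = PARAM_NAMES) -> dict[str, float]:
    """Mean signed weight per feature across folds; a feature not selected
    in a fold contributes weight 0 there."""
    fold_weights = np.asarray(fold_weights, float)
    if fold_weights.ndim != 2 or fold_weights.shape[1] != len(feature_names):
        raise ValueError("fold_weights must be folds x features")
    mean_w = fold_weights.mean(axis=0)
    return {nm: float(w) for nm, w in zip(feature_names, mean_w)}
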