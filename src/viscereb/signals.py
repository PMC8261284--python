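"""Temporal preprocessing of voxel/ROI BOLD series and ROI summary extraction.

The processing chain mirrors a standard resting-state recipe: discard the
first volumes, remove a per-channel linear trend, low-/band-pass to the
0-0.08 Hz band, regress out nine nuisance covariates (six motion-like
series, global, white-matter and CSF signals), then summarize each region
of interest by the first eigenvariate of its voxel block.  All operations
act on arrays with time along axis 0.

Nuisance regressors are themselves detrended and filtered with the same
settings before the regression so that the residual cannot re-acquire
frequencies outside the pass band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .regions import REGIONS

NUISANCE_COLUMNS: tuple[str, ...] = (
    "motion1", "motion2", "motion3", "motion4", "motion5", "motion6",
    "global", "wm", "csf",
)


@dataclass
class VoxelBlock:
    """All voxels of one ROI: ``data`` is (n_voxels, n_time)."""

    roi_label: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("VoxelBlock.data must be (n_voxels, n_time) with >=1 voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VoxelBlock.data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceMatrix:
    """Nine nuisance covariates, time along axis 0, fixed column order."""

    data: np.ndarray
    column_names: tuple[str, ...] = NUISANCE_COLUMNS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(NUISANCE_COLUMNS):
            raise ValueError("NuisanceMatrix.data must be (n_time, 9)")
        if tuple(self.column_names) != NUISANCE_COLUMNS:
            raise ValueError(f"nuisance columns must be {NUISANCE_COLUMNS}")


@dataclass
class RoiTimeSeries:
    """ROI summary time courses: ``data`` is (n_time, 4), columns in
    region order (PV, SV_L, SV_R, C)."""

    data: np.ndarray
    tr_seconds: float = 2.0
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(REGIONS):
            raise ValueError("RoiTimeSeries.data must be (n_time, 4)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RoiTimeSeries.data contains non-finite values")

    @property
    def n_time(self) -> int:
        return self.data.shape[0]


def _as_2d(series: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    if x.ndim == 2:
        return x, False
    raise ValueError("series must be 1-D or (time, channels)")


def drop_initial(series: np.ndarray, n_drop: int) -> np.ndarray:
    """Remove the first ``n_drop`` samples from every channel."""
    x, squeeze = _as_2d(series)
    if not 0 <= n_drop < x.shape[0]:
        raise ValueError(f"n_drop must satisfy 0 <= n_drop < {x.shape[0]}, got {n_drop}")
    out = x[n_drop:].copy()
    return out[:, 0] if squeeze else out


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the per-channel least-squares line; the residual is orthogonal
    to both the intercept and the linear ramp."""
    x, squeeze = _as_2d(series)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to detrend")
    out = sps.detrend(x, axis=0, type="linear")
    return out[:, 0] if squeeze else out


def bandpass(series: np.ndarray, low_hz: float = 0.0, high_hz: float = 0.08,
             tr_seconds: float = 2.0, order: int = 4) -> np.ndarray:
    """Zero-phase forward-backward Butterworth filter.

    A band starting at 0 Hz is realized as a low-pass at ``high_hz`` (DC and
    drift are handled by detrending).  ``high_hz`` must not exceed the
    Nyquist frequency 1/(2 TR).
    """
    x, squeeze = _as_2d(series)
    nyq = 0.5 / tr_seconds
    if not 0.0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyq:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyq}")
    fs = 1.0 / tr_seconds
    if low_hz <= 0.0:
        sos = sps.butter(order, high_hz, btype="low", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, x, axis=0)
    return out[:, 0] if squeeze else np.ascontiguousarray(out)


def regress_nuisance(series: np.ndarray, nuisance: NuisanceMatrix | np.ndarray) -> np.ndarray:
    """Residualize each channel on the nuisance columns plus an intercept."""
    x, squeeze = _as_2d(series)
    nd = nuisance.data if isinstance(nuisance, NuisanceMatrix) else np.asarray(nuisance, float)
    if nd.shape[0] != x.shape[0]:
        raise ValueError(
            f"row mismatch: series has {x.shape[0]} samples, nuisance {nd.shape[0]}"
        )
    design = np.column_stack([np.ones(x.shape[0]), nd])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ("intercept",) + (
            tuple(nuisance.column_names) if isinstance(nuisance, NuisanceMatrix)
            else tuple(f"col{i}" for i in range(nd.shape[1]))
        )
        bad = []
        for j in range(1, design.shape[1]):
            others = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"nuisance design is rank-deficient; offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    out = x - design @ beta
    return out[:, 0] if squeeze else out


def first_eigenvariate(block: VoxelBlock) -> np.ndarray:
    """First principal time course of an ROI voxel block.

    SVD of the temporally demeaned (time x voxel) matrix; the leading left
    singular vector is scaled to unit variance (ddof=1) and its sign chosen
    so it correlates non-negatively with the across-voxel mean time course.
    """
    x = block.data.T.astype(float)  # time x voxel
    if x.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("voxel block has zero temporal variance")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    course = u[:, 0] * s[0]
    mean_course = xc.mean(axis=1)
    if mean_course @ course < 0:
        course = -course
    sd = course.std(ddof=1)
    return course / sd


def tsnr(raw_series: np.ndarray, mode: str = "standard",
         cleaned_series: np.ndarray | None = None,
         residual_series: np.ndarray | None = None) -> float:
    """Temporal signal-to-noise ratio of a single time course.

    ``standard``: temporal mean / temporal SD of the raw series (the
    conventional definition).  ``sd_ratio``: SD(cleaned) / SD(residual),
    the ratio of signal SD to noise SD given a decomposition of the raw
    series into a cleaned component and a residual.
    """
    raw = np.asarray(raw_series, dtype=float)
    if mode == "standard":
        sd = raw.std(ddof=1)
        if sd <= 0:
            raise ValueError("zero temporal variance in raw series")
        return float(raw.mean() / sd)
    if mode == "sd_ratio":
        if cleaned_series is None or residual_series is None:
            raise ValueError("mode='sd_ratio' requires cleaned_series and residual_series")
        sd_noise = np.asarray(residual_series, float).std(ddof=1)
        if sd_noise <= 0:
            raise ValueError("zero-variance residual (degenerate noise estimate)")
        return float(np.asarray(cleaned_series, float).std(ddof=1) / sd_noise)
    raise ValueError("mode must be 'standard' or 'sd_ratio'")


def tsnr_group_test(tsnr_a: np.ndarray, tsnr_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two groups of tSNR
    values; returns (t, p)."""
    res = stats.ttest_ind(np.asarray(tsnr_a, float), np.asarray(tsnr_b, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)


def smooth_spatial(blocks: dict[str, VoxelBlock], fwhm_mm: float | None = None
                   ) -> dict[str, VoxelBlock]:
    """Spatial-smoothing hook.

    Synthetic voxel blocks carry no spatial geometry, so this is a
    pass-through; real-data users smoothing on a voxel grid should do so
    upstream (at the volume stage) and can override this hook.
    """
    if fwhm_mm not in (None, 0, 0.0):
        raise NotImplementedError(
            "voxel blocks carry no spatial geometry; smooth volumes upstream")
    return blocks


def preprocess_subject(blocks: dict[str, VoxelBlock] | list[VoxelBlock],
                       nuisance: NuisanceMatrix,
                       n_drop: int = 10,
                       band: tuple[float, float] = (0.0, 0.08),
                       tr_seconds: float | None = None) -> RoiTimeSeries:
    """Full voxel-level chain followed by eigenvariate extraction.

    Order: drop initial volumes -> linear detrend -> band-pass -> nuisance
    regression (against regressors given the same drop/detrend/filter) ->
    first eigenvariate per ROI.  Returns a (time x 4) RoiTimeSeries in
    region order with the processing steps recorded in ``provenance``.
    """
    if isinstance(blocks, dict):
        block_map = blocks
    else:
        block_map = {b.roi_label: b for b in blocks}
    missing = [r for r in REGIONS if r not in block_map]
    if missing:
        raise ValueError(f"missing voxel blocks for regions: {missing}")
    tr = tr_seconds if tr_seconds is not None else block_map[REGIONS[0]].tr_seconds

    nuis = drop_initial(nuisance.data, n_drop)
    nuis = detrend_linear(nuis)
    nuis = bandpass(nuis, band[0], band[1], tr)

    columns = []
    for roi in REGIONS:
        blk = block_map[roi]
        if blk.data.shape[1] != nuisance.data.shape[0]:
            raise ValueError(
                f"ROI {roi}: {blk.data.shape[1]} volumes but nuisance has "
                f"{nuisance.data.shape[0]} rows"
            )
        x = blk.data.T  # time x voxel
        x = drop_initial(x, n_drop)
        x = detrend_linear(x)
        x = bandpass(x, band[0], band[1], tr)
        x = regress_nuisance(x, NuisanceMatrix(nuis))
        columns.append(first_eigenvariate(VoxelBlock(roi, x.T, tr)))
    provenance = [
        {"step": "drop_initial", "n_drop": n_drop},
        {"step": "detrend_linear"},
        {"step": "bandpass", "low_hz": band[0], "high_hz": band[1], "order": 4,
         "realization": "zero-phase Butterworth (low-pass when low_hz == 0)"},
        {"step": "regress_nuisance", "columns": list(NUISANCE_COLUMNS),
         "regressors_filtered": True},
        {"step": "first_eigenvariate", "scaling": "unit variance (ddof=1)",
         "sign": "non-negative correlation with voxel-mean course"},
    ]
    return RoiTimeSeries(np.column_stack(columns), tr, provenance)
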