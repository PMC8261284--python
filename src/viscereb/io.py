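"""Readers and writers for the pipeline's on-disk formats.

Synthetic or real data move through plain, inspectable formats: 4D NIfTI
for voxel BOLD (with a 3D integer-label mask naming the four ROIs), TSV
for nuisance regressors and ROI time series, CSV for clinical scores, and
JSON for posteriors, group models and configuration.  Time series round-
trip losslessly at 15 significant digits; every result file can embed the
configuration hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ecfit import ParamVector, SubjectPosterior
from .regions import N_PARAMS, PARAM_NAMES, REGIONS
from .signals import NUISANCE_COLUMNS, NuisanceMatrix, RoiTimeSeries, VoxelBlock

_FLOAT_FMT = "%.15g"

#: ROI name -> integer label used in mask volumes (0 = background)
ROI_LABELS: dict[str, int] = {name: k + 1 for k, name in enumerate(REGIONS)}


# ---------------------------------------------------------------------------
# NIfTI voxel blocks
# ---------------------------------------------------------------------------

def save_bold(path: str | Path, blocks: dict[str, VoxelBlock],
              mask_path: str | Path) -> None:
    """Write one subject's voxel blocks as a single 4D NIfTI (voxels laid
    out along x) plus an integer ROI-label mask volume."""
    order = [blocks[r] for r in REGIONS]
    n_time = order[0].n_time
    total = sum(b.n_voxels for b in order)
    vol = np.zeros((total, 1, 1, n_time))
    mask = np.zeros((total, 1, 1), dtype=np.int16)
    at = 0
    for roi, blk in zip(REGIONS, order):
        vol[at:at + blk.n_voxels, 0, 0, :] = blk.data
        mask[at:at + blk.n_voxels, 0, 0] = ROI_LABELS[roi]
        at += blk.n_voxels
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


def load_bold(path: str | Path, mask_path: str | Path,
              tr_seconds: float = 2.0) -> dict[str, VoxelBlock]:
    """Read a 4D BOLD NIfTI and an integer ROI mask into voxel blocks.

    Mask labels must be exactly the four expected ROI labels (plus 0
    background); any extra label is reported by value.
    """
    img = nib.load(str(path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj)
    if data.shape[:3] != mask.shape[:3]:
        raise ValueError(
            f"BOLD grid {data.shape[:3]} does not match mask grid {mask.shape[:3]}")
    flat = data.reshape(-1, data.shape[3])
    labels = np.rint(mask).astype(int).reshape(-1)
    present = set(np.unique(labels)) - {0}
    expected = set(ROI_LABELS.values())
    extra = sorted(present - expected)
    if extra:
        raise ValueError(f"mask contains unexpected labels {extra}; "
                         f"expected {sorted(expected)} (0 = background)")
    blocks = {}
    for roi, lab in ROI_LABELS.items():
        rows = flat[labels == lab]
        if rows.shape[0] == 0:
            raise ValueError(f"mask has no voxels for ROI {roi} (label {lab})")
        blocks[roi] = VoxelBlock(roi, rows, tr_seconds)
    return blocks


# ---------------------------------------------------------------------------
# TSV / CSV tables
# ---------------------------------------------------------------------------

def save_nuisance(path: str | Path, nuisance: NuisanceMatrix) -> None:
    pd.DataFrame(nuisance.data, columns=list(NUISANCE_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_nuisance(path: str | Path) -> NuisanceMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in NUISANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"nuisance table is missing columns {missing}")
    return NuisanceMatrix(df[list(NUISANCE_COLUMNS)].to_numpy(float))


def save_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=list(REGIONS))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = Path(path).with_suffix(".json")
    meta.write_text(json.dumps(
        {"tr_seconds": ts.tr_seconds, "provenance": ts.provenance}, indent=2))


def load_timeseries(path: str | Path) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGIONS if c not in df.columns]
    if missing:
        raise ValueError(f"time-series table is missing ROI columns {missing}")
    tr, prov = 2.0, []
    meta = Path(path).with_suffix(".json")
    if meta.exists():
        m = json.loads(meta.read_text())
        tr = float(m.get("tr_seconds", 2.0))
        prov = m.get("provenance", [])
    return RoiTimeSeries(df[list(REGIONS)].to_numpy(float), tr, prov)


def save_clinical(path: str | Path, records: list) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_clinical(path: str | Path, logger=None) -> pd.DataFrame:
    """Clinical CSV; recovery columns are recomputed from post - pre when
    absent (with a notice)."""
    df = pd.read_csv(path)
    need = ["bcva_pre_od", "bcva_pre_os", "bcva_post_od", "bcva_post_os"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns {missing}")
    for eye in ("od", "os"):
        col = f"recovery_{eye}"
        if col not in df.columns:
            df[col] = df[f"bcva_post_{eye}"] - df[f"bcva_pre_{eye}"]
            if logger is not None:
                logger.info("computed %s from post - pre", col)
    return df


# ---------------------------------------------------------------------------
# JSON posteriors / results
# ---------------------------------------------------------------------------

def save_posterior(path: str | Path, post: SubjectPosterior) -> None:
    payload = {
        "index_map": list(PARAM_NAMES),
        "mean": post.mean.values.tolist(),
        "covariance": post.covariance.tolist(),
        "free_energy": post.free_energy,
        "fit_diagnostics": post.fit_diagnostics,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_posterior(path: str | Path) -> SubjectPosterior:
    payload = json.loads(Path(path).read_text())
    if tuple(payload["index_map"]) != PARAM_NAMES:
        raise ValueError("posterior file has a different parameter index map")
    mean = np.asarray(payload["mean"], float)
    cov = np.asarray(payload["covariance"], float)
    if mean.shape != (N_PARAMS,) or cov.shape != (N_PARAMS, N_PARAMS):
        raise ValueError("posterior file has malformed mean/covariance")
    return SubjectPosterior(ParamVector(mean), cov,
                            float(payload["free_energy"]),
                            payload.get("fit_diagnostics", {}))


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
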