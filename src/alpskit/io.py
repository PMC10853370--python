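"""File-format adapters: NIfTI volumes, FSL bval/bvec gradient tables,
cohort CSV tables, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme
from .phantom import DWIStudy, GROUPS

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvalbvec",
    "load_bvalbvec",
    "save_dwi_study",
    "load_dwi_study",
    "COHORT_COLUMNS",
    "validate_cohort_table",
    "load_cohort_csv",
    "save_cohort_csv",
    "save_json",
]

# required cohort-table columns; the ALPS triplet is unitless, MDRT in Gy
COHORT_COLUMNS = ("subject_id", "group", "alps_left", "alps_right", "alps_wholebrain")


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def load_nifti(path) -> Tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_bvalbvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """FSL dialect: bvals on one space-separated row; bvecs as 3 rows."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in scheme.bvecs.T:
            f.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def load_bvalbvec(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows, found {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"gradient table mismatch: {bval_path} has {bvals.size} entries "
            f"but {bvec_path} has {bvecs.shape[1]} columns"
        )
    return GradientScheme(bvals=bvals, bvecs=bvecs.T)


def save_dwi_study(study: DWIStudy, out_dir, stem: Optional[str] = None) -> dict:
    """Write one subject: <stem>.nii.gz + <stem>.bval/.bvec + mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or (study.subject_id or "dwi")
    paths = {
        "dwi": out_dir / f"{stem}.nii.gz",
        "bval": out_dir / f"{stem}.bval",
        "bvec": out_dir / f"{stem}.bvec",
        "mask": out_dir / f"{stem}_mask.nii.gz",
    }
    save_nifti(study.signals, study.affine, paths["dwi"])
    save_bvalbvec(study.scheme, paths["bval"], paths["bvec"])
    save_nifti(study.mask.astype(np.uint8), study.affine, paths["mask"])
    return {k: str(v) for k, v in paths.items()}


def load_dwi_study(dwi_path, bval_path, bvec_path, mask_path=None,
                   subject_id: str = "") -> DWIStudy:
    signals, affine = load_nifti(dwi_path)
    scheme = load_bvalbvec(bval_path, bvec_path)
    if signals.shape[-1] != scheme.n:
        raise ValueError(
            f"{dwi_path}: {signals.shape[-1]} volumes but gradient table has {scheme.n}"
        )
    if mask_path is not None:
        mask = load_nifti(mask_path)[0].astype(bool)
    else:
        mask = np.ones(signals.shape[:3], dtype=bool)
    voxel_size = float(np.linalg.norm(affine[:3, 0]))
    return DWIStudy(signals=signals, scheme=scheme, mask=mask,
                    voxel_size=voxel_size, affine=affine, subject_id=subject_id)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = sorted(set(table["group"]) - set(GROUPS))
    if bad:
        raise ValueError(
            f"unknown group labels {bad}; allowed labels are {list(GROUPS)}"
        )
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject ids: {dupes}")
    alps = table[["alps_left", "alps_right", "alps_wholebrain"]].to_numpy(float)
    if np.any(~np.isfinite(alps)) or np.any(alps <= 0):
        raise ValueError("ALPS values must be finite and positive")
    return table


def load_cohort_csv(path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


def save_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def save_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
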