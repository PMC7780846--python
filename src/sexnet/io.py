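"""NIfTI and cohort-table I/O.

Volumes are exchanged as NIfTI with an isotropic-spacing affine (2 mm by
default); tables as CSV.  The cohort reader enforces the required columns
(subject_id, sex, age, pds, ses), drops and counts incomplete rows, and
normalizes the sex coding to girl = 1, boy = 0.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import Atlas, SyntheticCohort

__all__ = [
    "save_volume",
    "load_volume",
    "read_cohort",
    "save_cohort",
    "REQUIRED_COLUMNS",
]

log = logging.getLogger("sexnet")

REQUIRED_COLUMNS = ("subject_id", "sex", "age", "pds", "ses")

_SEX_CODES = {"0": 0, "1": 1, "M": 0, "F": 1, "m": 0, "f": 1, "boy": 0, "girl": 1}


def save_volume(data: np.ndarray, path: str | Path, spacing: float = 2.0) -> Path:
    """Write a volume as NIfTI with an isotropic-spacing diagonal affine."""
    path = Path(path)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, isotropic spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    return data, float(zooms[0])


def _normalize_sex(value) -> int:
    key = str(value).strip()
    if key in _SEX_CODES:
        return _SEX_CODES[key]
    try:
        as_float = float(key)
    except ValueError:
        raise ValueError(f"unrecognized sex code {value!r}; expected 0/1/F/M") from None
    if as_float in (0.0, 1.0):
        return int(as_float)
    raise ValueError(f"unrecognized sex code {value!r}; expected 0/1/F/M")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and type a cohort table; drop (and count) incomplete rows.

    Adds z-scored covariate columns and an integer ``pds_level`` when
    absent.  The drop count is logged and stored in ``df.attrs["n_dropped"]``.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"cohort table {path} is missing required column(s): {missing}")
    n_raw = len(df)
    df = df.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
    n_dropped = n_raw - len(df)
    if n_dropped:
        log.info("dropped %d incomplete row(s) from %s", n_dropped, path)
    df["sex"] = df["sex"].map(_normalize_sex)
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("age", "pds", "ses"):
        df[col] = pd.to_numeric(df[col])
    if not df["pds"].between(1, 5).all():
        raise ValueError("pds values must lie in [1, 5]")
    if "pds_level" not in df.columns:
        df["pds_level"] = np.clip(np.rint(df["pds"]), 1, 5).astype(int)
    for col in ("age", "pds", "ses"):
        zcol = f"z_{col}"
        if zcol not in df.columns:
            x = df[col].to_numpy(dtype=np.float64)
            sd = x.std()
            df[zcol] = (x - x.mean()) / sd if sd > 0 else 0.0
    df.attrs["n_dropped"] = n_dropped
    return df


def save_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort: per-subject NIfTI volumes, atlas, table, truth."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    for sid, vol in zip(cohort.records["subject_id"], cohort.volumes):
        save_volume(vol, outdir / "volumes" / f"{sid}.nii.gz", cohort.spacing)
    save_volume(cohort.atlas.labels, outdir / "atlas.nii.gz", cohort.spacing)
    cohort.records.to_csv(outdir / "cohort.csv", index=False)
    truth = {
        "seed": cohort.seed,
        "effects": [
            {
                "region_label": e.region_label,
                "effect_kind": e.effect_kind,
                "driver": e.driver,
                "magnitude": e.magnitude,
            }
            for e in cohort.truth
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir


def load_volumes(volumes_dir: str | Path, subject_ids: list[str]) -> tuple[np.ndarray, float]:
    """Load one NIfTI per subject id from a directory; returns stacked array."""
    volumes_dir = Path(volumes_dir)
    vols = []
    spacing = 2.0
    for sid in subject_ids:
        candidates = [volumes_dir / f"{sid}.nii.gz", volumes_dir / f"{sid}.nii"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no volume found for subject {sid} in {volumes_dir}")
        data, spacing = load_volume(path)
        vols.append(data)
    return np.stack(vols), spacing


def load_atlas(path: str | Path) -> Atlas:
    """Load an integer-label atlas volume (region geometry unknown for real atlases)."""
    data, spacing = load_volume(path)
    labels = np.rint(data).astype(np.int32)
    regions = {int(lab): ([], 0.0) for lab in np.unique(labels) if lab != 0}
    return Atlas(labels=labels, regions=regions, spacing=spacing)
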