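"""NIfTI label-volume I/O, cohort manifests, and tidy metric tables.

Volumes are reoriented on load to the canonical patient frame (RAS-like:
x left–right, +y anterior, +z superior) so that downstream metrics are
insensitive to the on-disk axis ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import PLANNING, LabelVolume, timepoint_order

MANIFEST_COLUMNS = (
    "patient_id",
    "timepoint",
    "body_path",
    "gas_path",
    "age_years",
    "sex",
    "ga",
    "feeding_tube",
)
#: optional precomputed alignment parameters (moving scan pose offset vs planning)
TRANSFORM_COLUMNS = ("t_x", "t_y", "t_z", "r_x", "r_y", "r_z")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3D NIfTI mask, reorient to canonical axes, binarise at 0.5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: voxel-size metadata absent or invalid: {zooms}")
    img = nib.as_closest_canonical(img)
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-3 * spacing.min()):
        raise ValueError(
            f"{path}: oblique affine not supported; axes must be grid-aligned"
        )
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return LabelVolume(voxels=data >= 0.5, spacing=spacing, origin=affine[:3, 3])


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), affine)
    img.header.set_zooms(vol.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def _parse_bool(value, column: str):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise ValueError(f"column {column!r}: cannot parse boolean from {value!r}")
    return _BOOL_MAP[key]


@dataclass
class CohortManifest:
    """Validated cohort manifest: one planning + ≥1 weekly row per patient."""

    table: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    def patient_rows(self, patient_id: str) -> pd.DataFrame:
        return self.table[self.table["patient_id"] == patient_id]

    def covariates(self) -> pd.DataFrame:
        """One row of covariates per patient."""
        cov = (
            self.table.groupby("patient_id", sort=False)[
                ["age_years", "sex", "ga", "feeding_tube"]
            ]
            .first()
            .reset_index()
        )
        return cov

    def summary(self) -> dict:
        cov = self.covariates()
        return {
            "n_patients": len(cov),
            "n_scans": len(self.table),
            "age_median": float(cov["age_years"].median()),
            "age_mean": float(cov["age_years"].mean()),
            "age_range": (float(cov["age_years"].min()), float(cov["age_years"].max())),
            "male_female": (int((cov["sex"] == "M").sum()), int((cov["sex"] == "F").sum())),
            "ga_noga": (int(cov["ga"].sum()), int((~cov["ga"]).sum())),
            "tube_notube": (
                int(cov["feeding_tube"].sum()),
                int((~cov["feeding_tube"]).sum()),
            ),
        }


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, dtype={"patient_id": str, "timepoint": str, "sex": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    return validate_manifest(table)


def validate_manifest(table: pd.DataFrame) -> CohortManifest:
    table = table.copy()
    for col in ("ga", "feeding_tube"):
        table[col] = [_parse_bool(v, col) for v in table[col]]
    table["age_years"] = table["age_years"].astype(float)
    bad_sex = set(table["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be M or F, got {sorted(bad_sex)}")
    for tp in table["timepoint"]:
        timepoint_order(tp)

    dup = table.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        rows = table.loc[dup, ["patient_id", "timepoint"]].to_records(index=False)
        raise ValueError(f"duplicate (patient, timepoint) rows: {list(rows)}")
    for pid, grp in table.groupby("patient_id", sort=False):
        n_plan = int((grp["timepoint"] == PLANNING).sum())
        if n_plan != 1:
            raise ValueError(f"patient {pid}: expected exactly 1 planning row, got {n_plan}")
        if len(grp) < 2:
            raise ValueError(f"patient {pid}: needs at least one weekly scan")
        for col in ("age_years", "sex", "ga", "feeding_tube"):
            if grp[col].nunique() != 1:
                raise ValueError(f"patient {pid}: covariate {col!r} varies within patient")
    table["_order"] = [timepoint_order(t) for t in table["timepoint"]]
    table = table.sort_values(["patient_id", "_order"]).drop(columns="_order")
    return CohortManifest(table.reset_index(drop=True))


# -- metric tables ----------------------------------------------------------

FRACTION_METRIC_COLUMNS = (
    "gas_ml", "gas_rel_ml",
    "body_avg_signed_mm", "body_avg_unsigned_mm",
    "surface_avg_signed_mm", "surface_avg_unsigned_mm",
    "t_x", "t_y", "t_z", "r_x", "r_y", "r_z",
)
PATIENT_METRIC_COLUMNS = (
    "gas_std_ml", "body_avg_unsigned_mm", "surface_avg_unsigned_mm",
)


def write_metrics_table(
    fractions: pd.DataFrame, patients: pd.DataFrame, path: str | Path
) -> Path:
    """Write per-fraction and per-patient summary metrics to one tidy CSV.

    Rows are tagged by ``row_type`` (``fraction`` / ``patient_summary``);
    the column order is deterministic and the file round-trips losslessly.
    """
    path = Path(path)
    frac = fractions.copy()
    frac.insert(0, "row_type", "fraction")
    pat = patients.copy()
    pat.insert(0, "row_type", "patient_summary")
    if "timepoint" not in pat.columns:
        pat["timepoint"] = ""
    columns = ["row_type", "patient_id", "timepoint"]
    rest = sorted((set(frac.columns) | set(pat.columns)) - set(columns))
    out = pd.concat([frac, pat], ignore_index=True)[columns + rest]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.12g")
    return path


def read_metrics_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_metrics_table`: (fractions, patients) frames."""
    table = pd.read_csv(Path(path), dtype={"patient_id": str, "timepoint": str})
    frac = table[table["row_type"] == "fraction"].drop(columns="row_type")
    pat = table[table["row_type"] == "patient_summary"].drop(columns="row_type")
    frac = frac.dropna(axis=1, how="all").reset_index(drop=True)
    pat = pat.dropna(axis=1, how="all").reset_index(drop=True)
    if "timepoint" in pat.columns and (pat["timepoint"].fillna("") == "").all():
        pat = pat.drop(columns="timepoint")
    return frac, pat
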