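"""Label volumes and scan records.

All volumes live on a canonical patient frame: index axis 0 → x (left–right),
axis 1 → y (posterior→anterior, +y anterior), axis 2 → z (inferior→superior).
World position of voxel index ``i`` is ``origin + i * spacing`` (voxel-centre
based, 0-based indexing). Masks are strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

PLANNING = "planning"
WEEK_TIMEPOINTS = tuple(f"week_{k}" for k in range(1, 6))
TIMEPOINTS = (PLANNING,) + WEEK_TIMEPOINTS


def timepoint_order(timepoint: str) -> int:
    """Sort key placing planning first, then week_1..week_5."""
    try:
        return TIMEPOINTS.index(timepoint)
    except ValueError:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}"
        ) from None


@dataclass
class LabelVolume:
    """A 3D binary mask with voxel spacing (mm) and world origin (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {voxels.ndim}D")
        if voxels.dtype != bool:
            values = np.unique(voxels)
            if not np.all(np.isin(values, (0, 1))):
                raise ValueError("voxels must be binary {0,1}")
            voxels = voxels.astype(bool)
        self.voxels = voxels
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def volume_ml(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_ml

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def extent_mm(self) -> np.ndarray:
        """World bounding box of the grid (outer voxel faces), shape (2, 3)."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return np.stack([lo, hi])

    def centroid_mm(self) -> np.ndarray:
        """World centroid of the foreground voxels."""
        if not self.voxels.any():
            raise ValueError("empty mask has no centroid")
        idx = np.argwhere(self.voxels)
        return self.index_to_world(idx.mean(axis=0))

    def same_grid(self, other: "LabelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.spacing.copy(), self.origin.copy())

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return LabelVolume(voxels, self.spacing.copy(), self.origin.copy())

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        """Membership of world points in the mask (nearest-voxel lookup).

        Points outside the grid count as outside the mask.
        """
        idx = np.rint(self.world_to_index(pts)).astype(int)
        inside_grid = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)
        out = np.zeros(len(idx), dtype=bool)
        ig = idx[inside_grid]
        out[inside_grid] = self.voxels[ig[:, 0], ig[:, 1], ig[:, 2]]
        return out


@dataclass
class ScanRecord:
    """One imaging timepoint: body and GI-gas masks on a shared grid."""

    patient_id: str
    timepoint: str
    body: LabelVolume
    gas: LabelVolume

    def __post_init__(self) -> None:
        timepoint_order(self.timepoint)
        if not self.body.same_grid(self.gas):
            raise ValueError(
                f"body and gas masks of {self.patient_id}/{self.timepoint} "
                "must share shape, spacing and origin"
            )

    @property
    def is_planning(self) -> bool:
        return self.timepoint == PLANNING

    def map_volumes(self, fn) -> "ScanRecord":
        return replace(self, body=fn(self.body), gas=fn(self.gas))


def sort_scans(scans: Iterable[ScanRecord]) -> list[ScanRecord]:
    return sorted(scans, key=lambda s: (s.patient_id, timepoint_order(s.timepoint)))
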