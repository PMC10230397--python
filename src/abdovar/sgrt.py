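"""Simulated surface-guided (SGRT) residual corrections.

After the treatment scan has been rigidly aligned to the planning scan
(treatment-position simulation), both scans are translated so the treatment
isocenter sits at the origin, their anterior body surfaces are lifted to
point clouds, and trimmed ICP estimates the residual six-degree-of-freedom
correction (t_x, t_y, t_z in mm; r_x, r_y, r_z in degrees, decomposed about
the isocenter) that an optical surface-tracking system would report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .icp import ICPParams, ICPResult, icp_point_clouds
from .metrics import AnteriorWindow, anterior_surface_map
from .transform import RigidTransform
from .volume import LabelVolume, ScanRecord

MIN_CLOUD_POINTS = 100


@dataclass
class PointCloud:
    """A set of surface points (world mm) with its provenance."""

    points: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def to_isocenter_frame(scan: ScanRecord, isocenter_mm) -> ScanRecord:
    """Shift a scan's coordinates so the treatment isocenter is the origin."""
    iso = np.asarray(isocenter_mm, dtype=float).reshape(3)
    lo, hi = scan.body.extent_mm()
    if np.any(iso < lo) or np.any(iso > hi):
        raise ValueError(f"isocenter {iso} lies outside the volume extent")

    def shift(vol: LabelVolume) -> LabelVolume:
        return LabelVolume(vol.voxels, vol.spacing.copy(), vol.origin - iso)

    return scan.map_volumes(shift)


def anterior_point_cloud(
    scan: ScanRecord, window: AnteriorWindow | None = None
) -> PointCloud:
    """Anterior body surface as a 3D point cloud (one point per column)."""
    amap = anterior_surface_map(scan.body, window)
    present = np.argwhere(np.isfinite(amap.y_mm))
    if len(present) < MIN_CLOUD_POINTS:
        raise ValueError(
            f"anterior surface yields only {len(present)} points "
            f"(minimum {MIN_CLOUD_POINTS} for registration)"
        )
    pts = np.column_stack(
        [
            amap.x_mm[present[:, 0]],
            amap.y_mm[present[:, 0], present[:, 1]],
            amap.z_mm[present[:, 1]],
        ]
    )
    return PointCloud(pts, provenance=f"{scan.patient_id}/{scan.timepoint}:anterior")


def icp_register(
    moving: PointCloud, fixed: PointCloud, params: ICPParams | None = None
) -> tuple[RigidTransform, ICPResult]:
    """Pose offset of the moving cloud relative to the fixed cloud.

    The six parameters are decomposed about the frame origin (the isocenter
    in the SGRT workflow); ``moving ≈ T(fixed)``, so the correction that
    aligns the moving surface onto the reference is ``T.invert()``.
    """
    result = icp_point_clouds(moving.points, fixed.points, params)
    return result.offset, result


def sgrt_correction(
    ct_scan: ScanRecord,
    cbct_scan: ScanRecord,
    isocenter_mm,
    params: ICPParams | None = None,
    window: AnteriorWindow | None = None,
) -> tuple[RigidTransform, ICPResult]:
    """Residual SGRT correction between a planning and a treatment scan.

    Both scans must already be in the common (aligned, cropped) frame; they
    are moved to the isocenter frame, anterior clouds extracted, and the
    treatment cloud registered to the planning cloud. The returned transform
    is the treatment surface's pose offset (t_x..r_z about the isocenter).
    """
    ct_iso = to_isocenter_frame(ct_scan, isocenter_mm)
    cbct_iso = to_isocenter_frame(cbct_scan, isocenter_mm)
    fixed_cloud = anterior_point_cloud(ct_iso, window)
    moving_cloud = anterior_point_cloud(cbct_iso, window)
    return icp_register(moving_cloud, fixed_cloud, params)
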