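"""Rigid co-registration of body masks and common field-of-view cropping.

The treatment scans are brought into the planning frame by registering body
surfaces (moments initialisation + trimmed ICP on iso-surface points); both
scans of a pair are then cropped to the axis-aligned box where both grids
carry data, so no metric ever compares anatomy against empty space.
"""

from __future__ import annotations

import numpy as np

from .icp import ICPParams, icp_point_clouds
from .metrics import extract_surface_points
from .transform import RigidTransform, apply_transform, transformed_extent_mm
from .volume import LabelVolume, ScanRecord


class RegistrationError(RuntimeError):
    def __init__(self, message: str, residual_mm: float | None = None):
        super().__init__(message)
        self.residual_mm = residual_mm


def register_masks_rigid(
    fixed_body: LabelVolume,
    moving_body: LabelVolume,
    params: ICPParams | None = None,
) -> RigidTransform:
    """Pose offset of the moving body surface relative to the fixed one.

    Minimises the mean surface distance between the two body iso-surfaces;
    the returned transform satisfies ``moving ≈ T(fixed)`` and is decomposed
    about the fixed body centroid. Apply ``T.invert()`` to the moving scan to
    align it.
    """
    params = params or ICPParams()
    if not fixed_body.voxels.any() or not moving_body.voxels.any():
        raise ValueError("cannot register empty masks")
    fixed_pts = extract_surface_points(fixed_body)
    moving_pts = extract_surface_points(moving_body)
    result = icp_point_clouds(moving_pts, fixed_pts, params)
    if not result.converged:
        raise RegistrationError(
            f"ICP did not converge within {params.max_iterations} iterations "
            f"(last mean residual {result.residual_mm:.3f} mm)",
            residual_mm=result.residual_mm,
        )
    return result.offset.with_center(fixed_body.centroid_mm())


def align_scan(
    scan: ScanRecord,
    offset: RigidTransform,
    reference: LabelVolume,
) -> tuple[ScanRecord, np.ndarray]:
    """Resample a scan into the reference grid undoing its pose offset.

    Returns the aligned scan plus the world bounding box (2, 3) that the
    moving grid maps onto — its valid extent for field-of-view cropping.
    """
    undo = offset.invert()
    aligned = scan.map_volumes(lambda v: apply_transform(v, undo, reference=reference))
    return aligned, transformed_extent_mm(scan.body, undo)


def crop_to_box(vol: LabelVolume, box_mm: np.ndarray) -> LabelVolume:
    """Crop to voxels whose centres lie inside a world box."""
    lo_idx = np.ceil((box_mm[0] - vol.origin) / vol.spacing - 1e-9).astype(int)
    hi_idx = np.floor((box_mm[1] - vol.origin) / vol.spacing + 1e-9).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(vol.shape) - 1)
    if np.any(hi_idx < lo_idx):
        raise ValueError("crop box does not intersect the volume grid")
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx))
    return LabelVolume(
        vol.voxels[sl].copy(),
        vol.spacing.copy(),
        vol.origin + lo_idx * vol.spacing,
    )


def common_fov_crop(
    fixed: ScanRecord,
    moving_aligned: ScanRecord,
    moving_extent_mm: np.ndarray | None = None,
) -> tuple[ScanRecord, ScanRecord]:
    """Crop both scans to the intersection of their valid world extents.

    ``moving_extent_mm`` is the world box the moving grid occupied before
    resampling into the fixed grid (from :func:`align_scan`); it defaults to
    the moving scan's current grid extent.
    """
    box_f = fixed.body.extent_mm()
    box_m = (
        np.asarray(moving_extent_mm, dtype=float)
        if moving_extent_mm is not None
        else moving_aligned.body.extent_mm()
    )
    lo = np.maximum(box_f[0], box_m[0])
    hi = np.minimum(box_f[1], box_m[1])
    if np.any(hi <= lo):
        raise ValueError("scans share no common field of view")
    box = np.stack([lo, hi])
    fixed_c = fixed.map_volumes(lambda v: crop_to_box(v, box))
    moving_c = moving_aligned.map_volumes(lambda v: crop_to_box(v, box))
    return fixed_c, moving_c
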