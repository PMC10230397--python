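"""Anatomical-change metrics between planning and treatment scans.

Implements the per-scan gas volumes with their variability summaries
(``Gas_std``, ``Gas_rel``), the bi-directional body-contour separation
(``Body_avg`` signed/unsigned) and the anterior-surface separation
(``Surface_avg`` signed/unsigned), computed from cleaned, co-registered
body/gas label masks.

Sign conventions: body separations are negative when the test (treatment)
contour sits inside the reference (planning) contour — shrinkage is negative
from both pooling directions. Anterior-surface separations are positive when
the test wall lies more anterior (distension). ``Gas_rel`` is fraction minus
reference, so a net gas reduction over treatment is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .volume import PLANNING, LabelVolume, ScanRecord, timepoint_order


# -- surface separations ----------------------------------------------------

@dataclass
class SurfaceSeparation:
    """A pooled bi-directional distance distribution with its two means."""

    distances_signed: np.ndarray
    n_ref: int
    n_test: int

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_signed, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("empty distance distribution")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        self.distances_signed = d

    @property
    def mean_signed(self) -> float:
        return float(self.distances_signed.mean())

    @property
    def mean_unsigned(self) -> float:
        return float(np.abs(self.distances_signed).mean())


def gas_volume(gas: LabelVolume) -> float:
    """Gas volume in ml (voxel count x voxel volume)."""
    return gas.volume_ml()


@dataclass
class GasMetrics:
    """Per-timepoint gas volumes with their variability summaries."""

    volumes_ml: dict
    reference: str
    gas_std_ml: float
    gas_rel_ml: dict = field(default_factory=dict)


def gas_metrics(
    volumes_ml: Mapping[str, float],
    include_planning: bool = True,
    reference: str | None = None,
) -> GasMetrics:
    """Summarise gas volumes across timepoints.

    ``gas_std_ml`` is the sample (n−1) standard deviation over the included
    timepoints; ``gas_rel_ml`` is each timepoint's volume minus the reference
    volume (planning by default, or a designated treatment scan when the
    planning scan is excluded from the sensitivity analysis).
    """
    vols = {tp: float(v) for tp, v in volumes_ml.items()}
    for tp, v in vols.items():
        timepoint_order(tp)
        if v < 0:
            raise ValueError(f"negative gas volume at {tp}: {v}")
    if reference is None:
        reference = PLANNING
    if reference not in vols:
        raise ValueError(f"reference timepoint {reference!r} not among volumes")
    included = dict(vols)
    if not include_planning and reference != PLANNING:
        included.pop(PLANNING, None)
    if len(included) < 2:
        raise ValueError("need at least 2 timepoints to compute Gas_std")
    values = np.array(list(included.values()))
    gas_std = float(values.std(ddof=1))
    gas_rel = {tp: v - vols[reference] for tp, v in included.items()}
    return GasMetrics(included, reference, gas_std, gas_rel)


def extract_surface_points(mask: LabelVolume) -> np.ndarray:
    """Sub-voxel surface points (world mm) of a binary mask.

    Vertices of the 0.5 iso-surface triangulation; the volume is zero-padded
    by one voxel so surfaces touching the grid border still close.
    """
    if not mask.voxels.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, _, _, _ = marching_cubes(padded, level=0.5)
    return mask.origin + (verts - 1.0) * mask.spacing


def _signed_nn_distances(
    src_pts: np.ndarray,
    dst_tree: cKDTree,
    inside: np.ndarray,
    negative_when_inside: bool,
) -> np.ndarray:
    dist, _ = dst_tree.query(src_pts, workers=-1)
    sign = np.where(inside == negative_when_inside, -1.0, 1.0)
    return dist * sign


def body_separation(ref_scan: ScanRecord, test_scan: ScanRecord) -> SurfaceSeparation:
    """Bi-directional body-contour separation between two aligned scans.

    For every test-surface point the distance to the nearest reference-surface
    point (negative if the point lies inside the reference body) and for every
    reference-surface point the distance to the nearest test-surface point
    (negative if it lies *outside* the test body), pooled into one
    distribution. A test scan encompassed by the reference therefore yields a
    negative mean from both directions.
    """
    ref_pts = extract_surface_points(ref_scan.body)
    test_pts = extract_surface_points(test_scan.body)
    ref_tree = cKDTree(ref_pts)
    test_tree = cKDTree(test_pts)
    d_test = _signed_nn_distances(
        test_pts, ref_tree, ref_scan.body.contains_points(test_pts),
        negative_when_inside=True,
    )
    d_ref = _signed_nn_distances(
        ref_pts, test_tree, test_scan.body.contains_points(ref_pts),
        negative_when_inside=False,
    )
    return SurfaceSeparation(
        np.concatenate([d_test, d_ref]), n_ref=len(ref_pts), n_test=len(test_pts)
    )


# -- anterior-surface (abdominal wall surrogate) ---------------------------

@dataclass(frozen=True)
class AnteriorWindow:
    """Analysis window for the anterior abdominal wall surrogate.

    ``x_fraction`` keeps the central fraction of the body's left–right width;
    ``z_range_mm`` optionally restricts the supero-inferior extent (defaults
    to the full common field of view).
    """

    x_fraction: float = 0.6
    z_range_mm: tuple[float, float] | None = None


@dataclass
class AnteriorMap:
    """Anterior-most body-surface height y(x, z), NaN where absent."""

    x_mm: np.ndarray
    z_mm: np.ndarray
    y_mm: np.ndarray  # shape (len(x_mm), len(z_mm))

    def common_columns(self, other: "AnteriorMap") -> np.ndarray:
        if self.y_mm.shape != other.y_mm.shape or not (
            np.allclose(self.x_mm, other.x_mm) and np.allclose(self.z_mm, other.z_mm)
        ):
            raise ValueError("anterior maps must share the same (x, z) lattice")
        return np.isfinite(self.y_mm) & np.isfinite(other.y_mm)


def anterior_surface_map(
    body: LabelVolume, window: AnteriorWindow | None = None
) -> AnteriorMap:
    """Map each (x, z) column in the window to its anterior-most y (mm).

    The height is the anterior face of the anterior-most body voxel in the
    column; columns that do not intersect the body are NaN. The map is by
    construction invariant to posterior-side mask edits.
    """
    window = window or AnteriorWindow()
    vox = body.voxels
    nx, ny, nz = vox.shape
    x_mm = body.origin[0] + np.arange(nx) * body.spacing[0]
    z_mm = body.origin[2] + np.arange(nz) * body.spacing[2]

    any_y = vox.any(axis=1)  # (nx, nz)
    if not any_y.any():
        raise ValueError("body mask is empty")
    x_present = np.flatnonzero(any_y.any(axis=1))
    x_lo, x_hi = x_mm[x_present[0]], x_mm[x_present[-1]]
    x_mid, x_half = 0.5 * (x_lo + x_hi), 0.5 * (x_hi - x_lo)
    in_x = np.abs(x_mm - x_mid) <= window.x_fraction * x_half + 1e-9
    in_z = np.ones(nz, dtype=bool)
    if window.z_range_mm is not None:
        z0, z1 = window.z_range_mm
        in_z = (z_mm >= z0) & (z_mm <= z1)
    sel = any_y & in_x[:, None] & in_z[None, :]
    if not sel.any():
        raise ValueError("anterior window does not intersect the body")

    # anterior-most occupied y index per column
    iy = ny - 1 - np.argmax(vox[:, ::-1, :], axis=1)
    y_face = body.origin[1] + (iy + 0.5) * body.spacing[1]
    y_mm = np.where(sel, y_face, np.nan)
    return AnteriorMap(x_mm, z_mm, y_mm)


def surface_separation(ref_map: AnteriorMap, test_map: AnteriorMap) -> SurfaceSeparation:
    """Anterior-posterior wall separation over common (x, z) columns.

    Positive where the test wall is more anterior than the reference
    (distension); only columns present in both maps contribute.
    """
    common = ref_map.common_columns(test_map)
    if not common.any():
        raise ValueError("anterior maps share no columns")
    delta = test_map.y_mm[common] - ref_map.y_mm[common]
    n = int(common.sum())
    return SurfaceSeparation(delta, n_ref=n, n_test=n)
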