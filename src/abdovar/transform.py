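"""Six-degree-of-freedom rigid transforms and mask resampling.

Convention (fixed throughout the package): translations ``t_x, t_y, t_z`` in
mm, rotations ``r_x, r_y, r_z`` in degrees applied intrinsically about x then
y then z, about a stated rotation centre (body centroid unless a treatment
isocenter is supplied). A transform maps a point ``p`` to
``R (p - c) + c + t``.

Registration routines return the *pose offset* of the moving surface relative
to the fixed one (``moving = T(fixed)``); applying ``T.invert()`` to the
moving scan aligns it onto the fixed scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import LabelVolume

#: intrinsic Euler axis order used for all parameter decompositions
EULER_ORDER = "XYZ"


def _vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"expected finite 3-vector, got {v}")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: translation (mm) + intrinsic x→y→z rotation (deg)."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", _vec3(self.translation))
        object.__setattr__(self, "rotation_deg", _vec3(self.rotation_deg))
        object.__setattr__(self, "center", _vec3(self.center))

    # parameter accessors mirroring the clinical naming
    @property
    def t_x(self) -> float: return float(self.translation[0])
    @property
    def t_y(self) -> float: return float(self.translation[1])
    @property
    def t_z(self) -> float: return float(self.translation[2])
    @property
    def r_x(self) -> float: return float(self.rotation_deg[0])
    @property
    def r_y(self) -> float: return float(self.rotation_deg[1])
    @property
    def r_z(self) -> float: return float(self.rotation_deg[2])

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), center)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler(EULER_ORDER, self.rotation_deg, degrees=True)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of the world mapping."""
        R = self.rotation.as_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation - R @ self.center
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        center = _vec3(center)
        R = np.asarray(M)[:3, :3]
        rot = Rotation.from_matrix(R)
        m = np.asarray(M)[:3, 3]
        t = m + R @ center - center
        return cls(t, rot.as_euler(EULER_ORDER, degrees=True), center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        R = self.rotation.as_matrix()
        return (pts - self.center) @ R.T + self.center + self.translation

    def invert(self) -> "RigidTransform":
        R = self.rotation
        t_inv = -R.inv().apply(self.translation)
        return RigidTransform(
            t_inv, R.inv().as_euler(EULER_ORDER, degrees=True), self.center
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), self.center)

    def with_center(self, center) -> "RigidTransform":
        """Same mapping re-expressed about a different rotation centre."""
        return RigidTransform.from_matrix(self.matrix(), center)

    def as_params(self) -> np.ndarray:
        """(t_x, t_y, t_z, r_x, r_y, r_z)."""
        return np.concatenate([self.translation, self.rotation_deg])

    def magnitude(self) -> tuple[float, float]:
        """(max |t| mm, max |r| deg) — handy for tolerance checks."""
        return float(np.abs(self.translation).max()), float(
            np.abs(self.rotation_deg).max()
        )

    def __str__(self) -> str:
        t, r = self.translation, self.rotation_deg
        return (
            f"t=({t[0]:+.2f},{t[1]:+.2f},{t[2]:+.2f})mm "
            f"r=({r[0]:+.2f},{r[1]:+.2f},{r[2]:+.2f})deg"
        )


def apply_transform(
    vol: LabelVolume,
    transform: RigidTransform,
    reference: LabelVolume | None = None,
) -> LabelVolume:
    """Resample a mask under a rigid motion of the imaged object.

    The output grid is the ``reference`` grid (default: the input grid) and
    voxels are filled by nearest-neighbour lookup, preserving binary values
    with half-voxel positional uncertainty.
    """
    ref = vol if reference is None else reference
    R = transform.rotation.as_matrix()
    S_in = np.diag(vol.spacing)
    S_out = np.diag(ref.spacing)
    # output index o -> world p = ref.origin + S_out o -> source world
    # q = R^T (p - c - t) + c -> source index (q - vol.origin) / vol.spacing
    A = np.linalg.inv(S_in) @ R.T @ S_out
    shift = R.T @ (ref.origin - transform.center - transform.translation) + (
        transform.center - vol.origin
    )
    offset = np.linalg.inv(S_in) @ shift
    voxels = ndimage.affine_transform(
        vol.voxels.astype(np.uint8),
        A,
        offset=offset,
        output_shape=ref.shape,
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return LabelVolume(voxels.astype(bool), ref.spacing.copy(), ref.origin.copy())


def transformed_extent_mm(vol: LabelVolume, transform: RigidTransform) -> np.ndarray:
    """Axis-aligned world bounding box of the moved grid, shape (2, 3)."""
    lo, hi = vol.extent_mm()
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    moved = transform.apply(corners)
    return np.stack([moved.min(axis=0), moved.max(axis=0)])
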