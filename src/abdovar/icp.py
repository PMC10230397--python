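"""Trimmed iterative-closest-point rigid registration of point clouds.

Classic point-to-point ICP: nearest-neighbour correspondences against a
KD-tree of the fixed cloud, adaptive trimming of badly matched points
(robustness for partially overlapping anterior surfaces), and a closed-form
least-squares rigid update (Kabsch / orthogonal Procrustes) per iteration.

Smooth, shallow surfaces such as an anterior abdominal dome admit sliding
local minima under point-to-point ICP, so the solver is multi-start: a
centroid init, a principal-axes init, and a few seeded small-rotation
restarts, keeping the result with the lowest trimmed mean residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .transform import RigidTransform


@dataclass(frozen=True)
class ICPParams:
    """Tuning knobs for the ICP solver.

    ``trim_fraction`` enables adaptive outlier rejection: matches farther
    than 3x the median match distance are dropped, capped at a dropped
    fraction of ``2 * trim_fraction`` per iteration (0 disables trimming).
    ``n_restarts`` additional seeded small-rotation starts guard against
    sliding local minima; restarts stop early once a start reaches
    ``restart_residual_mm``.
    """

    max_iterations: int = 200
    convergence_tol_mm: float = 1e-6
    trim_fraction: float = 0.1
    max_points: int = 5000
    n_restarts: int = 3
    restart_rotation_deg: float = 4.0
    restart_residual_mm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.convergence_tol_mm <= 0 or self.max_iterations < 1:
            raise ValueError("tolerances and iteration counts must be positive")


@dataclass
class ICPResult:
    """Outcome of an ICP run.

    ``alignment`` maps the moving cloud onto the fixed cloud (about the frame
    origin); ``offset`` is its inverse — the pose of the moving surface
    relative to the fixed one, which is what the registration interfaces
    report.
    """

    alignment: RigidTransform
    residual_mm: float
    n_iterations: int
    converged: bool
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def offset(self) -> RigidTransform:
        return self.alignment.invert()


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit: R, t minimising ||R p + t - q||^2."""
    mu_p = moving.mean(axis=0)
    mu_q = fixed.mean(axis=0)
    H = (moving - mu_p).T @ (fixed - mu_q)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, mu_q - R @ mu_p


def _check_not_collinear(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(points) < 3 or s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError(f"{label} point cloud is degenerate (collinear)")


def _subsample(points: np.ndarray, max_points: int, seed: int) -> np.ndarray:
    if len(points) <= max_points:
        return points
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(points), size=max_points, replace=False)
    return points[np.sort(idx)]


def _principal_axes_init(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid + principal-axes initial guess, biased towards identity.

    Eigenvector sign ambiguities are resolved by picking, per axis, the sign
    keeping the implied rotation closest to the identity — adequate for the
    small-angle setup range this pipeline deals with; falls back to the pure
    centroid init on reflections or large implied angles.
    """
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    _, _, Vm = np.linalg.svd(moving - mu_m, full_matrices=False)
    _, _, Vf = np.linalg.svd(fixed - mu_f, full_matrices=False)
    R = Vf.T @ np.diag(np.sign(np.diag(Vf @ Vm.T))) @ Vm
    if np.linalg.det(R) < 0 or np.trace(R) < 2.0:
        R = np.eye(3)
    return R, mu_f - R @ mu_m


def _run_single(
    moving: np.ndarray,
    tree: cKDTree,
    fixed: np.ndarray,
    R0: np.ndarray,
    t0: np.ndarray,
    params: ICPParams,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    cur_R, cur_t = R0.copy(), t0.copy()
    keep_floor = max(0.5, 1.0 - 2.0 * params.trim_fraction)
    history: list[float] = []
    prev = np.inf
    converged = False
    for iteration in range(1, params.max_iterations + 1):
        pts = moving @ cur_R.T + cur_t
        dist, match = tree.query(pts, workers=-1)
        if params.trim_fraction > 0:
            keep = dist <= max(3.0 * np.median(dist), 1e-12)
            if keep.mean() < keep_floor:
                keep = dist <= np.quantile(dist, keep_floor)
        else:
            keep = np.ones(len(dist), dtype=bool)
        residual = float(dist[keep].mean())
        history.append(residual)
        R, t = kabsch(pts[keep], fixed[match[keep]])
        cur_R = R @ cur_R
        cur_t = R @ cur_t + t
        if abs(prev - residual) < params.convergence_tol_mm:
            converged = True
            break
        prev = residual
    return cur_R, cur_t, history, iteration, converged


def icp_point_clouds(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: ICPParams | None = None,
    init: RigidTransform | None = None,
) -> ICPResult:
    """Align ``moving`` onto ``fixed`` with multi-start trimmed ICP.

    The returned transform is decomposed about the frame origin; callers
    working about a centroid or isocenter re-express it with
    :meth:`RigidTransform.with_center`.
    """
    params = params or ICPParams()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    _check_not_collinear(moving, "moving")
    _check_not_collinear(fixed, "fixed")
    moving = _subsample(moving, params.max_points, params.seed)
    fixed = _subsample(fixed, params.max_points, params.seed)
    tree = cKDTree(fixed)
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)

    starts: list[tuple[np.ndarray, np.ndarray]] = []
    if init is not None:
        M = init.matrix()
        starts.append((M[:3, :3], M[:3, 3]))
    starts.append((np.eye(3), mu_f - mu_m))
    starts.append(_principal_axes_init(moving, fixed))
    rng = np.random.default_rng(params.seed)
    for _ in range(params.n_restarts):
        R = Rotation.from_euler(
            "XYZ", rng.uniform(-params.restart_rotation_deg,
                               params.restart_rotation_deg, 3),
            degrees=True,
        ).as_matrix()
        starts.append((R, mu_f - R @ mu_m))

    best = None
    for R0, t0 in starts:
        run = _run_single(moving, tree, fixed, R0, t0, params)
        if best is None or run[2][-1] < best[2][-1]:
            best = run
        if best[2][-1] < params.restart_residual_mm:
            break

    cur_R, cur_t, history, iteration, converged = best
    M = np.eye(4)
    M[:3, :3] = cur_R
    M[:3, 3] = cur_t
    return ICPResult(
        alignment=RigidTransform.from_matrix(M),
        residual_mm=history[-1],
        n_iterations=iteration,
        converged=converged,
        residual_history=np.asarray(history),
    )
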