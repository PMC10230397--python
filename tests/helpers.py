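"""Shared fixtures helpers and independent oracles used across the suite.

The oracles here deliberately avoid the library's own code paths (KD-trees,
dynamic programmes) so they can serve as independent references: brute-force
all-pairs surface distances, enumeration-based rank tests, and subset
enumeration for the conditional logistic test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from abdovar.volume import LabelVolume, ScanRecord


# -- mask builders ----------------------------------------------------------

def make_sphere(
    radius_mm: float,
    spacing: float = 2.0,
    margin_mm: float = 6.0,
    origin_shift=(0.0, 0.0, 0.0),
) -> LabelVolume:
    half = radius_mm + margin_mm
    n = 2 * int(np.ceil(half / spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    voxels = X**2 + Y**2 + Z**2 <= radius_mm**2
    origin = -((n - 1) / 2) * spacing * np.ones(3) + np.asarray(origin_shift)
    return LabelVolume(voxels, np.full(3, spacing), origin)


def make_box(
    half_extents_mm=(20.0, 15.0, 25.0), spacing: float = 2.0, margin_mm: float = 6.0
) -> LabelVolume:
    he = np.asarray(half_extents_mm, dtype=float)
    shape = (2 * np.ceil((he + margin_mm) / spacing) + 1).astype(int)
    origin = -(shape - 1) / 2 * spacing
    grids = [origin[i] + np.arange(shape[i]) * spacing for i in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    voxels = (np.abs(X) <= he[0]) & (np.abs(Y) <= he[1]) & (np.abs(Z) <= he[2])
    return LabelVolume(voxels, np.full(3, spacing), origin)


def random_blob(seed: int, shape=(20, 20, 20), spacing: float = 2.0) -> LabelVolume:
    """Random smooth connected blob (for property and oracle tests)."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    voxels = smooth > np.quantile(smooth, 0.7)
    voxels = ndimage.binary_closing(voxels, np.ones((2, 2, 2)))
    labels, n = ndimage.label(voxels, np.ones((3, 3, 3)))
    if n == 0:
        centre = tuple(s // 2 for s in shape)
        voxels = np.zeros(shape, bool)
        voxels[centre[0] - 2 : centre[0] + 2, centre[1] - 2 : centre[1] + 2,
               centre[2] - 2 : centre[2] + 2] = True
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        voxels = labels == counts.argmax()
    origin = -(np.array(shape) - 1) / 2 * spacing
    return LabelVolume(voxels, np.full(3, spacing), origin)


def as_scan(body: LabelVolume, patient="P", timepoint="planning") -> ScanRecord:
    gas = body.with_voxels(np.zeros(body.shape, bool))
    return ScanRecord(patient, timepoint, body, gas)


# -- independent oracles ----------------------------------------------------

def surface_points_oracle(mask: LabelVolume) -> np.ndarray:
    """Marching-cubes surface vertices (same definition as the library)."""
    from skimage.measure import marching_cubes

    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, _, _, _ = marching_cubes(padded, level=0.5)
    return mask.origin + (verts - 1.0) * mask.spacing


def brute_force_body_separation(ref: ScanRecord, test: ScanRecord) -> np.ndarray:
    """All-pairs signed bi-directional distances (no KD-tree)."""
    ref_pts = surface_points_oracle(ref.body)
    test_pts = surface_points_oracle(test.body)
    d_matrix = cdist(test_pts, ref_pts)

    def inside(mask: LabelVolume, pts):
        idx = np.rint((pts - mask.origin) / mask.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
        vals = np.zeros(len(pts), bool)
        vals[ok] = mask.voxels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return vals

    d_test = d_matrix.min(axis=1)
    d_test = np.where(inside(ref.body, test_pts), -d_test, d_test)
    d_ref = d_matrix.min(axis=0)
    d_ref = np.where(inside(test.body, ref_pts), d_ref, -d_ref)
    return np.concatenate([d_test, d_ref])


def mann_whitney_enumeration_oracle(a, b) -> float:
    """Two-sided exact p by explicit enumeration of group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(pooled)
    t_obs = ranks[: len(a)].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n), len(a))]
    )
    p_le = np.mean(sums <= t_obs + 1e-9)
    p_ge = np.mean(sums >= t_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_logistic_enumeration_oracle(y, x) -> tuple[float, float]:
    """(one-sided, two-sided) conditional p by explicit subset enumeration."""
    y = np.asarray(y, int)
    x = np.asarray(x, float)
    m = y.sum()
    t_obs = x[y == 1].sum()
    sums = np.array(
        [x[list(c)].sum() for c in itertools.combinations(range(len(x)), m)]
    )
    p_le = np.mean(sums <= t_obs + 1e-9)
    p_ge = np.mean(sums >= t_obs - 1e-9)
    one = min(p_le, p_ge)
    return one, min(1.0, 2.0 * one)


def spearman_formula(x, y) -> float:
    """1 - 6 sum(d^2) / (n (n^2-1)) — valid for tie-free data."""
    rx = rankdata(x)
    ry = rankdata(y)
    d = rx - ry
    n = len(rx)
    return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))
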