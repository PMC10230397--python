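import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from abdovar.metrics import (
    AnteriorWindow,
    SurfaceSeparation,
    anterior_surface_map,
    body_separation,
    extract_surface_points,
    gas_metrics,
    gas_volume,
    surface_separation,
)
from abdovar.synthetic import generate_phantom_scan
from abdovar.transform import RigidTransform, apply_transform
from abdovar.volume import LabelVolume
from helpers import as_scan, brute_force_body_separation, make_box, make_sphere


class TestGasVolume:
    def test_empty_mask(self):
        vol = make_sphere(10.0)
        assert gas_volume(vol.with_voxels(np.zeros(vol.shape, bool))) == 0.0

    def test_single_2mm_voxel(self):
        voxels = np.zeros((5, 5, 5), bool)
        voxels[2, 2, 2] = True
        vol = LabelVolume(voxels, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        assert gas_volume(vol) == pytest.approx(0.008)

    def test_digitised_sphere_within_3pct_of_analytic(self):
        vol = make_sphere(20.0, spacing=2.0)
        analytic = 4.0 / 3.0 * np.pi * 20.0**3 / 1000.0
        assert gas_volume(vol) == pytest.approx(analytic, rel=0.03)


class TestGasMetrics:
    def test_sample_sd(self):
        gm = gas_metrics({"planning": 100.0, "week_1": 150.0, "week_2": 200.0})
        assert gm.gas_std_ml == pytest.approx(50.0)
        assert gm.gas_rel_ml["planning"] == 0.0
        assert gm.gas_rel_ml["week_2"] == pytest.approx(100.0)

    def test_constant_volumes(self):
        gm = gas_metrics({"planning": 80.0, "week_1": 80.0, "week_2": 80.0})
        assert gm.gas_std_ml == 0.0
        assert all(v == 0.0 for v in gm.gas_rel_ml.values())

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            gas_metrics({"planning": 100.0})

    def test_gas_std_permutation_invariant(self):
        vols = {"planning": 10.0, "week_1": 120.0, "week_2": 45.0, "week_3": 80.0}
        shuffled = dict(reversed(list(vols.items())))
        assert gas_metrics(vols).gas_std_ml == gas_metrics(shuffled).gas_std_ml

    def test_gas_rel_antisymmetric_under_reference_swap(self):
        vols = {"planning": 100.0, "week_1": 160.0}
        forward = gas_metrics(vols)
        swapped = gas_metrics(vols, reference="week_1")
        assert forward.gas_rel_ml["week_1"] == -swapped.gas_rel_ml["planning"]

    def test_planning_excluded_reference_cbct(self):
        gm = gas_metrics(
            {"planning": 500.0, "week_1": 100.0, "week_2": 140.0, "week_3": 90.0},
            include_planning=False,
            reference="week_2",
        )
        assert "planning" not in gm.volumes_ml
        assert gm.gas_rel_ml["week_2"] == 0.0
        assert gm.gas_std_ml == pytest.approx(np.std([100, 140, 90], ddof=1))


class TestSurfacePoints:
    def test_sphere_points_near_radius(self):
        vol = make_sphere(20.0, spacing=2.0)
        pts = extract_surface_points(vol)
        radii = np.linalg.norm(pts, axis=1)
        assert np.all(np.abs(radii - 20.0) <= 2.0)

    def test_single_voxel_closed_surface(self):
        voxels = np.zeros((5, 5, 5), bool)
        voxels[2, 2, 2] = True
        pts = extract_surface_points(LabelVolume(voxels, (1, 1, 1), (0, 0, 0)))
        assert len(pts) >= 6
        # points enclose the voxel centre on all six sides
        assert np.all(pts.min(axis=0) < [2, 2, 2]) and np.all(pts.max(axis=0) > [2, 2, 2])

    def test_point_count_scales_with_area(self):
        n1 = len(extract_surface_points(make_sphere(10.0, spacing=1.0)))
        n2 = len(extract_surface_points(make_sphere(20.0, spacing=1.0)))
        assert n2 / n1 == pytest.approx(4.0, rel=0.2)

    def test_empty_mask_rejected(self):
        vol = make_sphere(5.0)
        with pytest.raises(ValueError, match="empty"):
            extract_surface_points(vol.with_voxels(np.zeros(vol.shape, bool)))


def eroded_scan(scan, mm, spacing):
    it = int(round(mm / spacing))
    voxels = ndimage.binary_erosion(
        scan.body.voxels, ndimage.generate_binary_structure(3, 1), iterations=it
    )
    return as_scan(scan.body.with_voxels(voxels), timepoint="week_1")


class TestBodySeparation:
    def test_identical_scans_zero(self):
        scan = as_scan(make_sphere(16.0, spacing=2.0))
        sep = body_separation(scan, as_scan(scan.body, timepoint="week_1"))
        assert abs(sep.mean_signed) < 0.05
        assert sep.mean_unsigned < 0.05

    def test_uniform_shrinkage_negative_2mm(self):
        ref = as_scan(make_sphere(20.0, spacing=1.0))
        test = as_scan(make_sphere(18.0, spacing=1.0), timepoint="week_1")
        sep = body_separation(ref, test)
        assert sep.mean_signed == pytest.approx(-2.0, abs=0.3)
        assert sep.mean_unsigned == pytest.approx(2.0, abs=0.3)

    def test_uniform_expansion_positive_2mm(self):
        ref = as_scan(make_sphere(18.0, spacing=1.0))
        test = as_scan(make_sphere(20.0, spacing=1.0), timepoint="week_1")
        assert body_separation(ref, test).mean_signed == pytest.approx(2.0, abs=0.3)

    def test_matches_brute_force_oracle(self):
        ref = as_scan(make_sphere(12.0, spacing=2.0))
        test = as_scan(make_sphere(10.0, spacing=2.0, origin_shift=(2, 0, 0)),
                       timepoint="week_1")
        sep = body_separation(ref, test)
        oracle = brute_force_body_separation(ref, test)
        assert np.abs(np.sort(sep.distances_signed) - np.sort(oracle)).max() < 1e-6

    def test_invariant_under_common_rigid_motion(self):
        """Moving both scans with the same rigid transform leaves the
        separation metrics unchanged within resampling tolerance."""
        ref = as_scan(make_sphere(18.0, spacing=2.0, margin_mm=14.0))
        test = as_scan(make_sphere(16.0, spacing=2.0, margin_mm=16.0),
                       timepoint="week_1")
        base = body_separation(ref, test)
        T = RigidTransform([4.0, -3.0, 2.0], [2.0, 1.0, -1.5])
        moved = body_separation(
            as_scan(apply_transform(ref.body, T)),
            as_scan(apply_transform(test.body, T), timepoint="week_1"),
        )
        assert moved.mean_signed == pytest.approx(base.mean_signed, abs=0.3)
        assert moved.mean_unsigned == pytest.approx(base.mean_unsigned, abs=0.3)


class TestSurfaceSeparationInvariants:
    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-30, 30, allow_nan=False), min_size=1, max_size=50)
    )
    def test_unsigned_bounds_signed(self, values):
        sep = SurfaceSeparation(np.array(values), n_ref=len(values), n_test=0)
        assert sep.mean_unsigned >= abs(sep.mean_signed) - 1e-12

    def test_equality_iff_single_sign(self):
        same = SurfaceSeparation(np.array([1.0, 2.5, 0.5]), 3, 0)
        assert same.mean_unsigned == pytest.approx(abs(same.mean_signed))
        mixed = SurfaceSeparation(np.array([1.0, -2.5, 0.5]), 3, 0)
        assert mixed.mean_unsigned > abs(mixed.mean_signed)


class TestAnteriorMap:
    def test_box_gives_constant_map(self):
        body = make_box(half_extents_mm=(20, 15, 25), spacing=1.0)
        amap = anterior_surface_map(body, AnteriorWindow(x_fraction=0.5))
        values = amap.y_mm[np.isfinite(amap.y_mm)]
        assert np.ptp(values) == 0.0
        assert values[0] == pytest.approx(15.5)  # anterior voxel face

    def test_wall_shift_raises_map_by_shift(self, small_spec):
        base = generate_phantom_scan(small_spec, 0.0, 0.0, seed=1)
        shifted = generate_phantom_scan(small_spec, 0.0, 5.0, seed=1)
        m0 = anterior_surface_map(base.body)
        m1 = anterior_surface_map(shifted.body)
        common = m0.common_columns(m1)
        delta = m1.y_mm[common] - m0.y_mm[common]
        # peak displacement equals the wall shift within one voxel
        assert delta.max() == pytest.approx(5.0, abs=small_spec.spacing_mm)
        assert delta.min() >= -1e-9

    def test_invariant_to_posterior_edits(self):
        body = make_box(spacing=1.0)
        amap = anterior_surface_map(body)
        voxels = body.voxels.copy()
        voxels[:, :3, :] = False  # carve the posterior side
        edited = anterior_surface_map(body.with_voxels(voxels))
        assert np.array_equal(
            np.nan_to_num(amap.y_mm), np.nan_to_num(edited.y_mm)
        )

    def test_window_missing_body_rejected(self):
        body = make_box(spacing=1.0)
        with pytest.raises(ValueError, match="window"):
            anterior_surface_map(body, AnteriorWindow(z_range_mm=(500.0, 600.0)))


class TestSurfaceSeparationMaps:
    def test_identical_maps_zero(self):
        body = make_box(spacing=1.0)
        amap = anterior_surface_map(body)
        sep = surface_separation(amap, amap)
        assert sep.mean_signed == 0.0 and sep.mean_unsigned == 0.0

    def test_constant_shift_exact(self):
        body = make_box(spacing=1.0)
        ref = anterior_surface_map(body)
        import copy

        test = copy.deepcopy(ref)
        test.y_mm = test.y_mm + 3.0
        assert surface_separation(ref, test).mean_signed == pytest.approx(3.0)

    def test_only_common_columns_count(self):
        body = make_box(spacing=1.0)
        ref = anterior_surface_map(body)
        import copy

        test = copy.deepcopy(ref)
        test.y_mm = test.y_mm + 2.0
        ref_missing = copy.deepcopy(ref)
        finite_x = np.flatnonzero(np.isfinite(ref.y_mm).any(axis=1))
        ref_missing.y_mm[finite_x[:3], :] = np.nan  # one flank absent
        sep_full = surface_separation(ref, test)
        sep_partial = surface_separation(ref_missing, test)
        assert sep_partial.mean_signed == pytest.approx(sep_full.mean_signed)
        assert sep_partial.n_ref < sep_full.n_ref

    def test_disjoint_lattices_rejected(self):
        a = anterior_surface_map(make_box(spacing=1.0))
        b = anterior_surface_map(make_box(spacing=2.0))
        with pytest.raises(ValueError, match="lattice"):
            surface_separation(a, b)
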