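"""Shape-measurement oracles: closed forms, quadrature, invariances."""

import numpy as np
import pytest

from nucleomorph import (
    VoxelGrid,
    chromatin_density,
    compactness,
    elongation,
    fit_ellipsoid,
    gate_g1,
    measure_nuclei,
    measure_surface,
    measure_volume,
)
from nucleomorph.phantom import ellipsoid_surface_area

from conftest import clean_spec
from nucleomorph import generate_nucleus


class TestVolume:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        assert measure_volume(mask, (150, 120, 120)) == pytest.approx(0.00216)

    def test_sphere_volume_within_2pc(self, sphere_phantom):
        grid, mask, truth = sphere_phantom
        V = measure_volume(mask.labels == 1, grid.spacing)
        assert V == pytest.approx(truth.volume_um3, rel=0.02)

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_volume(np.zeros((3, 3, 3), bool), (150, 120, 120))


class TestSurface:
    def test_sphere_area_within_3pc(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        S = measure_surface(mask.labels == 1, grid.spacing)
        assert S == pytest.approx(4 * np.pi * 9, rel=0.03)

    def test_box_area_within_3pc(self):
        # axis-aligned box: smoothing off (it would round the sharp edges)
        spacing = np.array([150.0, 120.0, 120.0])
        nvox = np.round(np.array([3.0, 4.0, 5.0]) / (spacing / 1000)).astype(int)
        mask = np.zeros(nvox + 10, bool)
        mask[5:5 + nvox[0], 5:5 + nvox[1], 5:5 + nvox[2]] = True
        a, b, c = nvox * spacing / 1000
        S = measure_surface(mask, spacing, smoothing_vox=0.0)
        assert S == pytest.approx(2 * (a * b + b * c + a * c), rel=0.03)

    def test_doubled_resolution_converges(self):
        # same sphere voxelized twice as finely: estimate closer to 4*pi*r^2
        exact = 4 * np.pi * 9
        errs = []
        for spacing in ((150.0, 120.0, 120.0), (75.0, 60.0, 60.0)):
            shape = tuple(int(2 * 3000 / s + 14) for s in spacing)
            center = tuple(n // 2 for n in shape)
            grid, mask, _ = generate_nucleus(
                clean_spec((3.0, 3.0, 3.0), shape, center, spacing=spacing)
            )
            errs.append(abs(measure_surface(mask.labels == 1, spacing) - exact))
        assert errs[1] < errs[0]

    def test_too_small_label_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1:3, 1:3] = True  # single plane: < 2 voxels along z
        with pytest.raises(ValueError, match="too small"):
            measure_surface(mask, (150, 120, 120))


class TestCompactness:
    def test_sphere_closed_form(self):
        V, S = 4 / 3 * np.pi * 27, 4 * np.pi * 9
        C, C_norm = compactness(V, S)
        assert C == pytest.approx(1 / (36 * np.pi), rel=1e-12)
        assert C_norm == pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance_is_exact(self):
        C1, n1 = compactness(100.0, 120.0)
        C2, n2 = compactness(100.0 * 8, 120.0 * 4)  # isotropic x2
        assert C2 == pytest.approx(C1, rel=1e-12)
        assert n2 == pytest.approx(n1, rel=1e-12)

    def test_elongated_ellipsoid_below_one(self):
        # quadrature oracle for the (6, 2, 2) um ellipsoid area
        V = 4 / 3 * np.pi * 6 * 2 * 2
        S = ellipsoid_surface_area(6, 2, 2)
        _, C_norm = compactness(V, S)
        assert C_norm < 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compactness(0.0, 1.0)


class TestFitEllipsoid:
    def test_recovers_642_within_3pc(self, ellipsoid_phantom):
        grid, mask, _ = ellipsoid_phantom
        r1, r2, r3, _ = fit_ellipsoid(mask.labels == 1, grid.spacing)
        assert r1 == pytest.approx(6.0, rel=0.03)
        assert r2 == pytest.approx(4.0, rel=0.03)
        assert r3 == pytest.approx(2.0, rel=0.03)

    def test_sphere_radii_equal(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        r1, r2, r3, _ = fit_ellipsoid(mask.labels == 1, grid.spacing)
        for r in (r1, r2, r3):
            assert r == pytest.approx(3.0, rel=0.03)

    def test_rotation_invariance(self, ellipsoid_phantom, rotated_ellipsoid_phantom):
        ga, ma, _ = ellipsoid_phantom
        gb, mb, _ = rotated_ellipsoid_phantom
        ra = fit_ellipsoid(ma.labels == 1, ga.spacing)[:3]
        rb = fit_ellipsoid(mb.labels == 1, gb.spacing)[:3]
        np.testing.assert_allclose(ra, rb, rtol=0.03)

    def test_degenerate_coplanar_label_rejected(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2, 1:5, 1:5] = True  # flat sheet
        with pytest.raises(ValueError, match="degenerate"):
            fit_ellipsoid(mask, (150, 120, 120))


class TestElongation:
    @pytest.mark.parametrize(
        "r1, r2, expected", [(3.0, 3.0, 1.0), (6.0, 4.0, 1.5), (6.0, 6.0, 1.0)]
    )
    def test_ratio(self, r1, r2, expected):
        assert elongation(r1, r2) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            elongation(2.0, 0.0)
        with pytest.raises(ValueError):
            elongation(1.0, 2.0)

    def test_scale_and_rotation_invariance_on_phantom(
        self, ellipsoid_phantom, rotated_ellipsoid_phantom
    ):
        ga, ma, _ = ellipsoid_phantom
        gb, mb, _ = rotated_ellipsoid_phantom
        r1a, r2a, _, _ = fit_ellipsoid(ma.labels == 1, ga.spacing)
        r1b, r2b, _, _ = fit_ellipsoid(mb.labels == 1, gb.spacing)
        assert elongation(r1a, r2a) == pytest.approx(elongation(r1b, r2b), rel=0.03)
        # doubling the spacing doubles the radii but leaves E unchanged
        r1c, r2c, _, _ = fit_ellipsoid(
            ma.labels == 1, tuple(2 * s for s in ga.spacing)
        )
        assert elongation(r1c, r2c) == pytest.approx(elongation(r1a, r2a), rel=1e-9)


class TestChromatinDensity:
    def _uniform_nucleus(self, value=0.5):
        grid, mask, _ = generate_nucleus(
            clean_spec((2.0, 2.0, 2.0), (36, 44, 44), (18, 22, 22))
        )
        data = np.where(mask.labels > 0, value, 0.0)
        return VoxelGrid(data, grid.spacing), mask

    def test_uniform_half_intensity_gives_half(self):
        grid, mask = self._uniform_nucleus(0.5)
        region = mask.labels == 1
        V = measure_volume(region, grid.spacing)
        assert chromatin_density(grid, region, V) == pytest.approx(0.5, rel=1e-9)

    def test_zero_intensity_gives_zero(self):
        grid, mask = self._uniform_nucleus(0.0)
        region = mask.labels == 1
        V = measure_volume(region, grid.spacing)
        assert chromatin_density(grid, region, V) == 0.0

    def test_linearity_in_intensity(self):
        g1, mask = self._uniform_nucleus(0.3)
        g2 = VoxelGrid(g1.data * 2, g1.spacing)
        region = mask.labels == 1
        V = measure_volume(region, g1.spacing)
        assert chromatin_density(g2, region, V) == pytest.approx(
            2 * chromatin_density(g1, region, V), rel=1e-12
        )

    def test_bit_depth_rescaling(self):
        grid, mask = self._uniform_nucleus(0.5)
        as_uint16 = VoxelGrid(
            np.round(grid.data * 65535).astype(np.uint16), grid.spacing
        )
        region = mask.labels == 1
        V = measure_volume(region, grid.spacing)
        assert chromatin_density(as_uint16, region, V) == pytest.approx(0.5, rel=1e-4)


class TestG1Gate:
    def test_zero_marker_negative(self):
        marker = VoxelGrid(np.zeros((4, 4, 4)), (150, 120, 120))
        mask = np.ones((4, 4, 4), bool)
        assert gate_g1(marker, mask, 0.1) is False

    def test_unit_marker_positive(self):
        marker = VoxelGrid(np.ones((4, 4, 4)), (150, 120, 120))
        mask = np.ones((4, 4, 4), bool)
        assert gate_g1(marker, mask, 0.1) is True

    def test_boundary_is_inclusive(self):
        marker = VoxelGrid(np.full((4, 4, 4), 0.25), (150, 120, 120))
        mask = np.ones((4, 4, 4), bool)
        assert gate_g1(marker, mask, 0.25) is True

    def test_misaligned_shapes_rejected(self):
        marker = VoxelGrid(np.zeros((4, 4, 4)), (150, 120, 120))
        with pytest.raises(ValueError, match="aligned"):
            gate_g1(marker, np.ones((3, 3, 3), bool), 0.1)


class TestMeasureNuclei:
    def test_full_record_against_truth(self, ellipsoid_phantom):
        grid, mask, truth = ellipsoid_phantom
        rec = measure_nuclei(grid, mask)[0]
        assert rec.volume_um3 == pytest.approx(truth.volume_um3, rel=0.02)
        assert rec.surface_um2 == pytest.approx(truth.surface_um2, rel=0.03)
        assert rec.elongation == pytest.approx(truth.elongation, rel=0.03)
        assert rec.compactness_norm == pytest.approx(truth.compactness_norm, rel=0.08)
        assert rec.g1_positive is None

    def test_marker_channel_sets_g1_flag(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        marker = VoxelGrid(
            np.where(mask.labels > 0, 0.9, 0.0), grid.spacing, "CDT1"
        )
        rec = measure_nuclei(grid, mask, marker=marker)[0]
        assert rec.g1_positive is True
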