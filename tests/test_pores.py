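"""Rim-curvature protocol: alignment, en-face search, measurement."""

import numpy as np
import pytest

from nemorph.core import VoxelGrid
from nemorph.pores import (
    MeasurementError,
    PoreClip,
    PoreMeasurement,
    align_envelope_to_x,
    angle_bias_check,
    extract_clip,
    find_en_face_angle,
    lumen_circularity,
    measure_rim_and_pore,
    to_perpendicular_view,
)
from nemorph.synthetic import SceneSpec, make_pore_volume


def _phantom(tilt, azimuth, rim=26.0, pore=80.0, noise=0.05, seed=5, n=81):
    spec = SceneSpec(volume_shape=(n, n, n), voxel_size=(3.0, 3.0, 3.0),
                     pore_specs=[(rim, pore, tilt, azimuth)], noise_sd=noise, seed=seed)
    grid, truth = make_pore_volume(spec)
    return PoreClip(grid=grid, center=tuple(truth.pores.loc[0, ["z", "y", "x"]]))


def _angle_error(a, b):
    """Angular distance modulo 180, sign-agnostic (mirror-equivalent views)."""
    d1 = abs((a - b + 90.0) % 180.0 - 90.0)
    d2 = abs((a + b + 90.0) % 180.0 - 90.0)
    return min(d1, d2)


@pytest.fixture(scope="module")
def volume():
    rng = np.random.default_rng(0)
    return VoxelGrid(rng.uniform(0, 1, (320, 320, 320)).astype(np.float32),
                     (0.75, 0.75, 0.75))


class TestExtractClip:
    def test_clip_shape_after_binning(self, volume):
        clip = extract_clip(volume, (120.0, 120.0, 120.0), 120.0, bin_factor=4)
        assert clip.grid.shape == (80, 80, 80)
        assert clip.grid.voxel_size == pytest.approx((3.0, 3.0, 3.0))
        assert clip.grid.data.dtype == np.uint8

    def test_edge_pore_rejected(self, volume):
        with pytest.raises(MeasurementError, match="enclosed"):
            extract_clip(volume, (30.0, 120.0, 120.0), 120.0)

    def test_deterministic(self, volume):
        a = extract_clip(volume, (120.0, 120.0, 120.0), 90.0)
        b = extract_clip(volume, (120.0, 120.0, 120.0), 90.0)
        np.testing.assert_array_equal(a.grid.data, b.grid.data)


class TestAlignment:
    def test_already_aligned_identity(self):
        clip = _phantom(30.0, 0.0)
        out = align_envelope_to_x(clip)
        assert abs(out.applied_rotations[-1][1]) <= 1.0

    def test_in_plane_tilt_recovered(self):
        clip = _phantom(30.0, 17.0)
        out = align_envelope_to_x(clip)
        assert out.applied_rotations[-1][0] == "z"
        assert _angle_error(out.applied_rotations[-1][1], -17.0) <= 2.0

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(1)
        clip = PoreClip(
            grid=VoxelGrid(rng.uniform(0, 1, (40, 40, 40)), (3.0, 3.0, 3.0)),
            center=(60.0, 60.0, 60.0),
        )
        with pytest.raises(MeasurementError):
            align_envelope_to_x(clip)


class TestEnFaceSearch:
    @pytest.mark.parametrize("tilt", [0.0, 30.0, 40.0])
    def test_known_tilt_recovered_within_half_step(self, tilt):
        clip = align_envelope_to_x(_phantom(tilt, 0.0))
        angle, profile = find_en_face_angle(clip, step_deg=10.0)
        assert _angle_error(angle, tilt) <= 5.0
        assert len(profile) == 18

    def test_rasterized_disc_circularity_near_one(self):
        yy, xx = np.mgrid[0:61, 0:61]
        img = np.where((yy - 30) ** 2 + (xx - 30) ** 2 <= 20 ** 2, 0.0, 1.0)
        # bright lumen inside a dark surround: invert to match pore contrast
        c = lumen_circularity(1.0 - img)
        assert 0.9 <= c <= 1.05

    def test_unaligned_clip_rejected(self):
        with pytest.raises(MeasurementError, match="align"):
            find_en_face_angle(_phantom(0.0, 0.0))

    def test_no_lumen_errors(self):
        # intact envelope, no pore: tiny fenestration fully blurred away
        spec = SceneSpec(volume_shape=(61, 61, 61), voxel_size=(3.0, 3.0, 3.0),
                        pore_specs=[(26.0, 80.0, 0.0, 0.0)], noise_sd=0.0, seed=0)
        grid, _ = make_pore_volume(spec)
        flat = grid.data.copy()
        flat[:, :, :] = flat[:, :1, :]  # collapse to featureless bands: no ring
        clip = PoreClip(grid=VoxelGrid(flat, (3.0, 3.0, 3.0)), center=(90.0,) * 3,
                        aligned=True)
        with pytest.raises(MeasurementError):
            find_en_face_angle(clip)


class TestPerpendicularView:
    def test_en_face_90_is_net_zero(self):
        clip = align_envelope_to_x(_phantom(90.0, 0.0))
        perp = to_perpendicular_view(clip, 90.0)
        assert perp.applied_rotations[-1] == ("x", 0.0)

    def test_double_application_flagged(self):
        clip = align_envelope_to_x(_phantom(0.0, 0.0))
        perp = to_perpendicular_view(clip, 0.0)
        with pytest.raises(MeasurementError, match="already"):
            to_perpendicular_view(perp, 0.0)

    def test_bands_interrupted_by_pore_in_central_slice(self):
        clip = align_envelope_to_x(_phantom(0.0, 0.0, noise=0.0))
        perp = to_perpendicular_view(clip, 0.0)
        sl = perp.grid.data[40]
        dark = sl < 0.5
        # two bands away from the pore axis ...
        assert dark[:, 10].sum() >= 2 and dark[:, 70].sum() >= 2
        # ... interrupted around the pore axis
        assert dark[35:46, 38:43].sum() == 0


@pytest.fixture(scope="module")
def measured():
    clip = align_envelope_to_x(_phantom(30.0, 0.0))
    angle, _ = find_en_face_angle(clip)
    perp = to_perpendicular_view(clip, angle)
    return measure_rim_and_pore(perp, en_face_angle=angle)


class TestMeasurement:
    def test_rim_diameters_within_3nm(self, measured):
        assert measured.rim_diameter_i == pytest.approx(26.0, abs=3.0)
        assert measured.rim_diameter_ii == pytest.approx(26.0, abs=3.0)

    def test_sides_agree_within_voxel(self, measured):
        assert abs(measured.rim_diameter_i - measured.rim_diameter_ii) <= 3.0

    def test_pore_diameter_reasonable(self, measured):
        assert measured.pore_diameter == pytest.approx(80.0, abs=6.0)

    def test_kappa_is_exactly_two_over_rd(self, measured):
        assert measured.kappa_i == 2.0 / measured.rim_diameter_i
        assert measured.kappa_i * measured.rim_diameter_i == pytest.approx(2.0, abs=1e-12)

    def test_kappa_decreasing_in_rd(self):
        m = [PoreMeasurement(0, 0.0, rd, rd, 80.0) for rd in (20.0, 26.0, 33.0)]
        kappas = [x.kappa_i for x in m]
        assert kappas == sorted(kappas, reverse=True)

    def test_flat_membranes_no_pore_error(self):
        # two intact parallel dark bands, no fenestration anywhere
        flat = np.ones((61, 61, 61), dtype=np.float32)
        r = 13.0 / 3.0
        for row in (30 - int(round(r)), 30 + int(round(r))):
            flat[:, row - 1: row + 2, :] = 0.0
        clip = PoreClip(grid=VoxelGrid(flat, (3.0, 3.0, 3.0)), center=(90.0,) * 3,
                        aligned=True, perpendicular=True)
        with pytest.raises(MeasurementError, match="no pore"):
            measure_rim_and_pore(clip)

    def test_requires_perpendicular_view(self):
        clip = align_envelope_to_x(_phantom(0.0, 0.0))
        with pytest.raises(MeasurementError, match="perpendicular"):
            measure_rim_and_pore(clip)

    def test_tilt_equivariance_noise_free(self):
        rds = []
        for tilt in (0.0, 20.0, 40.0):
            clip = align_envelope_to_x(_phantom(tilt, 0.0, noise=0.0))
            angle, _ = find_en_face_angle(clip)
            m = measure_rim_and_pore(to_perpendicular_view(clip, angle),
                                     en_face_angle=angle)
            rds.append((m.rim_diameter_i + m.rim_diameter_ii) / 2.0)
        assert max(rds) - min(rds) <= 3.0  # one working-voxel pitch


class TestAngleBias:
    def test_proportional_rim_gives_unit_correlation(self):
        ms = [PoreMeasurement(i, a, 20.0 + a / 10.0, 20.0 + a / 10.0, 80.0 + a)
              for i, a in enumerate([10.0, 40.0, 90.0, 130.0])]
        res = angle_bias_check(ms)
        assert res.r_rim == pytest.approx(1.0)
        assert res.r_pore == pytest.approx(1.0)

    def test_two_points_rejected(self):
        ms = [PoreMeasurement(0, 10.0, 26.0, 26.0, 80.0),
              PoreMeasurement(1, 40.0, 27.0, 27.0, 81.0)]
        with pytest.raises(ValueError):
            angle_bias_check(ms)

    def test_zero_variance_flagged(self):
        ms = [PoreMeasurement(i, a, 26.0, 26.0, 80.0) for i, a in
              enumerate([10.0, 40.0, 90.0])]
        assert angle_bias_check(ms).degenerate
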