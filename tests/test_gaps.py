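"""Gap detection, size classification and vicinity density statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from nemorph.gaps import (
    CLASS_ORDER,
    classify_gap,
    density_comparison,
    find_gaps,
    random_control_points,
    sample_vicinity,
)


class TestClassification:
    @pytest.mark.parametrize("area,expected", [
        (8_000.0, "small"),      # inside the printed small range
        (50_000.0, "medium"),    # inside the printed medium range
        (200_000.0, "large"),    # inside the printed large range
        (10_000.0, "small"),     # dead zone, below midpoint threshold
        (95_000.0, "large"),     # dead zone, above midpoint threshold
    ])
    def test_default_thresholds(self, area, expected):
        assert classify_gap(area) == expected

    @pytest.mark.parametrize("area,expected", [
        (8_000.0, "small"), (50_000.0, "medium"), (200_000.0, "large"),
        (10_000.0, "unclassified"), (95_000.0, "unclassified"),
    ])
    def test_strict_ranges_expose_dead_zones(self, area, expected):
        assert classify_gap(area, strict=True) == expected

    def test_monotone_in_area(self):
        areas = np.linspace(1_000, 400_000, 500)
        ranks = [CLASS_ORDER[classify_gap(a)] for a in areas]
        assert ranks == sorted(ranks)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            classify_gap(0.0)


class TestFindGaps:
    def test_phantom_gap_recovered_within_voxel(self, small_scene):
        spec, _, labels, truth = small_scene
        records = find_gaps(labels, ne_label=1, max_edge_separation=140.0)
        assert len(records) == len(truth.gaps) == 2
        vx, vz = labels.voxel_size[2], labels.voxel_size[0]
        got = sorted(records, key=lambda r: r.dx)
        want = truth.gaps.sort_values("dx")
        for rec, (_, row) in zip(got, want.iterrows()):
            assert abs(rec.dx - row["dx"]) <= vx
            assert abs(rec.dz - row["dz"]) <= vz
            assert rec.area == pytest.approx(rec.dx * rec.dz)  # exact product

    def test_intact_envelope_yields_no_gaps(self, small_scene):
        spec, *_ = small_scene
        from nemorph.synthetic import SceneSpec, make_telophase_scene

        intact = SceneSpec(**{**spec.__dict__, "gap_specs": [], "vesicle_count": 0})
        _, labels, _ = make_telophase_scene(intact)
        assert find_gaps(labels, 1) == []

    def test_wide_discontinuities_not_counted(self, small_scene):
        spec, _, labels, _ = small_scene
        # both phantom gaps are narrower than 140 nm; a 50 nm ceiling drops one
        narrow = find_gaps(labels, 1, max_edge_separation=50.0)
        assert len(narrow) < 2 or all(r.dx <= 50.0 for r in narrow)

    def test_missing_ne_label_raises(self, small_scene):
        _, _, labels, _ = small_scene
        with pytest.raises(ValueError, match="absent"):
            find_gaps(labels, ne_label=9)


class TestVicinity:
    def test_distance_partition(self):
        center = (0.0, 0.0, 0.0)
        pts = np.array([[0, 0, 300], [0, 400, 0], [800, 0, 0]], dtype=float)
        f = sample_vicinity(center, pts)
        assert (f.close_count, f.far_count) == (2, 1)

    def test_empty_scene_zero_densities(self):
        f = sample_vicinity((0, 0, 0), np.empty((0, 3)))
        assert f.close_density == f.far_density == 0.0

    def test_density_normalisation(self):
        # one vesicle in the close disc: density = 1 / (pi * 0.5^2) um^-2
        f = sample_vicinity((0, 0, 0), np.array([[0.0, 0.0, 100.0]]))
        assert f.close_density == pytest.approx(1.0 / (np.pi * 0.25))

    def test_rotation_invariance_about_center(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-900, 900, (200, 3))
        theta = np.deg2rad(37.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        a = sample_vicinity((0, 0, 0), pts)
        b = sample_vicinity((0, 0, 0), pts @ rot.T)
        assert (a.close_count, a.far_count) == (b.close_count, b.far_count)

    def test_uniform_field_equal_densities(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1000, 1000, (40_000, 3))
        f = sample_vicinity((0, 0, 0), pts, projected_2d=True)
        assert f.close_density == pytest.approx(f.far_density, rel=0.1)

    def test_bad_radii(self):
        with pytest.raises(ValueError):
            sample_vicinity((0, 0, 0), np.empty((0, 3)), radius=400, close_radius=500)


class TestControls:
    def test_deterministic_for_seed(self, small_scene):
        _, _, labels, _ = small_scene
        a = random_control_points(labels, 5, seed=7, min_separation=100.0)
        b = random_control_points(labels, 5, seed=7, min_separation=100.0)
        assert a == b

    def test_points_lie_on_ne(self, small_scene):
        _, _, labels, _ = small_scene
        (p,) = random_control_points(labels, 1, seed=3, min_separation=50.0)
        idx = tuple(int(round(c / v)) for c, v in zip(p, labels.voxel_size))
        assert labels.labels[idx] == 1

    def test_infeasible_separation_raises(self, small_scene):
        _, _, labels, _ = small_scene
        with pytest.raises(RuntimeError):
            random_control_points(labels, 10, seed=1, min_separation=5_000.0)

    def test_exclusion_zone_respected(self, small_scene):
        _, _, labels, _ = small_scene
        excl = [(300.0, 190.0, 450.0)]
        pts = random_control_points(labels, 4, seed=2, min_separation=50.0,
                                    exclusion_centers=excl, exclusion_radius=400.0)
        for p in pts:
            assert np.linalg.norm(np.subtract(p, excl[0])) >= 400.0


class TestDensityComparison:
    @staticmethod
    def _fields(densities_by_group, rng):
        from nemorph.gaps import SamplingField

        fields = []
        for group, mean in densities_by_group.items():
            for _ in range(10):
                f = SamplingField(center=(0, 0, 0), kind="gap_endpoint")
                f.close_density = max(rng.normal(mean, 0.5), 0.0)
                f.far_density = max(rng.normal(mean / 2, 0.5), 0.0)
                f.group = group
                fields.append(f)
        return fields

    def test_constructed_enrichment_detected(self):
        rng = np.random.default_rng(5)
        fields = self._fields({"large": 10.0, "medium": 2.2, "control": 2.0}, rng)
        comp = density_comparison(fields)["close"]
        assert comp.pair_p("large", "control") < 0.001
        assert comp.pair_p("medium", "control") > 0.05

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(6)
        fields = self._fields({"a": 4.0, "b": 4.0}, rng)
        comp = density_comparison(fields)["close"]
        assert comp.pair_p("a", "b") > 0.05

    def test_two_group_anova_equals_t_test(self):
        rng = np.random.default_rng(7)
        fields = self._fields({"a": 4.0, "b": 5.0}, rng)
        comp = density_comparison(fields)["close"]
        a = [f.close_density for f in fields if f.group == "a"]
        b = [f.close_density for f in fields if f.group == "b"]
        t = sps.ttest_ind(a, b)
        assert comp.omnibus_p == pytest.approx(t.pvalue, rel=1e-9)  # F = t^2

    def test_insufficient_groups_rejected(self):
        rng = np.random.default_rng(8)
        fields = self._fields({"a": 4.0}, rng)
        with pytest.raises(ValueError):
            density_comparison(fields)
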