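"""Phantom generators: voxelization oracles, contour ground truth, cohorts."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from villimorph import phantoms
from villimorph.datatypes import BACKGROUND, CAPILLARY, STROMA, TROPHOBLAST
from villimorph.errors import (BoundsError, ConfigurationError,
                               FeasibilityError, GeometryError)


def brute_force_sphere_count(radius, voxel_size, shape, center):
    """Independent lattice-point census: voxel centres strictly inside."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                z = (i + 0.5) * voxel_size - center[0]
                y = (j + 0.5) * voxel_size - center[1]
                x = (k + 0.5) * voxel_size - center[2]
                if z * z + y * y + x * x < radius * radius:
                    count += 1
    return count


class TestPrimitives:
    def test_sphere_voxel_count_matches_lattice_census(self, sphere48):
        spec, volume, _ = sphere48
        shape = volume.labels.shape
        center = tuple(s * spec.voxel_size / 2 for s in shape)
        expected = brute_force_sphere_count(spec.radius, spec.voxel_size,
                                            shape, center)
        assert int(volume.foreground().sum()) == expected
        # ≈ (4/3)π(R/h)³ up to lattice rounding
        continuum = 4 / 3 * math.pi * (spec.radius / spec.voxel_size) ** 3
        assert expected == pytest.approx(continuum, rel=0.03)

    def test_sphere_ground_truth_closed_form(self, sphere48):
        spec, _, truth = sphere48
        assert truth.volume == pytest.approx(4 / 3 * math.pi * 48**3)
        assert truth.surface_area == pytest.approx(4 * math.pi * 48**2)
        # SA:V of a sphere is 3/R: 62.5 mm^-1 at R = 48 µm
        assert truth.sa_to_v == pytest.approx(62.5)

    def test_capped_cylinder_ground_truth_closed_form(self):
        spec = phantoms.PrimitiveSpec("capped_cylinder", radius=25.0,
                                      length=500.0, voxel_size=2.5)
        volume, truth = phantoms.make_primitive_label(spec)
        r, length = 25.0, 500.0
        assert truth.volume == pytest.approx(
            math.pi * r**2 * length + 4 / 3 * math.pi * r**3)
        assert truth.surface_area == pytest.approx(
            2 * math.pi * r * length + 4 * math.pi * r**2)
        # voxelized volume tracks the analytic one
        measured = volume.foreground().sum() * spec.voxel_size**3
        assert measured == pytest.approx(truth.volume, rel=0.02)

    def test_primitive_exceeding_grid_raises(self):
        spec = phantoms.PrimitiveSpec("sphere", radius=48.0, voxel_size=4.8,
                                      grid_shape=(12, 12, 12))
        with pytest.raises(BoundsError):
            phantoms.make_primitive_label(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            phantoms.PrimitiveSpec("cube", radius=1, voxel_size=1)
        with pytest.raises(ConfigurationError):
            phantoms.PrimitiveSpec("capped_cylinder", radius=1, voxel_size=1)


class TestCrossSections:
    def test_smooth_section_pa_is_2_over_r(self):
        spec = phantoms.CrossSectionSpec(outer_radius=28.0,
                                         trophoblast_thickness=8.0,
                                         pixel_size=0.5)
        _, truth = phantoms.make_cross_section(spec)
        # basal contour is a circle of radius 20 µm → P:A = 2/r = 0.1 µm⁻¹
        assert truth.pa == pytest.approx(0.1, rel=1e-5)

    def test_ground_truth_matches_shoelace_oracle(self):
        spec = phantoms.CrossSectionSpec(
            outer_radius=60.0, trophoblast_thickness=15.0,
            invagination_count=9, invagination_depth=18.0,
            invagination_width=10.0, pixel_size=0.5)
        truth = phantoms.contour_ground_truth(spec)
        v = phantoms.basal_contour_vertices(spec)
        x, y = v[:, 0], v[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        seglen = float(np.hypot(*(v - np.roll(v, -1, axis=0)).T).sum())
        assert truth.inner_area == pytest.approx(shoelace, rel=1e-9)
        assert truth.inner_perimeter == pytest.approx(seglen, rel=1e-9)

    def test_invaginations_raise_pa_at_equal_area(self, equal_area_pair):
        smooth_truth = equal_area_pair["smooth"][2]
        invag_truth = equal_area_pair["invaginated"][2]
        # rel 1e-5 absorbs the inscribed-polygon area deficit of the
        # 2048-vertex contour (~2π²/3n² ≈ 1.6e-6)
        assert invag_truth.inner_area == pytest.approx(smooth_truth.inner_area,
                                                       rel=1e-5)
        assert invag_truth.pa > smooth_truth.pa

    def test_labels_partition_grid(self, equal_area_pair):
        _, cross, _ = equal_area_pair["invaginated"]
        present = set(np.unique(cross.labels))
        assert present == {BACKGROUND, TROPHOBLAST, STROMA, CAPILLARY}

    def test_overlapping_capillaries_rejected(self):
        with pytest.raises(GeometryError, match="overlap"):
            phantoms.make_cross_section(phantoms.CrossSectionSpec(
                outer_radius=40.0, trophoblast_thickness=10.0,
                capillary_centers=((0.0, 0.0), (4.0, 0.0)),
                capillary_radius=5.0, pixel_size=0.5))

    def test_capillary_crossing_basal_contour_rejected(self):
        with pytest.raises(GeometryError, match="basal"):
            phantoms.make_cross_section(phantoms.CrossSectionSpec(
                outer_radius=40.0, trophoblast_thickness=10.0,
                capillary_centers=((27.0, 0.0),), capillary_radius=5.0,
                pixel_size=0.5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(count=st.integers(0, 16), depth_frac=st.floats(0.05, 0.6),
           r_basal=st.floats(10.0, 60.0))
    def test_contour_truth_consistent_for_random_specs(self, count, depth_frac,
                                                       r_basal):
        """Property: shapely ground truth ≡ shoelace/arc-length on vertices."""
        spec = phantoms.CrossSectionSpec(
            outer_radius=r_basal * 1.3, trophoblast_thickness=r_basal * 0.3,
            invagination_count=count,
            invagination_depth=depth_frac * r_basal if count else 0.0,
            invagination_width=max(0.15 * 2 * math.pi * r_basal / count, 1.0)
            if count else 0.0,
            pixel_size=1.0)
        truth = phantoms.contour_ground_truth(spec)
        v = phantoms.basal_contour_vertices(spec)
        x, y = v[:, 0], v[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert truth.inner_area == pytest.approx(shoelace, rel=1e-9)
        assert truth.pa >= 2.0 / r_basal * (1 - 1e-6)  # circle minimizes P:A


class TestRenderIntensity:
    def test_zero_noise_reproduces_class_means(self, equal_area_pair):
        _, cross, _ = equal_area_pair["smooth"]
        img = phantoms.render_intensity(
            cross, {0: 10.0, 1: 80.0, 2: 150.0, 3: 220.0}, noise_sd=0.0)
        for value, mean in ((0, 10.0), (1, 80.0), (2, 150.0), (3, 220.0)):
            assert np.all(img.values[cross.labels == value] == mean)

    def test_same_seed_is_bitwise_identical(self, equal_area_pair):
        _, cross, _ = equal_area_pair["smooth"]
        means = {0: 50.0, 1: 200.0, 2: 200.0, 3: 200.0}
        a = phantoms.render_intensity(cross, means, noise_sd=10.0, seed=7)
        b = phantoms.render_intensity(cross, means, noise_sd=10.0, seed=7)
        c = phantoms.render_intensity(cross, means, noise_sd=10.0, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_missing_class_mean_rejected(self, equal_area_pair):
        _, cross, _ = equal_area_pair["smooth"]
        with pytest.raises(ConfigurationError, match="class mean"):
            phantoms.render_intensity(cross, {0: 50.0, 1: 200.0}, noise_sd=1.0)


class TestCohort:
    def test_study_cohort_hits_group_targets(self):
        cohort = phantoms.make_cohort(phantoms.study_cohort_spec(seed=3),
                                      rasterize=False)
        t = cohort.table
        per_placenta = t.groupby(["group", "placenta_id"]).mean(numeric_only=True)
        means = per_placenta.groupby("group").mean()
        assert means.loc["equid", "sa_to_v_mm_inv"] == pytest.approx(73.47, rel=0.10)
        assert means.loc["human", "sa_to_v_mm_inv"] == pytest.approx(43.34, rel=0.10)
        assert means.loc["equid", "pa_um_inv"] == pytest.approx(0.24, rel=0.10)
        assert means.loc["human", "pa_um_inv"] == pytest.approx(0.12, rel=0.10)
        assert (t[t.group == "equid"].groupby("placenta_id").size() >= 5).all()

    def test_zero_spread_gives_identical_villi(self):
        spec = phantoms.CohortSpec(
            groups=(phantoms.GroupSpec("g", 2, 3, 50.0, 0.0, 0.1, 0.0),),
            seed=0, within_placenta_cv=0.0)
        table = phantoms.make_cohort(spec, rasterize=False).table
        assert table["sa_to_v_mm_inv"].nunique() == 1
        assert table["pa_um_inv"].nunique() == 1

    def test_same_seed_reproduces_table_bitwise(self):
        spec = phantoms.study_cohort_spec(seed=11)
        a = phantoms.make_cohort(spec, rasterize=False).table
        b = phantoms.make_cohort(spec, rasterize=False).table
        assert a.equals(b)
        assert a.to_csv() == b.to_csv()

    def test_unresolvable_sa_to_v_target_raises(self):
        spec = phantoms.CohortSpec(
            groups=(phantoms.GroupSpec("g", 1, 1, 400.0, 0.0, 0.1, 0.0),),
            seed=0, voxel_size=4.8, within_placenta_cv=0.0)
        with pytest.raises(FeasibilityError):
            phantoms.make_cohort(spec, rasterize=False)

    def test_rasterized_cohort_produces_artifacts(self):
        spec = phantoms.CohortSpec(
            groups=(phantoms.GroupSpec("g", 1, 2, 60.0, 5.0, 0.15, 0.01,
                                       invagination_count=6),),
            seed=0, pixel_size=0.5)
        cohort = phantoms.make_cohort(spec, rasterize=True)
        assert len(cohort.volumes) == 2
        assert len(cohort.cross_sections) == 2
        assert cohort.volumes[0].voxel_size == 4.8
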