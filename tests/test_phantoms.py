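"""Phantom construction: masks, ratios, catalog counts, emission sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from comptoncam.grids import GridSpec, ImageVolume
from comptoncam.phantoms import (
    ConcentrationRatio,
    RigidTransform,
    TumorGeometrySpec,
    default_rototranslations,
    enumerate_catalog,
    load_default_catalog,
    make_body_cylinder,
    make_source_distribution,
    rototranslate,
    sample_emission_points,
)


@pytest.fixture(scope="module")
def grid():
    return GridSpec.default()


@pytest.fixture(scope="module")
def body(grid):
    return make_body_cylinder(grid)


class TestBodyCylinder:
    def test_volume_matches_analytic(self, body, grid):
        analytic = np.pi * 30.0**2 * 100.0 / np.prod(grid.spacing)
        assert body.values.sum() == pytest.approx(analytic, rel=0.10)

    def test_zero_radius_empty(self, grid):
        assert make_body_cylinder(grid, radius=0.0).values.sum() == 0

    def test_mirror_symmetry(self, body):
        assert np.array_equal(body.values, body.values[::-1, :, :])
        assert np.array_equal(body.values, body.values[:, ::-1, :])

    def test_oversized_cylinder_clipped_with_warning(self, grid, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            vol = make_body_cylinder(grid, radius=100.0, height=500.0)
        assert "clipped" in caplog.text
        assert vol.values.max() == 1.0


class TestSourceDistribution:
    tumor = TumorGeometrySpec("sphere", {"radius": 10.0})

    def test_infinite_ratio_zero_normal_tissue(self, body):
        vol = make_source_distribution(body, self.tumor, math.inf)
        tmask = self.tumor.voxelize(body.grid)
        bmask = (body.values > 0) & ~tmask
        assert np.all(vol.values[tmask] == 1.0)
        assert np.all(vol.values[bmask] == 0.0)

    def test_ratio_four_gives_quarter(self, body):
        vol = make_source_distribution(body, self.tumor, 4.0)
        bmask = (body.values > 0) & ~self.tumor.voxelize(body.grid)
        assert np.all(vol.values[bmask] == 0.25)
        assert vol.values.max() == 1.0

    def test_ratio_one_uniform(self, body):
        vol = make_source_distribution(body, self.tumor, 1.0)
        inside = vol.values[body.values > 0]
        assert np.all(inside == 1.0)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationRatio(0.5)

    def test_tumor_outside_body_rejected(self, body):
        far = TumorGeometrySpec(
            "sphere", {"radius": 5.0},
            RigidTransform.from_euler_z_translation(0.0, (29.0, 0.0, 0.0)),
        )
        with pytest.raises(ValueError, match="voxel"):
            make_source_distribution(body, far, 4.0)

    def test_empty_tumor_rejected(self, body):
        tiny = TumorGeometrySpec("sphere", {"radius": 0.1})
        with pytest.raises(ValueError, match="empty"):
            make_source_distribution(body, tiny, 4.0)


class TestRototranslation:
    tumor = TumorGeometrySpec("box", {"half_sizes": [8.0, 8.0, 8.0]})

    def test_identity_preserves_mask(self, grid):
        moved = rototranslate(self.tumor, RigidTransform.identity())
        assert np.array_equal(moved.voxelize(grid), self.tumor.voxelize(grid))

    def test_full_turn_preserves_mask(self, grid):
        moved = rototranslate(
            self.tumor, RigidTransform.from_euler_z_translation(360.0)
        )
        assert np.array_equal(moved.voxelize(grid), self.tumor.voxelize(grid))

    def test_one_voxel_translation_is_integer_shift(self, grid):
        moved = rototranslate(
            self.tumor,
            RigidTransform.from_euler_z_translation(0.0, (grid.spacing[0], 0, 0)),
        )
        ref = np.roll(self.tumor.voxelize(grid), 1, axis=0)
        ref[0, :, :] = False
        assert np.array_equal(moved.voxelize(grid), ref)

    def test_composition_order(self, grid):
        t1 = RigidTransform.from_euler_z_translation(90.0)
        t2 = RigidTransform.from_euler_z_translation(0.0, (4.0, 0.0, 0.0))
        once = rototranslate(rototranslate(self.tumor, t1), t2)
        composed = rototranslate(self.tumor, t2.compose(t1))
        assert np.array_equal(once.voxelize(grid), composed.voxelize(grid))


class TestCatalog:
    def test_full_scale_counts(self):
        base = enumerate_catalog(17, (3.0, 4.0, 5.0, math.inf), 3)
        assert len(base) == 71
        full = enumerate_catalog(
            17, (3.0, 4.0, 5.0, math.inf), 3,
            rototranslations=default_rototranslations(),
        )
        assert len(full) == 355

    def test_empty_catalog(self):
        assert enumerate_catalog(0, (), 0) == []

    def test_default_geometries_count_and_validity(self):
        geoms = load_default_catalog()
        assert len(geoms) == 20

    def test_all_catalog_entries_fit_in_body(self):
        """Every geometry x ratio x rototranslation stays inside the body."""
        grid = GridSpec.default(shape=(40, 40, 80))
        body = make_body_cylinder(grid)
        for spec in enumerate_catalog(rototranslations=default_rototranslations()):
            vol = make_source_distribution(body, spec.geometry, spec.ratio)
            assert vol.values.max() == 1.0


class TestEmissionSampling:
    def test_single_hot_voxel_confines_points(self, grid, rng):
        vals = np.zeros(grid.shape)
        vals[3, 4, 5] = 1.0
        pts = sample_emission_points(ImageVolume(grid, vals), 500, rng)
        lo = np.array(grid.origin) + np.array([3, 4, 5]) * grid.spacing[0] - 2.0
        assert np.all(pts >= lo - 1e-9) and np.all(pts <= lo + 4.0 + 1e-9)

    def test_zero_count(self, grid, rng):
        vals = np.zeros(grid.shape)
        vals[0, 0, 0] = 1.0
        assert sample_emission_points(ImageVolume(grid, vals), 0, rng).shape == (0, 3)

    def test_all_zero_source_rejected(self, grid, rng):
        with pytest.raises(ValueError):
            sample_emission_points(ImageVolume.zeros(grid), 10, rng)

    def test_two_voxel_ratio(self, grid, rng):
        """3:1 activity -> 3:1 counts within the binomial 99% interval."""
        vals = np.zeros(grid.shape)
        vals[0, 0, 0] = 3.0
        vals[10, 10, 10] = 1.0
        n = 100_000
        pts = sample_emission_points(ImageVolume(grid, vals), n, rng)
        n_hot = int(np.sum(pts[:, 0] < grid.origin[0] + 2.0))
        lo, hi = stats.binom.interval(0.99, n, 0.75)
        assert lo <= n_hot <= hi

    def test_chi_square_goodness_of_fit(self, rng):
        """Sampled voxel frequencies match an 8-voxel activity map."""
        g = GridSpec(shape=(2, 2, 2), spacing=(1, 1, 1))
        weights = np.arange(1.0, 9.0).reshape(2, 2, 2)
        vol = ImageVolume(g, weights)
        n = 1_000_000
        pts = sample_emission_points(vol, n, rng)
        ijk = np.floor(pts - np.array(g.origin) + 0.5).astype(int)
        idx = np.ravel_multi_index(ijk.T, g.shape)
        counts = np.bincount(idx, minlength=8)
        expected = weights.ravel() / weights.sum() * n
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.01
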