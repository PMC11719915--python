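"""Detector geometry and the analytic Monte-Carlo event generator."""

import numpy as np
import pytest
from scipy import stats

from comptoncam.detector import standard_geometry
from comptoncam.grids import GridSpec, ImageVolume
from comptoncam.kinematics import CONSTANTS, scattering_angle
from comptoncam.simulate import (
    EventList,
    energy_window_filter,
    klein_nishina_sample,
    simulate_events,
)
from comptoncam.simulate import _kn_density_unnormalized

EG = CONSTANTS.source_photon_energy


class TestGeometry:
    def test_single_module_has_four_crystals(self, single_module):
        assert single_module.n_crystals == 4

    def test_four_module_has_sixteen_crystals(self, four_module):
        assert four_module.n_crystals == 16

    def test_rotated_modules_front_faces_at_60mm(self, four_module):
        """Module-frame origins (front-face centers) sit 60 mm off-axis."""
        for module in four_module.modules[:2]:
            front = min(module, key=lambda s: np.hypot(*s.center[:2]))
            local_front = front.center - front.orientation @ np.array([0, 0, 2.5])
            assert np.hypot(*local_front[:2]) == pytest.approx(60.0, abs=1e-9)

    def test_translated_modules_offset_along_axis(self, four_module):
        z_offsets = sorted(m[0].center[2] for m in four_module.modules[2:])
        assert z_offsets == [-10.0, 10.0]

    def test_slab_containment_and_ray_intersection(self, single_module):
        slab = single_module.crystals[0]
        assert slab.contains(slab.center[None])[0]
        # ray through the slab center along x
        lo, hi = slab.ray_intersect(
            np.array([[0.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]])
        )
        assert hi[0] - lo[0] == pytest.approx(5.0)  # 5 mm thickness along x


class TestKleinNishina:
    def test_samples_in_range(self, rng):
        th = klein_nishina_sample(EG, rng, 1000)
        assert np.all((th >= 0) & (th <= np.pi))

    def test_histogram_matches_density(self, rng):
        """Chi-square of 2e5 draws against the analytic angular density."""
        n = 200_000
        th = klein_nishina_sample(EG, rng, n)
        edges = np.linspace(-1, 1, 41)
        counts, _ = np.histogram(np.cos(th), bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = _kn_density_unnormalized(EG, centers)
        expected = dens / dens.sum() * n
        # renormalize exactly for the test's binning
        p = stats.chisquare(counts, expected * counts.sum() / expected.sum()).pvalue
        assert p > 0.01

    def test_low_energy_limit_is_thomson(self, rng):
        """As the photon softens the angular law tends to 1 + cos^2."""
        n = 100_000
        th = klein_nishina_sample(1e-6, rng, n)
        edges = np.linspace(-1, 1, 21)
        counts, _ = np.histogram(np.cos(th), bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        thomson = 1.0 + centers**2
        expected = thomson / thomson.sum() * n
        p = stats.chisquare(counts, expected * counts.sum() / expected.sum()).pvalue
        assert p > 0.01


class TestSimulateEvents:
    def test_energy_conservation_exact(self, point_events):
        assert np.allclose(point_events.total_energy, EG, atol=0)

    def test_event_kinematics_self_consistent(self, point_events):
        """The kinematic cone angle equals the geometric angle between the
        scatter axis and the true source direction (no smearing)."""
        ev = point_events
        axis = ev.d1 - ev.d2
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        to_src = ev.true_origin - ev.d1
        to_src /= np.linalg.norm(to_src, axis=1, keepdims=True)
        geometric = np.arccos(np.clip(np.sum(axis * to_src, axis=1), -1, 1))
        kinematic = scattering_angle(ev.total_energy, ev.e1)
        assert np.max(np.abs(geometric - kinematic)) < 1e-9

    def test_interaction_points_inside_crystals(self, point_events, four_module):
        inside1 = np.zeros(len(point_events), bool)
        inside2 = np.zeros(len(point_events), bool)
        for slab in four_module.crystals:
            inside1 |= slab.contains(point_events.d1, atol=1e-6)
            inside2 |= slab.contains(point_events.d2, atol=1e-6)
        assert inside1.all() and inside2.all()

    def test_detection_fraction_order_of_magnitude(self, point_events):
        eff = len(point_events) / point_events.provenance["n_generated"]
        assert 1e-3 <= eff <= 1e-2

    def test_reproducible_for_fixed_seed(self, point_source, four_module):
        a = simulate_events(point_source, four_module, 50_000, rng=9)
        b = simulate_events(point_source, four_module, 50_000, rng=9)
        assert np.array_equal(a.d1, b.d1) and np.array_equal(a.e1, b.e1)

    def test_negative_count_rejected(self, point_source, four_module, rng):
        with pytest.raises(ValueError):
            simulate_events(point_source, four_module, -1, rng)

    def test_minimum_separation_within_one_crystal(self, point_events, four_module):
        """Sub-millimeter scatter/absorption pairs are only allowed across
        crystal boundaries (the 1 mm cut is a position-resolution surrogate
        within a single crystal)."""
        sep = np.linalg.norm(point_events.d2 - point_events.d1, axis=1)
        close = sep < 1.0 - 1e-12
        for i in np.nonzero(close)[0]:
            same = any(
                slab.contains(point_events.d1[i][None], atol=1e-7)[0]
                and slab.contains(point_events.d2[i][None], atol=1e-7)[0]
                for slab in four_module.crystals
            )
            assert not same


class TestEnergyWindow:
    def test_unsmeared_all_retained(self, point_events):
        filtered = energy_window_filter(point_events)
        assert len(filtered) == len(point_events)

    def test_boundary_event_removed(self):
        ev = EventList(
            d1=[[0, 0, 0], [1, 1, 1]],
            d2=[[5, 5, 5], [6, 6, 6]],
            e1=[0.2, 0.2],
            e2=[0.269, 0.278],
        )
        out = energy_window_filter(ev)
        assert len(out) == 1 and out.e2[0] == pytest.approx(0.278)

    def test_invalid_window(self, point_events):
        with pytest.raises(ValueError):
            energy_window_filter(point_events, 0.5, 0.4)

    def test_smeared_retention_matches_normal_probability(
        self, point_source, four_module
    ):
        """With sigma = 5 keV per deposit the total is N(0.478, sigma*sqrt(2));
        the retained fraction must match the closed-form window probability."""
        sigma = 0.005
        ev = simulate_events(
            point_source, four_module, 1_000_000, rng=77, energy_sigma=sigma
        )
        kept = energy_window_filter(ev)
        frac = len(kept) / len(ev)
        s_tot = sigma * np.sqrt(2.0)
        p = stats.norm.cdf(0.485, EG, s_tot) - stats.norm.cdf(0.470, EG, s_tot)
        lo, hi = stats.binom.interval(0.999, len(ev), p)
        assert lo <= len(kept) <= hi, (frac, p)


class TestEventListIO:
    def test_tsv_round_trip(self, point_events, tmp_path):
        sub = point_events.select(np.arange(50))
        path = tmp_path / "events.tsv"
        sub.to_tsv(path)
        back = EventList.from_tsv(path)
        assert np.allclose(back.d1, sub.d1) and np.allclose(back.e2, sub.e2)
        assert back.provenance["geometry"] == "four_module"

    def test_hdf5_round_trip(self, point_events, tmp_path):
        sub = point_events.select(np.arange(50))
        path = tmp_path / "events.h5"
        sub.to_hdf5(path)
        back = EventList.from_hdf5(path)
        assert np.array_equal(back.d1, sub.d1)
        assert np.array_equal(back.true_origin, sub.true_origin)


class TestGeometryYAML:
    def test_round_trip(self, four_module, tmp_path):
        from comptoncam.detector import geometry_from_yaml, geometry_to_yaml

        path = tmp_path / "geom.yaml"
        geometry_to_yaml(four_module, path)
        back = geometry_from_yaml(path)
        assert back.n_crystals == four_module.n_crystals
        for a, b in zip(back.crystals, four_module.crystals):
            assert np.allclose(a.center, b.center)
            assert np.allclose(a.orientation, b.orientation)
            assert a.half_sizes == b.half_sizes
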