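"""Shared fixtures: grids, detector geometries and cached simulations.

Session-scoped fixtures cache the expensive Monte-Carlo products (event
lists, MLEM pairs, the small training dataset) so every test file can
reuse them without re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from comptoncam.dataset import NoiseSpec, SupervisedDataset, build_manifest, make_pair
from comptoncam.detector import standard_geometry
from comptoncam.grids import GridSpec, ImageVolume
from comptoncam.phantoms import (
    default_rototranslations,
    enumerate_catalog,
    make_body_cylinder,
    make_source_distribution,
)
from comptoncam.simulate import energy_window_filter, simulate_events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_grid() -> GridSpec:
    return GridSpec.default()


@pytest.fixture(scope="session")
def four_module():
    return standard_geometry("four_module")


@pytest.fixture(scope="session")
def single_module():
    return standard_geometry("single")


@pytest.fixture(scope="session")
def point_source(default_grid) -> ImageVolume:
    vals = np.zeros(default_grid.shape)
    vals[10, 10, 20] = 1.0
    return ImageVolume(default_grid, vals)


@pytest.fixture(scope="session")
def point_events(point_source, four_module):
    """~6k energy-windowed events from an on-axis point source."""
    ev = simulate_events(point_source, four_module, 1_000_000, rng=42)
    return energy_window_filter(ev)


@pytest.fixture(scope="session")
def demo_grid() -> GridSpec:
    """Coarse grid for network-sized volumes (divisible by 4)."""
    return GridSpec.default(shape=(16, 16, 32))


@pytest.fixture(scope="session")
def demo_dataset(demo_grid, four_module) -> SupervisedDataset:
    """Small supervised dataset: 10 samples x 6 images, 3-way split.

    Two full-ratio geometries x {4:1, inf} + one inf-only geometry, each
    with one extra rototranslation; inputs are iteration-10 MLEM
    reconstructions (clean + 5 noisy variants), labels iteration-60.
    """
    specs = enumerate_catalog(
        2, (4.0, float("inf")), 1, rototranslations=default_rototranslations()[:1]
    )
    body = make_body_cylinder(demo_grid)
    master = np.random.default_rng(7)
    pairs = {}
    for sid, spec in enumerate(specs):
        src = make_source_distribution(body, spec.geometry, spec.ratio)
        ev = energy_window_filter(
            simulate_events(src, four_module, 300_000, rng=master.integers(2**31))
        )
        pairs[sid] = make_pair(ev, demo_grid)
    noise = NoiseSpec(n_noisy_per_sample=5)
    manifest = build_manifest(
        n_base=5, n_rototrans=1, noise=noise, split_counts=(6, 2, 2), seed=7
    )
    return SupervisedDataset.from_pairs(pairs, manifest, rng=11)
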