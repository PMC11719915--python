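"""Voxelized gamma-source activity phantoms.

The emitting object is a soft-tissue cylinder (default radius 30 mm,
height 100 mm, axis along z) containing a boron-loaded tumor sub-region.
Because the therapeutic boron dose is proportional to the local boron
concentration, the 478 keV prompt-gamma activity map is taken as 1 in
tumor voxels and ``1/ratio`` in normal-tissue voxels for a
tumor-to-normal concentration ratio ``T/N = ratio`` (0 for an infinite
ratio, i.e. no boron outside the tumor).

Tumor regions are parametric solids (sphere, ellipsoid, box, spherical
shell, ring/torus, multi-sphere) carrying a rigid pose; rototranslations
compose poses in continuous space and the solid is re-voxelized
afterwards, so repeated transforms never accumulate resampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .grids import GridSpec, ImageVolume

__all__ = [
    "RigidTransform",
    "TumorGeometrySpec",
    "ConcentrationRatio",
    "SourceSpec",
    "make_body_cylinder",
    "make_source_distribution",
    "rototranslate",
    "enumerate_catalog",
    "sample_emission_points",
    "load_default_catalog",
    "default_rototranslations",
]


def _rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class RigidTransform:
    """Rotation followed by translation: ``p -> R p + t`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthogonal matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_z_translation(
        cls, angle_deg: float = 0.0, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        return cls(_rotation_matrix("z", angle_deg), np.asarray(translation, float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` applied after ``other``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the solid's canonical frame."""
        return (np.asarray(points, float) - self.translation) @ self.rotation


@dataclass(frozen=True)
class ConcentrationRatio:
    """Tumor-to-normal boron concentration ratio T/N.

    ``math.inf`` encodes zero boron in normal tissue.  The therapeutic
    premise requires T/N >= 1.
    """

    ratio: float

    def __post_init__(self) -> None:
        if not (self.ratio >= 1.0):
            raise ValueError("concentration ratio must be >= 1 (or inf)")

    @property
    def normal_tissue_activity(self) -> float:
        return 0.0 if math.isinf(self.ratio) else 1.0 / self.ratio

    def __str__(self) -> str:
        return "inf" if math.isinf(self.ratio) else f"{self.ratio:g}"


_KINDS = ("sphere", "ellipsoid", "box", "shell", "ring", "multi_sphere")


@dataclass(frozen=True)
class TumorGeometrySpec:
    """A parametric tumor solid with a rigid pose.

    ``params`` by kind (all lengths in mm, in the solid's canonical frame
    centered at its own origin):

    - ``sphere``: ``radius``
    - ``ellipsoid``: ``semi_axes`` (a, b, c)
    - ``box``: ``half_sizes`` (hx, hy, hz)
    - ``shell``: ``r_inner``, ``r_outer`` (spherical shell)
    - ``ring``: ``r_major``, ``r_minor`` (torus in the local xy plane)
    - ``multi_sphere``: ``centers`` (list of xyz), ``radii`` (list)
    """

    kind: str
    params: dict
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown tumor kind {self.kind!r}; one of {_KINDS}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for world-frame points, shape (n, 3)."""
        q = self.pose.inverse_apply(points)
        p = self.params
        if self.kind == "sphere":
            return (q**2).sum(axis=1) <= p["radius"] ** 2
        if self.kind == "ellipsoid":
            a = np.asarray(p["semi_axes"], float)
            return ((q / a) ** 2).sum(axis=1) <= 1.0
        if self.kind == "box":
            h = np.asarray(p["half_sizes"], float)
            return np.all(np.abs(q) <= h, axis=1)
        if self.kind == "shell":
            r2 = (q**2).sum(axis=1)
            return (r2 >= p["r_inner"] ** 2) & (r2 <= p["r_outer"] ** 2)
        if self.kind == "ring":
            rho = np.hypot(q[:, 0], q[:, 1])
            return (rho - p["r_major"]) ** 2 + q[:, 2] ** 2 <= p["r_minor"] ** 2
        # multi_sphere
        centers = np.asarray(p["centers"], float)
        radii = np.asarray(p["radii"], float)
        d2 = ((q[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.any(d2 <= radii[None, :] ** 2, axis=1)

    def voxelize(self, grid: GridSpec) -> np.ndarray:
        """Binary mask on ``grid`` (membership tested at voxel centers)."""
        return self.contains(grid.voxel_centers()).reshape(grid.shape)


@dataclass(frozen=True)
class SourceSpec:
    """One catalog entry: geometry x concentration ratio x rototranslation."""

    geometry_id: int
    geometry: TumorGeometrySpec
    ratio: ConcentrationRatio
    rototranslation_id: int = 0

    @property
    def label(self) -> str:
        return (
            f"g{self.geometry_id:02d}_r{self.ratio}_t{self.rototranslation_id}"
        )


# --------------------------------------------------------------------------
# body and activity maps


def make_body_cylinder(
    grid: GridSpec, radius: float = 30.0, height: float = 100.0
) -> ImageVolume:
    """Binary mask of the soft-tissue body cylinder.

    The cylinder axis is the grid z-axis through (x, y) = (0, 0),
    centered between the bases at z = 0.  A cylinder extending past the
    grid is clipped with a warning rather than rejected.
    """
    if radius < 0 or height < 0:
        raise ValueError("radius and height must be non-negative")
    centers = grid.voxel_centers()
    inside = (
        (np.hypot(centers[:, 0], centers[:, 1]) <= radius)
        & (np.abs(centers[:, 2]) <= height / 2)
    )
    ext = grid.extent_mm
    if 2 * radius > ext[0] + 1e-9 or 2 * radius > ext[1] + 1e-9 or height > ext[2] + 1e-9:
        import logging

        logging.getLogger(__name__).warning(
            "body cylinder (r=%g, h=%g) exceeds grid extent %s; mask clipped",
            radius,
            height,
            ext,
        )
    return ImageVolume(grid, inside.reshape(grid.shape).astype(float))


def make_source_distribution(
    body: ImageVolume,
    tumor: TumorGeometrySpec,
    ratio: ConcentrationRatio | float,
) -> ImageVolume:
    """Activity map: 1 in the tumor, ``1/ratio`` in normal tissue, 0 outside.

    The tumor solid must lie entirely inside the body mask; the returned
    volume has maximum value 1.
    """
    if not isinstance(ratio, ConcentrationRatio):
        ratio = ConcentrationRatio(float(ratio))
    grid = body.grid
    body_mask = body.values > 0
    tumor_mask = tumor.voxelize(grid)
    if not tumor_mask.any():
        raise ValueError("tumor region voxelizes to an empty mask on this grid")
    n_outside = int(np.count_nonzero(tumor_mask & ~body_mask))
    if n_outside:
        raise ValueError(
            f"tumor region leaves the body: {n_outside} voxel(s) outside the mask"
        )
    values = np.zeros(grid.shape)
    values[body_mask] = ratio.normal_tissue_activity
    values[tumor_mask] = 1.0
    return ImageVolume(grid, values)


def rototranslate(
    spec: TumorGeometrySpec, transform: RigidTransform
) -> TumorGeometrySpec:
    """Apply a rigid transform to the tumor pose (continuous-space compose)."""
    return replace(spec, pose=transform.compose(spec.pose))


# --------------------------------------------------------------------------
# catalog


def load_default_catalog() -> list[TumorGeometrySpec]:
    """The package's 20 default tumor geometries (YAML package data)."""
    text = (
        resources.files("comptoncam").joinpath("data/tumor_catalog.yaml").read_text()
    )
    entries = yaml.safe_load(text)["geometries"]
    out = []
    for e in entries:
        pose = RigidTransform.from_euler_z_translation(
            e.get("rotate_z_deg", 0.0), e.get("translate_mm", (0.0, 0.0, 0.0))
        )
        out.append(
            TumorGeometrySpec(
                kind=e["kind"], params=e["params"], pose=pose, name=e["name"]
            )
        )
    return out


def default_rototranslations() -> list[RigidTransform]:
    """The four fixed augmentation rototranslations (explicit, not random)."""
    return [
        RigidTransform.from_euler_z_translation(30.0, (0.0, 0.0, 5.0)),
        RigidTransform.from_euler_z_translation(-30.0, (0.0, 0.0, -5.0)),
        RigidTransform.from_euler_z_translation(90.0, (3.0, -3.0, 8.0)),
        RigidTransform.from_euler_z_translation(180.0, (-3.0, 3.0, -8.0)),
    ]


def enumerate_catalog(
    n_geometries_full: int = 17,
    ratios_full=(3.0, 4.0, 5.0, math.inf),
    n_geometries_inf_only: int = 3,
    geometries: list[TumorGeometrySpec] | None = None,
    rototranslations: list[RigidTransform] | None = None,
) -> list[SourceSpec]:
    """Cross-product catalog of source distributions.

    The first ``n_geometries_full`` geometries are paired with every ratio
    in ``ratios_full``; the next ``n_geometries_inf_only`` only with an
    infinite T/N ratio.  With the defaults this yields 17*4 + 3 = 71 base
    distributions, and 71*5 = 355 once the four augmentation
    rototranslations (plus identity) are included.
    """
    if n_geometries_full < 0 or n_geometries_inf_only < 0:
        raise ValueError("geometry counts must be >= 0")
    if geometries is None:
        geometries = load_default_catalog()
    needed = n_geometries_full + n_geometries_inf_only
    if len(geometries) < needed:
        raise ValueError(f"catalog has {len(geometries)} geometries, need {needed}")
    transforms = [RigidTransform.identity()]
    if rototranslations:
        transforms += list(rototranslations)
    out: list[SourceSpec] = []
    for tid, tr in enumerate(transforms):
        for gid in range(n_geometries_full):
            for r in ratios_full:
                out.append(
                    SourceSpec(gid, rototranslate(geometries[gid], tr),
                               ConcentrationRatio(float(r)), tid)
                )
        for gid in range(n_geometries_full, needed):
            out.append(
                SourceSpec(gid, rototranslate(geometries[gid], tr),
                           ConcentrationRatio(math.inf), tid)
            )
    return out


# --------------------------------------------------------------------------
# emission sampling


def sample_emission_points(
    source: ImageVolume, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` emission positions (mm) from the activity map.

    Voxels are selected with probability proportional to their activity;
    within a voxel the position is uniform.  Reproducible for a fixed
    generator state.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    weights = source.values.ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("source distribution has no positive activity")
    if n == 0:
        return np.empty((0, 3))
    idx = rng.choice(weights.size, size=n, p=weights / total)
    ijk = np.column_stack(np.unravel_index(idx, source.grid.shape)).astype(float)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    spacing = np.asarray(source.grid.spacing)
    origin = np.asarray(source.grid.origin)
    return origin + (ijk + jitter) * spacing
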