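"""CZT Compton-camera geometry: oriented crystal slabs grouped in modules.

A sensor module is four 20 mm x 20 mm x 5 mm CZT parallelepipeds stacked
along the module's depth direction, with the 20 x 20 face looking at the
body cylinder.  The single-module configuration places the front face at
60 mm from the cylinder axis; the four-module configuration derives two
modules by rotating the original by +/-60 degrees about the cylinder
axis and two more by translating it by +/-10 mm along the axis (those
two form one larger effective module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrystalSlab",
    "DetectorGeometry",
    "standard_geometry",
    "geometry_to_yaml",
    "geometry_from_yaml",
]


@dataclass(frozen=True)
class CrystalSlab:
    """An oriented rectangular crystal.

    ``half_sizes`` are along the slab's local axes; ``orientation`` maps
    local to world coordinates.  The default half sizes (10, 10, 2.5)
    give the canonical 20 x 20 x 5 mm CZT drift-strip crystal with the
    thin direction along local z.
    """

    center: np.ndarray
    half_sizes: tuple[float, float, float] = (10.0, 10.0, 2.5)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        R = np.asarray(self.orientation, dtype=float)
        if any(h <= 0 for h in self.half_sizes):
            raise ValueError("half_sizes must be positive")
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "orientation", R)
        object.__setattr__(self, "half_sizes", tuple(float(h) for h in self.half_sizes))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.center) @ self.orientation

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        q = np.abs(self.to_local(points))
        h = np.asarray(self.half_sizes)
        return np.all(q <= h + atol, axis=-1)

    def ray_intersect(
        self, origins: np.ndarray, directions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Entry/exit parameters of rays with the slab (vectorized).

        Returns ``(t_entry, t_exit)`` per ray; rays that miss get
        ``t_entry > t_exit``.  Origins inside the slab yield a negative
        ``t_entry``.
        """
        o = self.to_local(origins)
        d = np.asarray(directions, float) @ self.orientation
        h = np.asarray(self.half_sizes)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-h - o) / d
            t2 = (h - o) / d
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        # axes with zero direction component: inside -> (-inf, inf), else miss
        par = d == 0
        inside_axis = np.abs(o) <= h
        lo = np.where(par, np.where(inside_axis, -np.inf, np.inf), lo)
        hi = np.where(par, np.where(inside_axis, np.inf, -np.inf), hi)
        return lo.max(axis=-1), hi.min(axis=-1)


# local->world mapping for the base module: local x -> world y, local
# y -> world z, local z -> world x, so the 20x20 face lies in the world
# y-z plane (parallel to the cylinder axis) and the 5 mm depth is radial.
_BASE_ORIENTATION = np.array(
    [[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
)


def _base_module(front_distance: float = 60.0) -> list[CrystalSlab]:
    slabs = []
    for i in range(4):
        center = np.array([front_distance + 2.5 + 5.0 * i, 0.0, 0.0])
        slabs.append(CrystalSlab(center=center, orientation=_BASE_ORIENTATION))
    return slabs


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class DetectorGeometry:
    """A set of modules, each a stack of four crystal slabs."""

    modules: tuple[tuple[CrystalSlab, ...], ...]
    name: str = "custom"

    @property
    def crystals(self) -> list[CrystalSlab]:
        return [slab for module in self.modules for slab in module]

    @property
    def n_crystals(self) -> int:
        return len(self.crystals)


def standard_geometry(config: str = "four_module") -> DetectorGeometry:
    """The canonical detector configurations.

    ``"single"``: one module, front face 60 mm from the cylinder axis,
    equidistant from the cylinder bases.  ``"four_module"``: two modules
    rotated by +/-60 degrees about the axis plus two copies of the
    original translated by +/-10 mm along the axis (16 crystals total).
    """
    base = _base_module()
    if config == "single":
        return DetectorGeometry(modules=(tuple(base),), name="single")
    if config == "four_module":
        modules = []
        for angle in (60.0, -60.0):
            R = _rot_z(angle)
            modules.append(
                tuple(
                    CrystalSlab(
                        center=R @ s.center,
                        half_sizes=s.half_sizes,
                        orientation=R @ s.orientation,
                    )
                    for s in base
                )
            )
        for dz in (10.0, -10.0):
            shift = np.array([0.0, 0.0, dz])
            modules.append(
                tuple(
                    CrystalSlab(
                        center=s.center + shift,
                        half_sizes=s.half_sizes,
                        orientation=s.orientation,
                    )
                    for s in base
                )
            )
        return DetectorGeometry(modules=tuple(modules), name="four_module")
    raise ValueError(f"unknown configuration {config!r}")


def geometry_to_yaml(det: DetectorGeometry, path) -> None:
    """Serialize module poses and slab sizes to a YAML file."""
    import yaml

    doc = {
        "name": det.name,
        "modules": [
            [
                {
                    "center_mm": [float(v) for v in s.center],
                    "half_sizes_mm": list(s.half_sizes),
                    "orientation": [[float(v) for v in row] for row in s.orientation],
                }
                for s in module
            ]
            for module in det.modules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def geometry_from_yaml(path) -> DetectorGeometry:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    modules = tuple(
        tuple(
            CrystalSlab(
                center=np.asarray(s["center_mm"], float),
                half_sizes=tuple(s["half_sizes_mm"]),
                orientation=np.asarray(s["orientation"], float),
            )
            for s in module
        )
        for module in doc["modules"]
    )
    return DetectorGeometry(modules=modules, name=doc.get("name", "custom"))
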