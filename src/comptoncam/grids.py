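"""Regular voxel grids and scalar image volumes.

Conventions used package-wide: right-handed coordinates in mm, voxel
indices 0-based with axis order (x, y, z), voxel values located at voxel
centers, and the body-cylinder axis along z.  The canonical imaging
region is an 80 mm x 80 mm x 160 mm parallelepiped centered on the
origin, long side along the cylinder axis; the default grid samples it
at 4 mm isotropic spacing (20 x 20 x 40 voxels), a desk-scale
resolution that keeps iterative reconstruction and network training
tractable on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GridSpec", "ImageVolume", "DEFAULT_REGION_MM"]

#: Physical extent (mm) of the canonical imaging region (x, y, z).
DEFAULT_REGION_MM = (80.0, 80.0, 160.0)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid.

    Attributes
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel size in mm along each axis.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be three integers >= 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @classmethod
    def default(cls, shape=(20, 20, 40), region_mm=DEFAULT_REGION_MM) -> "GridSpec":
        """Grid covering ``region_mm`` centered on the coordinate origin."""
        spacing = tuple(r / s for r, s in zip(region_mm, shape))
        origin = tuple(-r / 2 + sp / 2 for r, sp in zip(region_mm, spacing))
        return cls(shape=shape, spacing=spacing, origin=origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape ``(n_voxels, 3)``, C order."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal: axis-aligned grid)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ImageVolume:
    """A non-negative scalar field on a :class:`GridSpec`.

    Used for source-activity maps, MLEM reconstructions and network
    inputs/labels alike.
    """

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("volume values must be non-negative")

    @classmethod
    def zeros(cls, grid: GridSpec) -> "ImageVolume":
        return cls(grid, np.zeros(grid.shape))

    @classmethod
    def full(cls, grid: GridSpec, value: float) -> "ImageVolume":
        return cls(grid, np.full(grid.shape, float(value)))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy())

    def normalized(self) -> "ImageVolume":
        """Affinely rescale values to [0, 1] (min -> 0, max -> 1)."""
        lo, hi = float(self.values.min()), float(self.values.max())
        if hi == lo:
            raise ValueError("cannot normalize a constant volume")
        return ImageVolume(self.grid, (self.values - lo) / (hi - lo))

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine())
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        aff = img.affine
        grid = GridSpec(
            shape=data.shape,
            spacing=tuple(float(abs(aff[i, i])) for i in range(3)),
            origin=tuple(float(aff[i, 3]) for i in range(3)),
        )
        return cls(grid, data)

    def to_raw_json(self, path: str | Path) -> None:
        """Lossless fallback: float64 .raw alongside a JSON grid header."""
        path = Path(path)
        raw = path.with_suffix(".raw")
        self.values.astype("<f8").tofile(raw)
        meta = {
            "shape": list(self.grid.shape),
            "spacing": list(self.grid.spacing),
            "origin": list(self.grid.origin),
            "dtype": "<f8",
            "order": "C",
            "raw_file": raw.name,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_raw_json(cls, path: str | Path) -> "ImageVolume":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        values = np.fromfile(
            path.parent / meta["raw_file"], dtype=meta["dtype"]
        ).reshape(meta["shape"])
        grid = GridSpec(
            shape=tuple(meta["shape"]),
            spacing=tuple(meta["spacing"]),
            origin=tuple(meta["origin"]),
        )
        return cls(grid, values)
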