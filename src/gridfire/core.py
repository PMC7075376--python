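"""Core geometric containers shared across the planning pipeline.

Coordinate conventions
----------------------
Patient coordinates follow the DICOM LPS convention: ``x`` increases toward
the patient's left, ``y`` toward posterior, ``z`` toward superior.  All
positions and spacings are millimetres.  Voxel arrays are indexed
``values[k, j, i]`` where ``k`` runs along ``z`` (slices), ``j`` along ``y``
(rows) and ``i`` along ``x`` (columns).  ``origin_mm`` is the patient-space
position of the *center* of voxel ``(0, 0, 0)``; masks use voxel-center-in-
region semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Grid", "ImageVolume", "Structure", "StructureSet"]


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid geometry: shape ``(nz, ny, nx)``, spacing ``(dx, dy, dz)``."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be strictly positive, got {self.spacing_mm}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates ``(x, y, z)`` along each patient axis."""
        dx, dy, dz = self.spacing_mm
        x0, y0, z0 = self.origin_mm
        nz, ny, nx = self.shape
        return (
            x0 + dx * np.arange(nx),
            y0 + dy * np.arange(ny),
            z0 + dz * np.arange(nz),
        )

    def voxel_centers(self, where: np.ndarray | None = None) -> np.ndarray:
        """Patient-space centers, ``(N, 3)`` as ``(x, y, z)``.

        ``where`` restricts to the True voxels of a boolean mask on this grid.
        """
        x, y, z = self.axis_coords()
        if where is None:
            zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
            return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        k, j, i = np.nonzero(where)
        return np.column_stack([x[i], y[j], z[k]])

    def slice_z(self, k: int) -> float:
        return self.origin_mm[2] + k * self.spacing_mm[2]

    def z_to_slice(self, z_mm: float) -> int:
        """Nearest slice index for a patient z position (must lie on the grid)."""
        dz = self.spacing_mm[2]
        k = int(round((z_mm - self.origin_mm[2]) / dz))
        if k < 0 or k >= self.shape[0]:
            raise ValueError(f"z={z_mm} mm lies outside the grid ({self.shape[0]} slices)")
        if abs(self.slice_z(k) - z_mm) > 0.5 * dz + 1e-6:
            raise ValueError(f"z={z_mm} mm does not coincide with any slice plane")
        return k


@dataclass
class ImageVolume:
    """3D scalar image (HU) with physical geometry.

    ``axis_directions`` is the orthonormal triad of patient-space directions of
    the (x, y, z) index axes; only the identity (axial, head-first supine) is
    produced by this package, but the field is validated on construction.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    axis_directions: np.ndarray = field(default_factory=lambda: np.eye(3))
    patient_position_label: str = "HFS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume.values must be a 3D array (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        a = np.asarray(self.axis_directions, dtype=float)
        if a.shape != (3, 3) or not np.allclose(a @ a.T, np.eye(3), atol=1e-6):
            raise ValueError("axis_directions must be an orthonormal 3x3 triad")
        self.axis_directions = a

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.values.shape), tuple(self.spacing_mm), tuple(self.origin_mm))


@dataclass
class Structure:
    """A named region: per-slice closed planar contours plus a cached voxel mask.

    ``contours`` is a list of ``(z_mm, vertices)`` pairs, vertices an ``(N, 2)``
    array of patient ``(x, y)`` mm on one axial plane, implicitly closed
    (first vertex is not repeated).
    """

    name: str
    contours: list[tuple[float, np.ndarray]] = field(default_factory=list)
    color: tuple[int, int, int] = (255, 0, 0)
    _mask: np.ndarray | None = None
    _mask_grid: Grid | None = None

    def mask(self, grid: Grid) -> np.ndarray:
        """Voxel mask on ``grid`` (rasterized from contours, cached)."""
        if self._mask is not None and self._mask_grid == grid:
            return self._mask
        from .rtio import contours_to_mask  # local import: rtio depends on core

        m = contours_to_mask(self.contours, grid)
        self._mask, self._mask_grid = m, grid
        return m

    @classmethod
    def from_mask(
        cls,
        name: str,
        mask: np.ndarray,
        grid: Grid,
        color: tuple[int, int, int] = (255, 0, 0),
    ) -> "Structure":
        from .rtio import mask_to_contours

        s = cls(name=name, contours=mask_to_contours(mask, grid), color=color)
        s._mask, s._mask_grid = mask.astype(bool), grid
        return s


@dataclass
class StructureSet:
    """Ordered collection of uniquely named structures on a reference grid."""

    structures: list[Structure] = field(default_factory=list)
    reference_grid: Grid | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise ValueError(f"structure names must be unique, got {names}")

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.structures)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}; available: {self.names()}")

    def add(self, structure: Structure) -> None:
        if structure.name in self:
            raise ValueError(f"structure {structure.name!r} already present")
        self.structures.append(structure)

    def mask(self, name: str, grid: Grid | None = None) -> np.ndarray:
        g = grid or self.reference_grid
        if g is None:
            raise ValueError("no grid supplied and no reference grid set")
        return self[name].mask(g)


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Relative electron density from HU via a bilinear ramp.

    Below water (HU <= 0): density = 1 + HU/1000, clipped at 0 (air ~ 0,
    lung ~ 0.25 at -750).  Above water: a shallower bone-like slope,
    density = 1 + HU/1950.
    """
    hu = np.asarray(hu, dtype=float)
    lo = np.clip(1.0 + hu / 1000.0, 0.0, None)
    hi = 1.0 + hu / 1950.0
    return np.where(hu <= 0.0, lo, hi)
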