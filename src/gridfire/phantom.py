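"""Synthetic CT + structure-set phantoms for end-to-end planning tests.

The generator emulates the geometry of deep-seated bulky-tumor patients: an
elliptical water-equivalent body cross-section, a spherical GTV placed at a
controlled depth below the anterior skin surface, a 5 mm skin shell (the body
minus a 5 mm Euclidean erosion), and optionally a cylindrical cord-like organ
at risk posterior to the target.  Tumor diameters of 6-15 cm and
skin-to-center depths of 4.3-10.4 cm span the clinical range of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Grid, ImageVolume, Structure, StructureSet

__all__ = ["PhantomSpec", "GeometryError", "make_phantom", "phantom_cohort", "benchmark_spec"]

SKIN_THICKNESS_MM = 5.0

HU_AIR = -1000.0
HU_WATER = 0.0
HU_LUNG = -750.0


class GeometryError(ValueError):
    """A phantom spec whose requested geometry cannot be realized."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic patient.

    ``gtv_center_depth_mm`` is the distance from the anterior skin surface to
    the tumor center along the anterior-posterior axis.  ``body_axes_mm`` are
    the (left-right, anterior-posterior) semi-axes of the elliptical body
    cross-section.  Identical specs (same seed) produce bit-identical phantoms.
    """

    body_axes_mm: tuple[float, float] = (160.0, 110.0)
    body_length_mm: float = 240.0
    gtv_diameter_mm: float = 100.0
    gtv_center_depth_mm: float = 90.0
    voxel_spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    oar_kind: str = "none"  # "none" | "cord-cylinder"
    hu_body: float = HU_WATER
    lung_insert: tuple[float, float, float, float] | None = None  # (x, y, z, radius) mm
    hu_lung_insert: float = HU_LUNG
    hu_noise_sd: float = 0.0
    margin_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gtv_diameter_mm <= 0:
            raise GeometryError("gtv_diameter_mm must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise GeometryError("voxel spacing must be strictly positive")
        if any(a <= 0 for a in self.body_axes_mm) or self.body_length_mm <= 0:
            raise GeometryError("body dimensions must be positive")
        if self.oar_kind not in ("none", "cord-cylinder"):
            raise GeometryError(f"unknown oar_kind {self.oar_kind!r}")
        ax, ay = self.body_axes_mm
        r = self.gtv_diameter_mm / 2.0
        yc = -ay + self.gtv_center_depth_mm  # body center at y=0; anterior surface at -ay
        if self.gtv_center_depth_mm < r:
            raise GeometryError(
                f"GTV of radius {r} mm at depth {self.gtv_center_depth_mm} mm "
                "protrudes through the anterior skin surface")
        # GTV must fit inside the elliptical cross-section and body length.
        if abs(yc) + r > ay or r > ax:
            raise GeometryError(
                f"GTV (radius {r} mm, center depth {self.gtv_center_depth_mm} mm) "
                f"does not fit inside body semi-axes {self.body_axes_mm} mm")
        if 2 * r > self.body_length_mm:
            raise GeometryError("GTV longer than the body")

    @property
    def gtv_center_mm(self) -> tuple[float, float, float]:
        return (0.0, -self.body_axes_mm[1] + self.gtv_center_depth_mm, 0.0)


def _grid_for(spec: PhantomSpec) -> Grid:
    dx, dy, dz = spec.voxel_spacing_mm
    ax, ay = spec.body_axes_mm
    hz = spec.body_length_mm / 2.0
    m = spec.margin_mm
    nx = int(np.ceil(2 * (ax + m) / dx))
    ny = int(np.ceil(2 * (ay + m) / dy))
    nz = int(np.ceil(2 * (hz + m) / dz))
    origin = (-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy, -(nz - 1) / 2.0 * dz)
    return Grid((nz, ny, nx), (dx, dy, dz), origin)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet]:
    """Build the CT-like volume and the BODY / GTV / SKIN (/ OAR) structures.

    The skin mask is BODY minus BODY eroded by 5 mm (Euclidean), so every
    skin voxel center lies within 5 mm of the body surface.
    """
    grid = _grid_for(spec)
    x, y, z = grid.axis_coords()
    xx = x[None, None, :]
    yy = y[None, :, None]
    zz = z[:, None, None]
    ax, ay = spec.body_axes_mm
    hz = spec.body_length_mm / 2.0

    body = ((xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0) & (np.abs(zz) <= hz)

    cx, cy, cz = spec.gtv_center_mm
    r = spec.gtv_diameter_mm / 2.0
    gtv = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r**2
    if not gtv.any():
        raise GeometryError("GTV too small to contain a single voxel center at this spacing")

    # Skin: body minus its 5 mm Euclidean erosion (distance-to-outside <= 5 mm).
    dist_in = ndimage.distance_transform_edt(body, sampling=grid.spacing_mm[::-1])
    skin = body & (dist_in <= SKIN_THICKNESS_MM)

    hu = np.full(grid.shape, HU_AIR)
    hu[body] = spec.hu_body
    if spec.lung_insert is not None:
        lx, ly, lz, lr = spec.lung_insert
        lung = (xx - lx) ** 2 + (yy - ly) ** 2 + (zz - lz) ** 2 <= lr**2
        hu[lung & body] = spec.hu_lung_insert
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu[body] += rng.normal(0.0, spec.hu_noise_sd, size=int(body.sum()))

    volume = ImageVolume(values=hu, spacing_mm=grid.spacing_mm, origin_mm=grid.origin_mm)
    sset = StructureSet(reference_grid=grid)
    sset.add(Structure.from_mask("BODY", body, grid, color=(0, 255, 0)))
    sset.add(Structure.from_mask("GTV", gtv, grid, color=(255, 0, 0)))
    sset.add(Structure.from_mask("SKIN", skin, grid, color=(255, 170, 0)))

    if spec.oar_kind == "cord-cylinder":
        oy = 0.72 * ay  # posterior, cord-like
        oar = ((xx - 0.0) ** 2 + (yy - oy) ** 2 <= 7.5**2) & (np.abs(zz) <= hz) & body
        if oar.any():
            sset.add(Structure.from_mask("CORD", oar, grid, color=(0, 120, 255)))
    return volume, sset


def phantom_cohort(n: int, seed: int) -> list[PhantomSpec]:
    """Sample ``n`` phantom specs spanning the clinical tumor-size/depth ranges.

    Diameters are uniform in [60, 150] mm and skin-to-center depths uniform in
    [43, 104] mm; the body is scaled so each tumor fits.  Deterministic given
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        d = float(rng.uniform(60.0, 150.0))
        depth = float(rng.uniform(43.0, 104.0))
        depth = max(depth, d / 2.0 + 8.0)  # keep the sphere clear of the skin shell
        ay = max(110.0, depth + d / 2.0 + 15.0)
        ax = max(160.0, d / 2.0 + 40.0)
        specs.append(
            PhantomSpec(
                body_axes_mm=(ax, ay),
                body_length_mm=max(240.0, d + 60.0),
                gtv_diameter_mm=d,
                gtv_center_depth_mm=depth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def benchmark_spec(voxel_mm: float = 2.5) -> PhantomSpec:
    """The benchmark deep-seated case: 10 cm spherical GTV, 9 cm below the skin."""
    return PhantomSpec(
        body_axes_mm=(160.0, 110.0),
        body_length_mm=240.0,
        gtv_diameter_mm=100.0,
        gtv_center_depth_mm=90.0,
        voxel_spacing_mm=(voxel_mm, voxel_mm, voxel_mm),
        oar_kind="cord-cylinder",
    )
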