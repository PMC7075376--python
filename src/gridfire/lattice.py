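"""GRID-lattice generation inside a target volume.

A 2D lattice of cell centers (hexagonal by default, square optional) is
anchored at the GTV centroid in the axial plane.  Each kept center carries a
cell — by default a cylinder of the hole diameter running parallel to the
superior-inferior axis, spanning and clipped to the GTV; optionally a sphere.
Longitudinal cylinders are what make the pattern deliverable by static
single-interval MLC apertures from coplanar beams with a 90 degree collimator:
every cylinder projects to one leaf-travel interval at any gantry angle, so
the crossfire "tunnels" need no beam modulation.

The hexagonal lattice is oriented with one primitive vector along the
patient's left-right axis; the six standard crossfire beams then all view the
lattice along row-normal directions and see clean stripe patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Grid

__all__ = ["LatticeSpec", "LatticeResult", "LatticeQC", "build_lattice", "lattice_qc"]


@dataclass(frozen=True)
class LatticeSpec:
    hole_diameter_mm: float = 10.0
    pitch_mm: float = 20.0
    arrangement: str = "hexagonal"  # "hexagonal" | "square"
    cell_shape: str = "cylinder-longitudinal"  # | "sphere"
    registration_offset_mm: tuple[float, float] = (0.0, 0.0)
    min_inside_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.hole_diameter_mm < self.pitch_mm:
            raise ValueError(
                f"need 0 < hole diameter ({self.hole_diameter_mm}) < pitch ({self.pitch_mm})")
        if not 0 < self.min_inside_fraction <= 1:
            raise ValueError("min_inside_fraction must lie in (0, 1]")
        if self.arrangement not in ("hexagonal", "square"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.cell_shape not in ("cylinder-longitudinal", "sphere"):
            raise ValueError(f"unknown cell_shape {self.cell_shape!r}")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Primitive lattice vectors in the axial (x, y) plane, mm."""
        p = self.pitch_mm
        if self.arrangement == "hexagonal":
            return np.array([p, 0.0]), np.array([p / 2.0, p * np.sqrt(3.0) / 2.0])
        return np.array([p, 0.0]), np.array([0.0, p])


@dataclass
class LatticeQC:
    n_cells: int
    mean_diameter_mm: float  # NaN when no cells
    diameters_mm: np.ndarray
    mean_pitch_mm: float  # NaN when pitch not applicable (< 2 cells)
    nn_distances_mm: np.ndarray
    nn_angles_deg: np.ndarray
    pitch_applicable: bool


@dataclass
class LatticeResult:
    mask: np.ndarray
    cell_centers_mm: np.ndarray  # (n, 2) axial positions
    cells_kept: int
    qc: LatticeQC
    spec: LatticeSpec = field(default=None)


def enumerate_centers(spec: LatticeSpec, anchor_xy: np.ndarray,
                      xlim: tuple[float, float], ylim: tuple[float, float]) -> np.ndarray:
    """All lattice points anchored at ``anchor_xy`` within the given bounds."""
    a1, a2 = spec.basis()
    # Solve integer ranges generously from the bounding box.
    span = max(xlim[1] - xlim[0], ylim[1] - ylim[0]) + 2 * spec.pitch_mm
    nmax = int(np.ceil(span / spec.pitch_mm)) + 2
    ii, jj = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1))
    pts = anchor_xy[None, :] + ii.reshape(-1, 1) * a1[None, :] + jj.reshape(-1, 1) * a2[None, :]
    keep = ((pts[:, 0] >= xlim[0]) & (pts[:, 0] <= xlim[1])
            & (pts[:, 1] >= ylim[0]) & (pts[:, 1] <= ylim[1]))
    return pts[keep]


def build_lattice(gtv_mask: np.ndarray, grid: Grid, spec: LatticeSpec) -> LatticeResult:
    """Generate the lattice mask inside the GTV.

    A cell is kept when at least ``min_inside_fraction`` of its cross-section
    lies inside the GTV cross-section on the GTV mid-slice (the axial slice
    of the centroid); ties at exactly the threshold are kept.  The lattice
    mask is the union of kept cells intersected with the GTV, so it is a
    strict subset of the GTV mask.
    """
    gtv_mask = np.asarray(gtv_mask, dtype=bool)
    if not gtv_mask.any():
        raise ValueError("GTV mask is empty")
    x, y, z = grid.axis_coords()
    k, j, i = np.nonzero(gtv_mask)
    centroid = np.array([x[i].mean(), y[j].mean(), z[k].mean()])
    k_mid = int(np.argmin(np.abs(z - centroid[2])))
    mid = gtv_mask[k_mid]

    anchor = centroid[:2] + np.asarray(spec.registration_offset_mm, dtype=float)
    r = spec.hole_diameter_mm / 2.0
    pad = r + grid.spacing_mm[0]
    centers = enumerate_centers(
        spec, anchor,
        (x[i].min() - pad, x[i].max() + pad),
        (y[j].min() - pad, y[j].max() + pad),
    )

    xx, yy = np.meshgrid(x, y)
    kept_centers = []
    discs = []
    for c in centers:
        disc = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r**2
        n_disc = int(disc.sum())
        if n_disc == 0:
            continue
        frac = int((disc & mid).sum()) / n_disc
        if frac >= spec.min_inside_fraction:
            kept_centers.append(c)
            discs.append(disc)

    mask = np.zeros_like(gtv_mask)
    if kept_centers:
        if spec.cell_shape == "cylinder-longitudinal":
            union2d = np.logical_or.reduce(discs)
            mask = union2d[None, :, :] & gtv_mask
        else:  # spheres centered on the centroid slice
            zz = z[:, None, None]
            for c in kept_centers:
                cell = ((xx[None] - c[0]) ** 2 + (yy[None] - c[1]) ** 2
                        + (zz - centroid[2]) ** 2 <= r**2)
                mask |= cell
            mask &= gtv_mask

    kept = np.asarray(kept_centers).reshape(-1, 2)
    result = LatticeResult(mask=mask, cell_centers_mm=kept, cells_kept=len(kept),
                           qc=None, spec=spec)
    result.qc = lattice_qc(result, grid, mid_slice=k_mid)
    return result


def lattice_qc(result: LatticeResult, grid: Grid, mid_slice: int | None = None) -> LatticeQC:
    """Parameter-recovery report: measured hole diameters and center pitch.

    Per-cell diameter is the equivalent-circle diameter of the cell's
    mid-slice cross-section (2*sqrt(area/pi)); pitch is the nearest-neighbor
    center distance.  Deterministic; an empty lattice yields a zero-cell
    report rather than an exception.
    """
    n = result.cells_kept
    if n == 0:
        return LatticeQC(0, float("nan"), np.empty(0), float("nan"),
                         np.empty(0), np.empty(0), False)
    if mid_slice is None:
        ks = np.nonzero(result.mask.any(axis=(1, 2)))[0]
        mid_slice = int(ks[len(ks) // 2])
    dx, dy, _ = grid.spacing_mm
    x, y, _ = grid.axis_coords()
    xx, yy = np.meshgrid(x, y)
    mid = result.mask[mid_slice]
    r_assign = result.spec.pitch_mm / 2.0 if result.spec else np.inf
    diams = []
    for c in result.cell_centers_mm:
        near = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_assign**2
        area = int((mid & near).sum()) * dx * dy
        diams.append(2.0 * np.sqrt(area / np.pi))
    diams = np.asarray(diams)

    if n >= 2:
        d = result.cell_centers_mm[:, None, :] - result.cell_centers_mm[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        nn_idx = np.argmin(dist, axis=1)
        nn = dist[np.arange(n), nn_idx]
        vec = result.cell_centers_mm[nn_idx] - result.cell_centers_mm
        angles = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 180.0
        return LatticeQC(n, float(diams.mean()), diams, float(nn.mean()), nn, angles, True)
    return LatticeQC(n, float(diams.mean()), diams, float("nan"),
                     np.empty(0), np.empty(0), False)
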