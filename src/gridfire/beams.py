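"""Crossfire beam geometry, beam's-eye-view projection, MLC aperture fitting.

Machine angles follow IEC 61217 for a head-first supine patient: gantry 0 has
the source anterior, angles increase clockwise viewed from the couch.  With a
90 degree collimator rotation the MLC leaf-travel axis is parallel to the
patient's superior-inferior axis for every coplanar beam, so the BEV frame is
``u`` = leaf-stack direction (axial-plane transverse) and ``v`` = leaf travel
(longitudinal).  BEV coordinates are expressed at the isocenter plane with
point-source magnification SAD / (source-to-point axis distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Grid

__all__ = [
    "BeamSpec",
    "MLCGeometry",
    "MLCAperture",
    "BEVImage",
    "make_crossfire_beams",
    "beam_frame",
    "project_points",
    "project_bev",
    "fit_mlc",
    "aperture_open_area",
    "aperture_fluence",
]

DEFAULT_GANTRY_START_DEG = 210.0


@dataclass(frozen=True)
class BeamSpec:
    gantry_deg: float
    collimator_deg: float = 90.0
    couch_deg: float = 0.0
    energy_label: str = "6MV"
    weight: float = 1.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sad_mm: float = 1000.0
    dose_rate_mu_per_min: float = 400.0

    def __post_init__(self) -> None:
        if not 0 <= self.gantry_deg < 360:
            raise ValueError(f"gantry angle must be in [0, 360), got {self.gantry_deg}")
        if self.weight <= 0:
            raise ValueError("beam weight must be positive")
        if self.sad_mm <= 0:
            raise ValueError("SAD must be positive")


@dataclass(frozen=True)
class MLCGeometry:
    """Uniform-width leaf bank (Millennium-120-like central leaves)."""

    leaf_width_mm_at_iso: float = 5.0
    leaf_pair_count: int = 60
    max_travel_mm: float = 200.0
    min_gap_closed_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.leaf_width_mm_at_iso <= 0:
            raise ValueError("leaf width must be positive")
        if self.leaf_pair_count % 2 or self.leaf_pair_count < 2:
            raise ValueError("leaf pair count must be even and >= 2")

    def edges(self) -> np.ndarray:
        """Leaf-pair strip boundaries along ``u``, centered on the axis."""
        half = self.leaf_pair_count * self.leaf_width_mm_at_iso / 2.0
        return -half + self.leaf_width_mm_at_iso * np.arange(self.leaf_pair_count + 1)


@dataclass
class MLCAperture:
    """Static aperture: per leaf pair one open interval [tip_a, tip_b] along v.

    Closed pairs have ``tip_a == tip_b`` parked at the lower jaw edge.
    ``jaws`` is the (u_min, u_max, v_min, v_max) rectangle bounding the
    open aperture.
    """

    tips_a: np.ndarray
    tips_b: np.ndarray
    is_open: np.ndarray
    jaws: tuple[float, float, float, float]
    mlc: MLCGeometry = field(default_factory=MLCGeometry)

    def __post_init__(self) -> None:
        if np.any(self.tips_a > self.tips_b + 1e-9):
            raise ValueError("aperture invariant violated: tip_a > tip_b")


@dataclass
class BEVImage:
    """Binary beam's-eye-view mask sampled on a regular (u, v) grid at iso."""

    mask: np.ndarray  # (n_u, n_v)
    u_axis: np.ndarray
    v_axis: np.ndarray
    excluded_points: int = 0  # voxels at/behind the source

    @property
    def spacing(self) -> tuple[float, float]:
        du = float(self.u_axis[1] - self.u_axis[0]) if len(self.u_axis) > 1 else 1.0
        dv = float(self.v_axis[1] - self.v_axis[0]) if len(self.v_axis) > 1 else 1.0
        return du, dv


def make_crossfire_beams(
    isocenter_mm: tuple[float, float, float],
    energy_label: str,
    start_deg: float = DEFAULT_GANTRY_START_DEG,
    n: int = 6,
    spacing_deg: float = 60.0,
    sad_mm: float = 1000.0,
    dose_rate_mu_per_min: float = 400.0,
) -> list[BeamSpec]:
    """Clockwise crossfire arrangement: gantry = start + k*spacing (mod 360).

    The default six beams {210, 270, 330, 30, 90, 150} pair each angle with
    its 180-degree complement, collimator 90 on all, equal weights.
    """
    if n * spacing_deg > 360 + 1e-9:
        raise ValueError("beam fan exceeds a full rotation")
    return [
        BeamSpec(
            gantry_deg=(start_deg + k * spacing_deg) % 360.0,
            energy_label=energy_label,
            isocenter_mm=tuple(isocenter_mm),
            sad_mm=sad_mm,
            dose_rate_mu_per_min=dose_rate_mu_per_min,
        )
        for k in range(n)
    ]


def beam_frame(beam: BeamSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(source, axis, e_u, e_v) in patient coordinates.

    ``axis`` points from source to isocenter; ``e_v`` is the leaf-travel
    direction (patient longitudinal for collimator 90) and ``e_u = e_v x axis``
    the leaf-stack direction.
    """
    if abs(beam.couch_deg) > 1e-9:
        raise NotImplementedError("non-zero couch angles are not supported")
    if abs(beam.collimator_deg - 90.0) > 1e-9 and abs(beam.collimator_deg) > 1e-9:
        raise NotImplementedError("only collimator 0 or 90 degrees supported")
    g = np.radians(beam.gantry_deg)
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    axis = np.array([-np.sin(g), np.cos(g), 0.0])
    source = iso - beam.sad_mm * axis
    if abs(beam.collimator_deg - 90.0) < 1e-9:
        e_v = np.array([0.0, 0.0, 1.0])
    else:
        e_v = np.cross(np.array([0.0, 0.0, 1.0]), axis)
    e_u = np.cross(e_v, axis)
    return source, axis, e_u, e_v


def project_points(points: np.ndarray, beam: BeamSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project patient-space points onto the isocenter plane.

    Returns (u, v, t) with (u, v) BEV coordinates at the isocenter plane and
    ``t`` the source-to-point distance along the beam axis (SAD at the iso
    plane; upstream points have t < SAD and are magnified by SAD/t).
    """
    source, axis, e_u, e_v = beam_frame(beam)
    r = np.atleast_2d(points) - source
    t = r @ axis
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = beam.sad_mm / t
    u = (r @ e_u) * scale
    v = (r @ e_v) * scale
    return u, v, t


def project_bev(
    mask: np.ndarray,
    grid: Grid,
    beam: BeamSpec,
    bev_spacing_mm: float = 0.5,
    margin_mm: float = 3.0,
) -> BEVImage:
    """Divergent projection of a voxel mask into a binary BEV image.

    Each voxel is supersampled finely enough that its projected footprint
    cannot leave pinholes on the BEV grid.  Voxels at or behind the source
    are excluded and counted.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = grid.voxel_centers(where=mask)
    if pts.size == 0:
        empty = np.zeros((1, 1), dtype=bool)
        return BEVImage(empty, np.zeros(1), np.zeros(1))
    # supersample each voxel; magnification stays < 1.5 for clinical geometry
    subs = [max(1, int(np.ceil(1.6 * s / bev_spacing_mm))) for s in grid.spacing_mm]
    offs = [(np.arange(ns) - (ns - 1) / 2.0) * (s / ns)
            for ns, s in zip(subs, grid.spacing_mm)]
    ox, oy, oz = np.meshgrid(*offs, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    allpts = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)

    u, v, t = project_points(allpts, beam)
    good = t > 1e-6
    excluded = int(np.count_nonzero(~good)) // len(offsets)
    u, v = u[good], v[good]

    u0 = np.floor((u.min() - margin_mm) / bev_spacing_mm) * bev_spacing_mm
    v0 = np.floor((v.min() - margin_mm) / bev_spacing_mm) * bev_spacing_mm
    nu = int(np.ceil((u.max() + margin_mm - u0) / bev_spacing_mm)) + 1
    nv = int(np.ceil((v.max() + margin_mm - v0) / bev_spacing_mm)) + 1
    iu = np.rint((u - u0) / bev_spacing_mm).astype(int)
    iv = np.rint((v - v0) / bev_spacing_mm).astype(int)
    bev = np.zeros((nu, nv), dtype=bool)
    bev[iu, iv] = True
    return BEVImage(
        mask=bev,
        u_axis=u0 + bev_spacing_mm * np.arange(nu),
        v_axis=v0 + bev_spacing_mm * np.arange(nv),
        excluded_points=excluded,
    )


def fit_mlc(
    bev: BEVImage,
    mlc: MLCGeometry = MLCGeometry(),
    overlap_threshold: float = 0.5,
    tip_margin_mm: float = 0.0,
) -> MLCAperture:
    """Fit a static single-interval-per-pair aperture to a BEV mask.

    A leaf pair participates when the mask area inside its width strip is at
    least ``overlap_threshold`` of the strip area spanned by the mask's
    travel-axis extent within that strip (ties open).  Participating pairs
    open over the covering interval [min - margin, max + margin] of the mask
    in their strip, which enforces the single-interval constraint; other
    pairs are closed and parked at the lower jaw.
    """
    edges = mlc.edges()
    du, dv = bev.spacing
    n = mlc.leaf_pair_count
    tips_a = np.zeros(n)
    tips_b = np.zeros(n)
    is_open = np.zeros(n, dtype=bool)

    if bev.mask.any():
        u_occ = bev.u_axis[bev.mask.any(axis=1)]
        if u_occ.min() < edges[0] or u_occ.max() > edges[-1]:
            raise ValueError(
                f"BEV mask (u in [{u_occ.min():.1f}, {u_occ.max():.1f}] mm) is wider "
                f"than the leaf bank ([{edges[0]:.1f}, {edges[-1]:.1f}] mm)")
        for p in range(n):
            in_strip = (bev.u_axis >= edges[p]) & (bev.u_axis < edges[p + 1])
            strip = bev.mask[in_strip, :]
            if strip.size == 0 or not strip.any():
                continue
            v_hit = bev.v_axis[strip.any(axis=0)]
            vmin, vmax = float(v_hit.min()), float(v_hit.max())
            area = strip.sum() * du * dv
            denom = mlc.leaf_width_mm_at_iso * (vmax - vmin + dv)
            if denom <= 0 or area / denom >= overlap_threshold:
                a = vmin - 0.5 * dv - tip_margin_mm
                b = vmax + 0.5 * dv + tip_margin_mm
                if abs(a) > mlc.max_travel_mm or abs(b) > mlc.max_travel_mm:
                    raise ValueError(f"leaf pair {p}: required opening [{a:.1f}, {b:.1f}] mm "
                                     f"exceeds travel range +-{mlc.max_travel_mm} mm")
                tips_a[p], tips_b[p], is_open[p] = a, b, True

    if is_open.any():
        idx = np.nonzero(is_open)[0]
        jaws = (float(edges[idx[0]]), float(edges[idx[-1] + 1]),
                float(tips_a[is_open].min()), float(tips_b[is_open].max()))
        park = jaws[2]
    else:
        jaws = (0.0, 0.0, 0.0, 0.0)
        park = 0.0
    tips_a[~is_open] = park
    tips_b[~is_open] = park
    return MLCAperture(tips_a=tips_a, tips_b=tips_b, is_open=is_open, jaws=jaws, mlc=mlc)


def aperture_open_area(aperture: MLCAperture, mlc: MLCGeometry | None = None) -> tuple[float, float]:
    """Open area (mm^2) and equivalent-square side (mm) of an aperture."""
    mlc = mlc or aperture.mlc
    lengths = (aperture.tips_b - aperture.tips_a)[aperture.is_open]
    area = float(lengths.sum() * mlc.leaf_width_mm_at_iso)
    return area, float(np.sqrt(area))


def aperture_fluence(
    aperture: MLCAperture,
    u_axis: np.ndarray,
    v_axis: np.ndarray,
) -> np.ndarray:
    """Binary primary-fluence map of an aperture on a BEV (u, v) grid."""
    mlc = aperture.mlc
    edges = mlc.edges()
    f = np.zeros((len(u_axis), len(v_axis)), dtype=float)
    for p in np.nonzero(aperture.is_open)[0]:
        in_u = (u_axis >= edges[p]) & (u_axis < edges[p + 1])
        in_v = (v_axis >= aperture.tips_a[p]) & (v_axis <= aperture.tips_b[p])
        f[np.ix_(in_u, in_v)] = 1.0
    return f
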