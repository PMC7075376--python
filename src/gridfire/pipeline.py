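"""End-to-end plan orchestration: lattice -> apertures -> dose -> metrics.

This is the importable counterpart of the command-line interface: one call
takes a CT volume plus structures and returns the lattice, the six fitted
crossfire fields, the composite dose and the full metric set, with the
field-by-field TMR monitor-unit second check alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beams import BeamSpec, MLCAperture, MLCGeometry, fit_mlc, make_crossfire_beams, project_bev
from .core import ImageVolume, Structure, StructureSet
from .dose import BeamModel, PlanResult, plan_dose, select_energy
from .evaluate import PlanMetrics, evaluate_plan, tmr_mu_check
from .lattice import LatticeResult, LatticeSpec, build_lattice

__all__ = ["PlanSetup", "PlanOutcome", "build_plan"]


@dataclass(frozen=True)
class PlanSetup:
    """Planning parameters (defaults are the standard crossfire technique)."""

    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    energy: str = "auto"  # "auto" | "6MV" | "18MV"
    prescription_gy: float = 15.0
    normalization: str = "max110"
    weighting: str = "equal"
    dose_rate_mu_per_min: float = 400.0
    n_beams: int = 6
    start_deg: float = 210.0
    spacing_deg: float = 60.0
    mlc: MLCGeometry = field(default_factory=MLCGeometry)
    overlap_threshold: float = 0.5
    tip_margin_mm: float = 0.0
    bev_spacing_mm: float = 0.5
    depth_steps: int = 160
    gtv_name: str = "GTV"
    body_name: str = "BODY"

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class PlanOutcome:
    lattice: LatticeResult
    lattice_structure: Structure
    beams: list[BeamSpec]
    apertures: list[MLCAperture]
    plan: PlanResult
    metrics: PlanMetrics
    mu_check_independent: np.ndarray
    mu_check_percent_diff: np.ndarray
    energy: str


def _target_depth_mm(volume: ImageVolume, body: np.ndarray, centroid_mm: np.ndarray) -> float:
    """Distance from the body surface to a point (its minimum depth)."""
    grid = volume.grid
    dist = ndimage.distance_transform_edt(body, sampling=grid.spacing_mm[::-1])
    dx, dy, dz = grid.spacing_mm
    x0, y0, z0 = grid.origin_mm
    idx = [(centroid_mm[2] - z0) / dz, (centroid_mm[1] - y0) / dy, (centroid_mm[0] - x0) / dx]
    return float(ndimage.map_coordinates(dist, np.asarray(idx)[:, None], order=1)[0])


def build_plan(
    volume: ImageVolume,
    structures: StructureSet,
    setup: PlanSetup = PlanSetup(),
    models: dict[str, BeamModel] | None = None,
) -> PlanOutcome:
    """Run the full crossfire GRID planning chain on one case."""
    grid = volume.grid
    for name in (setup.gtv_name, setup.body_name):
        if name not in structures:
            raise KeyError(f"required structure {name!r} missing; "
                           f"available: {structures.names()}")
    gtv = structures.mask(setup.gtv_name, grid)
    body = structures.mask(setup.body_name, grid)

    lattice = build_lattice(gtv, grid, setup.lattice)
    lattice_structure = Structure.from_mask(f"{setup.gtv_name}_GRID", lattice.mask, grid,
                                            color=(255, 128, 0))

    x, y, z = grid.axis_coords()
    k, j, i = np.nonzero(gtv)
    iso = np.array([x[i].mean(), y[j].mean(), z[k].mean()])

    energy = setup.energy
    if energy == "auto":
        energy = select_energy(_target_depth_mm(volume, body, iso))
    if models is None:
        models = {energy: BeamModel.default(energy)}

    beams = make_crossfire_beams(tuple(iso), energy, start_deg=setup.start_deg,
                                 n=setup.n_beams, spacing_deg=setup.spacing_deg,
                                 dose_rate_mu_per_min=setup.dose_rate_mu_per_min)
    apertures = [
        fit_mlc(project_bev(lattice.mask, grid, b, bev_spacing_mm=setup.bev_spacing_mm),
                setup.mlc, overlap_threshold=setup.overlap_threshold,
                tip_margin_mm=setup.tip_margin_mm)
        for b in beams
    ]
    plan = plan_dose(volume, beams, apertures, models, setup.prescription_gy,
                     normalization_mode=setup.normalization, weighting=setup.weighting,
                     depth_steps=setup.depth_steps)
    metrics = evaluate_plan(plan, structures, grid,
                            gtv_name=setup.gtv_name, body_name=setup.body_name)

    mu_indep = np.zeros(len(beams))
    mu_pct = np.zeros(len(beams))
    for q, (b, ap) in enumerate(zip(beams, apertures)):
        mu_indep[q], mu_pct[q] = tmr_mu_check(
            volume, b, ap, models[b.energy_label],
            plan.field_iso_dose_gy[q], plan.mu[q])

    return PlanOutcome(
        lattice=lattice,
        lattice_structure=lattice_structure,
        beams=beams,
        apertures=apertures,
        plan=plan,
        metrics=metrics,
        mu_check_independent=mu_indep,
        mu_check_percent_diff=mu_pct,
        energy=energy,
    )
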