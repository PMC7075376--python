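"""Plan-quality metrics, protocol compliance, MU verification, escalation.

Implements the GRID-plan evaluation quantities: the peak-to-valley dose ratio
(maximum over minimum dose inside the target), cumulative DVH metrics (Dmax,
mean, DxCC), the skin-shell doses, the D2cm spillage metric (maximum dose at
>= 2 cm from the target surface, in % of prescription), single-fraction
organ-at-risk limits, a TMR-based field-by-field monitor-unit second check,
the single-field GRID-block MU look-up formula, and the linear dose-
escalation simulation (15 -> 23 Gy against the skin limits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .beams import MLCAperture, aperture_open_area, beam_frame
from .core import Grid, ImageVolume
from .dose import BeamModel, PlanResult, beam_on_time, radiological_depth

log = logging.getLogger(__name__)

__all__ = [
    "PlanMetrics",
    "RTOGLimits",
    "pvdr",
    "DVH",
    "dvh",
    "d2cm",
    "rtog_check",
    "tmr_mu_check",
    "aperture_point_factor",
    "gridblock_mu",
    "evaluate_plan",
    "escalate",
    "summarize_cohort",
]


@dataclass
class PlanMetrics:
    prescription_gy: float
    mean_gtv_dose_gy: float
    pvdr: float
    skin_dmax_gy: float
    skin_d5cc_gy: float
    skin_d10cc_gy: float
    d2cm_percent: float
    oar_max_gy: dict[str, float] = field(default_factory=dict)
    total_mu: float = 0.0
    beam_on_time_min: float = 0.0

    def scaled(self, factor: float) -> "PlanMetrics":
        """Metrics after a linear rescale of the prescription (engine linearity)."""
        return replace(
            self,
            prescription_gy=self.prescription_gy * factor,
            mean_gtv_dose_gy=self.mean_gtv_dose_gy * factor,
            skin_dmax_gy=self.skin_dmax_gy * factor,
            skin_d5cc_gy=self.skin_d5cc_gy * factor,
            skin_d10cc_gy=self.skin_d10cc_gy * factor,
            oar_max_gy={k: v * factor for k, v in self.oar_max_gy.items()},
            total_mu=self.total_mu * factor,
            beam_on_time_min=self.beam_on_time_min * factor,
        )


@dataclass(frozen=True)
class RTOGLimits:
    """Single-fraction organ-at-risk dose limits (Gy), strict '<' semantics."""

    cord_max: float = 14.0
    heart_max: float = 22.0
    esophagus_max: float = 15.4
    ribs_max: float = 30.0
    ribs_1cc: float = 22.0
    skin_max: float = 26.0
    skin_10cc: float = 23.0
    stomach_bowel_max: float = 12.4
    stomach_bowel_10cc: float = 11.2

    def __post_init__(self) -> None:
        vals = self.__dict__.values()
        if any(v <= 0 for v in vals):
            raise ValueError("all dose limits must be positive")
        for organ, (dxcc, dmax) in {
            "ribs": (self.ribs_1cc, self.ribs_max),
            "skin": (self.skin_10cc, self.skin_max),
            "stomach_bowel": (self.stomach_bowel_10cc, self.stomach_bowel_max),
        }.items():
            if dxcc > dmax:
                raise ValueError(f"{organ}: DxCC limit must not exceed the max limit")


# (organ key, metric) pairs evaluated by rtog_check
_CONSTRAINTS = [
    ("cord", "dmax", "cord_max"),
    ("heart", "dmax", "heart_max"),
    ("esophagus", "dmax", "esophagus_max"),
    ("ribs", "dmax", "ribs_max"),
    ("ribs", "d1cc", "ribs_1cc"),
    ("skin", "dmax", "skin_max"),
    ("skin", "d10cc", "skin_10cc"),
    ("stomach_bowel", "dmax", "stomach_bowel_max"),
    ("stomach_bowel", "d10cc", "stomach_bowel_10cc"),
]


def pvdr(dose: np.ndarray, gtv_mask: np.ndarray, erode_voxels: int = 0) -> float:
    """Peak-to-valley dose ratio: max/min dose inside the target.

    Optional mask erosion suppresses boundary interpolation artifacts (off by
    default).  A zero minimum is reported as ``inf`` (flagged in the log).
    """
    mask = np.asarray(gtv_mask, dtype=bool)
    if erode_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_voxels)
    if not mask.any():
        raise ValueError("target mask is empty (after erosion)")
    vals = np.asarray(dose)[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("dose contains non-finite values inside the target")
    lo = float(vals.min())
    if lo == 0.0:
        log.warning("PVDR: minimum target dose is zero; ratio reported as inf")
        return float("inf")
    return float(vals.max()) / lo


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    dose_gy: np.ndarray  # ascending dose axis
    volume_cc: np.ndarray  # volume receiving >= dose (monotone non-increasing)
    sorted_doses: np.ndarray  # per-voxel doses, descending
    voxel_cc: float

    @property
    def total_volume_cc(self) -> float:
        return len(self.sorted_doses) * self.voxel_cc

    @property
    def dmax(self) -> float:
        return float(self.sorted_doses[0])

    @property
    def dmean(self) -> float:
        return float(self.sorted_doses.mean())

    def dose_at_volume(self, v_cc: float) -> float:
        """Minimum dose to the hottest ``v_cc`` cm^3 (DxCC); D(0+) is Dmax."""
        if v_cc < 0:
            raise ValueError("volume must be non-negative")
        if v_cc > self.total_volume_cc:
            log.warning("requested %.1f cc exceeds structure volume %.1f cc; "
                        "returning minimum dose", v_cc, self.total_volume_cc)
            return float(self.sorted_doses[-1])
        n = int(np.ceil(v_cc / self.voxel_cc))
        return float(self.sorted_doses[max(0, min(n, len(self.sorted_doses)) - 1)])

    def volume_at_dose(self, d_gy: float) -> float:
        return float(np.count_nonzero(self.sorted_doses >= d_gy) * self.voxel_cc)


def dvh(dose: np.ndarray, mask: np.ndarray, grid: Grid, n_bins: int = 256) -> DVH:
    """Cumulative DVH of ``mask`` (volumes are voxel count x voxel volume)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("structure mask is empty")
    vox_cc = grid.voxel_volume_mm3 / 1000.0
    vals = np.sort(np.asarray(dose)[mask])[::-1]
    axis = np.linspace(0.0, max(vals[0], 1e-12), n_bins)
    volume = np.array([np.count_nonzero(vals >= d) for d in axis]) * vox_cc
    return DVH(dose_gy=axis, volume_cc=volume, sorted_doses=vals, voxel_cc=vox_cc)


def d2cm(
    dose: np.ndarray,
    gtv_mask: np.ndarray,
    body_mask: np.ndarray,
    grid: Grid,
    prescription_gy: float,
    distance_mm: float = 20.0,
) -> float:
    """Maximum dose >= 2 cm from the target surface, as % of prescription."""
    gtv = np.asarray(gtv_mask, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~gtv, sampling=grid.spacing_mm[::-1])
    sel = body & (dist >= distance_mm)
    if not sel.any():
        log.warning("D2cm not applicable: no body voxels beyond %.0f mm of the target",
                    distance_mm)
        return float("nan")
    return float(np.asarray(dose)[sel].max()) / prescription_gy * 100.0


def rtog_check(measured: dict[str, dict[str, float]], limits: RTOGLimits) -> pd.DataFrame:
    """Per-constraint compliance table.

    ``measured`` maps organ keys (cord, heart, esophagus, ribs, skin,
    stomach_bowel) to their available metrics ({"dmax": Gy, "d1cc": Gy,
    "d10cc": Gy}).  Limits use strict '<': a value exactly at the limit
    fails.  Missing organs or metrics are reported as not-evaluated, which
    does not break overall compliance.
    """
    rows = []
    for organ, metric, limit_name in _CONSTRAINTS:
        limit = getattr(limits, limit_name)
        value = measured.get(organ, {}).get(metric)
        if value is None:
            rows.append((organ, metric, np.nan, limit, np.nan, "not-evaluated"))
        else:
            status = "pass" if value < limit else "fail"
            rows.append((organ, metric, value, limit, limit - value, status))
    df = pd.DataFrame(rows, columns=["organ", "metric", "value_gy", "limit_gy",
                                     "margin_gy", "status"])
    df.attrs["overall_pass"] = bool((df["status"] != "fail").all())
    return df


def _erf_rect_sum(aperture: MLCAperture, sigma_mm: float, u: float, v: float) -> float:
    """Integral of a Gaussian kernel at (u, v) over the open leaf rectangles."""
    edges = aperture.mlc.edges()
    if sigma_mm <= 0:
        for p in np.nonzero(aperture.is_open)[0]:
            if edges[p] <= u < edges[p + 1] and aperture.tips_a[p] <= v <= aperture.tips_b[p]:
                return 1.0
        return 0.0
    total = 0.0
    for p in np.nonzero(aperture.is_open)[0]:
        fu = ndtr((edges[p + 1] - u) / sigma_mm) - ndtr((edges[p] - u) / sigma_mm)
        fv = ndtr((aperture.tips_b[p] - v) / sigma_mm) - ndtr((aperture.tips_a[p] - v) / sigma_mm)
        total += fu * fv
    return float(total)


def aperture_point_factor(aperture: MLCAperture, model: BeamModel,
                          u: float = 0.0, v: float = 0.0) -> float:
    """Fluence of the dual-Gaussian kernel at a BEV point, by closed-form erf sums.

    Integrates the narrow penumbra and broad scatter kernel components over
    every open leaf rectangle and adds the closed-leaf transmission; this is
    the analytic counterpart of the engine's grid convolution and serves as
    the grid-aperture output correction in the MU second check.  For a broad
    open field the factor is ~1.
    """
    a = _erf_rect_sum(aperture, model.penumbra_sigma_mm, u, v)
    if model.scatter_weight > 0:
        a = ((1.0 - model.scatter_weight) * a
             + model.scatter_weight * _erf_rect_sum(aperture, model.scatter_sigma_mm, u, v))
    t = model.mlc_transmission
    return t + (1.0 - t) * a


def tmr_mu_check(
    volume: ImageVolume,
    beam: BeamSpec,
    aperture: MLCAperture,
    model: BeamModel,
    dose_at_iso_gy: float,
    mu_plan: float,
    include_aperture_factor: bool = True,
) -> tuple[float, float]:
    """Independent TMR-based MU for one field and % difference vs the plan MU.

    MU = D / [output x Sc,p(s) x TMR(d_iso, s) x A] with d_iso the ray-traced
    water-equivalent depth to the isocenter, s the equivalent square of the
    open aperture, and A the analytic grid-aperture factor at the isocenter
    (1 for broad open fields; see :func:`aperture_point_factor`).  The depth
    and the aperture factor are computed by routes independent of the dose
    engine.  %diff = 100 (MU_plan - MU_indep) / MU_indep.
    """
    source, _, _, _ = beam_frame(beam)
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    d_iso = radiological_depth(volume, source, iso)
    _, side = aperture_open_area(aperture)
    tmr = float(model.tmr(d_iso, side)[0])
    if tmr <= 0:
        raise ValueError(f"TMR is zero at depth {d_iso:.1f} mm; cannot verify MU")
    a = aperture_point_factor(aperture, model) if include_aperture_factor else 1.0
    if a <= 0:
        raise ValueError("isocenter receives no primary fluence from this aperture")
    mu_indep = (dose_at_iso_gy * 100.0) / (
        model.output_cgy_per_mu * model.scp(side) * model.grid_output_factor * tmr * a)
    pct = 100.0 * (mu_plan - mu_indep) / mu_indep
    return mu_indep, pct


def gridblock_mu(
    prescribed_dose_cgy: float,
    model: BeamModel | None = None,
    field_size_mm: float | None = None,
    depth_mm: float | None = None,
    pdd_percent: float | None = None,
) -> float:
    """Single-field GRID-block MU: dose / [cGy/MU(dmax) x %DD(r, d)], SSD 100.

    ``pdd_percent`` may be given directly (a look-up-table value); otherwise
    it is taken from the beam model's %DD table at (depth, field size).
    """
    output = model.output_cgy_per_mu if model is not None else 1.0
    if pdd_percent is None:
        if model is None or field_size_mm is None or depth_mm is None:
            raise ValueError("need either pdd_percent or (model, field size, depth)")
        pdd_percent = float(model.pdd(depth_mm, field_size_mm)[0])
    if pdd_percent <= 0:
        raise ValueError("%DD must be positive")
    return prescribed_dose_cgy / (output * pdd_percent / 100.0)


# Structure-name aliases -> canonical organ keys used by the limits table.
STRUCTURE_ORGAN_KEYS = {
    "CORD": "cord",
    "SPINALCORD": "cord",
    "HEART": "heart",
    "ESOPHAGUS": "esophagus",
    "RIBS": "ribs",
    "SKIN": "skin",
    "STOMACH": "stomach_bowel",
    "BOWEL": "stomach_bowel",
}


def evaluate_plan(
    plan: PlanResult,
    structures,
    grid: Grid,
    gtv_name: str = "GTV",
    skin_name: str = "SKIN",
    body_name: str = "BODY",
) -> PlanMetrics:
    """Compute the full metric set of a composite plan."""
    dose = plan.dose.values
    gtv = structures.mask(gtv_name, grid)
    body = structures.mask(body_name, grid)
    skin = structures.mask(skin_name, grid)
    skin_dvh = dvh(dose, skin, grid)
    oar = {}
    for s in structures:
        if s.name in (gtv_name, skin_name, body_name) or s.name.startswith("GTV_"):
            continue
        oar[s.name] = float(dose[s.mask(grid)].max()) if s.mask(grid).any() else 0.0
    rate = plan.beams[0].dose_rate_mu_per_min
    return PlanMetrics(
        prescription_gy=plan.prescription_gy,
        mean_gtv_dose_gy=float(dose[gtv].mean()),
        pvdr=pvdr(dose, gtv),
        skin_dmax_gy=skin_dvh.dmax,
        skin_d5cc_gy=skin_dvh.dose_at_volume(5.0),
        skin_d10cc_gy=skin_dvh.dose_at_volume(10.0),
        d2cm_percent=d2cm(dose, gtv, body, grid, plan.prescription_gy),
        oar_max_gy=oar,
        total_mu=plan.total_mu,
        beam_on_time_min=beam_on_time(plan.total_mu, rate),
    )


def _measured_from_metrics(m: PlanMetrics) -> dict[str, dict[str, float]]:
    measured: dict[str, dict[str, float]] = {
        "skin": {"dmax": m.skin_dmax_gy, "d10cc": m.skin_d10cc_gy},
    }
    for name, dmax_gy in m.oar_max_gy.items():
        key = STRUCTURE_ORGAN_KEYS.get(name.upper().replace(" ", ""))
        if key is not None:
            measured.setdefault(key, {})["dmax"] = dmax_gy
    return measured


def escalate(
    base: PlanMetrics,
    limits: RTOGLimits = RTOGLimits(),
    dp_values_gy: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Dose-escalation simulation: rescale the plan linearly over Dp values.

    Every dose metric scales with Dp / Dp_base (engine linearity), so the
    table reports skin Dmax / D5cc / D10cc and overall limit compliance per
    prescription, plus the largest prescription on the grid that passes all
    limits (``None`` when none does, including a base plan already failing).
    """
    if dp_values_gy is None:
        dp_values_gy = np.arange(15.0, 23.0 + 1e-9, 1.0)
    if not base.prescription_gy > 0:
        raise ValueError("base plan must carry a positive prescription")
    rows = []
    feasible: float | None = None
    for dp in dp_values_gy:
        m = base.scaled(dp / base.prescription_gy)
        table = rtog_check(_measured_from_metrics(m), limits)
        ok = table.attrs["overall_pass"]
        rows.append((dp, m.skin_dmax_gy, m.skin_d5cc_gy, m.skin_d10cc_gy, ok))
        if ok and (feasible is None or dp > feasible):
            feasible = float(dp)
    df = pd.DataFrame(rows, columns=["dp_gy", "skin_dmax_gy", "skin_d5cc_gy",
                                     "skin_d10cc_gy", "all_limits_pass"])
    return df, feasible


def summarize_cohort(metrics: list[PlanMetrics]) -> pd.DataFrame:
    """Mean +- SD (sample, n-1) and range per metric over a cohort of plans."""
    if not metrics:
        raise ValueError("empty cohort")
    cols = ["mean_gtv_dose_gy", "pvdr", "skin_dmax_gy", "skin_d5cc_gy",
            "skin_d10cc_gy", "d2cm_percent", "total_mu", "beam_on_time_min"]
    df = pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metrics])
    single = len(metrics) == 1
    if single:
        log.warning("cohort of one plan: SD reported as 0")
    out = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1).fillna(0.0) if not single else pd.Series(0.0, index=df.columns),
        "min": df.min(),
        "max": df.max(),
        "n": len(metrics),
    })
    return out
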