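"""Metrics, compliance, MU verification and escalation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gridfire as gf
from gridfire.core import Grid
from gridfire.dose import BeamModel
from gridfire.evaluate import (
    RTOGLimits,
    aperture_point_factor,
    d2cm,
    dvh,
    escalate,
    gridblock_mu,
    pvdr,
    rtog_check,
    summarize_cohort,
    tmr_mu_check,
)


def _grid(shape=(10, 10, 10), spacing=2.0):
    return Grid(shape, (spacing,) * 3, (0.0, 0.0, 0.0))


# -- PVDR -------------------------------------------------------------------


def test_pvdr_uniform_is_one():
    d = np.full((4, 4, 4), 7.0)
    assert pvdr(d, np.ones_like(d, bool)) == 1.0


def test_pvdr_toy_values():
    d = np.zeros((1, 1, 3))
    d[0, 0] = [4.0, 6.0, 10.0]
    assert pvdr(d, np.ones_like(d, bool)) == pytest.approx(2.5)


def test_pvdr_zero_minimum_is_inf():
    d = np.zeros((2, 2, 2))
    d[0, 0, 0] = 5.0
    assert pvdr(d, np.ones_like(d, bool)) == np.inf


def test_pvdr_erosion_drops_boundary():
    d = np.full((5, 5, 5), 10.0)
    d[0, 0, 0] = 1.0  # cold corner voxel
    m = np.ones_like(d, bool)
    assert pvdr(d, m) == 10.0
    assert pvdr(d, m, erode_voxels=1) == 1.0  # corner eroded away


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.floats(0.1, 50.0))
def test_pvdr_invariant_under_scaling(scale):
    rng = np.random.default_rng(5)
    d = rng.uniform(1.0, 9.0, size=(4, 4, 4))
    m = np.ones_like(d, bool)
    assert pvdr(d * scale, m) == pytest.approx(pvdr(d, m), rel=1e-12)


# -- DVH --------------------------------------------------------------------


def test_dvh_uniform_structure():
    g = _grid()  # 8 mm3 voxels; 1000 voxels = 8 cc
    d = np.full(g.shape, 10.0)
    m = np.ones(g.shape, bool)
    h = dvh(d, m, g)
    assert h.total_volume_cc == pytest.approx(8.0)
    assert h.dose_at_volume(5.0) == 10.0
    assert h.dmax == 10.0
    assert h.volume_at_dose(0.0) == pytest.approx(8.0)  # full structure volume


def test_dvh_linear_ramp_quantile_oracle():
    """D(v) on a linear ramp matches the sorting-based quantile within a voxel."""
    g = Grid((1, 1, 1000), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    d = np.linspace(0.0, 20.0, 1000).reshape(g.shape)
    m = np.ones(g.shape, bool)
    h = dvh(d, m, g)
    vox_cc = 1e-3
    for v_cc in (0.05, 0.2, 0.5):
        n = int(np.ceil(v_cc / vox_cc))
        oracle = np.sort(d.ravel())[::-1][n - 1]
        assert h.dose_at_volume(v_cc) == pytest.approx(oracle, abs=20.0 / 1000)


def test_dvh_monotone_non_increasing():
    rng = np.random.default_rng(2)
    g = _grid()
    d = rng.uniform(0, 30, g.shape)
    h = dvh(d, np.ones(g.shape, bool), g)
    assert np.all(np.diff(h.volume_cc) <= 1e-12)


def test_dvh_overflow_volume_returns_min():
    g = _grid((2, 2, 2))
    d = np.arange(8.0).reshape(g.shape)
    h = dvh(d, np.ones(g.shape, bool), g)
    assert h.dose_at_volume(1e6) == 0.0


def test_dvh_empty_structure_rejected():
    g = _grid()
    with pytest.raises(ValueError):
        dvh(np.zeros(g.shape), np.zeros(g.shape, bool), g)


# -- D2cm -------------------------------------------------------------------


def _sphere_masks(n=40, spacing=2.0, r_gtv=12.0):
    g = Grid((n, n, n), (spacing,) * 3,
             (-(n - 1) / 2 * spacing,) * 3)
    x, y, z = g.axis_coords()
    rr = np.sqrt(x[None, None, :] ** 2 + y[None, :, None] ** 2 + z[:, None, None] ** 2)
    return g, rr <= r_gtv, rr <= 36.0


def test_d2cm_uniform_dose_is_100pct():
    g, gtv, body = _sphere_masks()
    d = np.full(g.shape, 15.0)
    assert d2cm(d, gtv, body, g, 15.0) == pytest.approx(100.0)


def test_d2cm_zero_outside_margin_is_0pct():
    g, gtv, body = _sphere_masks()
    from scipy import ndimage
    dist = ndimage.distance_transform_edt(~gtv, sampling=g.spacing_mm[::-1])
    d = np.where(dist < 20.0, 15.0, 0.0)
    assert d2cm(d, gtv, body, g, 15.0) == 0.0


def test_d2cm_matches_brute_force_distance_oracle():
    """Equality with a cdist-based distance map on a small random dose."""
    from scipy.spatial.distance import cdist

    g, gtv, body = _sphere_masks(n=24, spacing=3.0)
    rng = np.random.default_rng(9)
    d = rng.uniform(0, 10, g.shape)
    pts = g.voxel_centers()
    gtv_pts = g.voxel_centers(where=gtv)
    dist = cdist(pts, gtv_pts).min(axis=1).reshape(g.shape)
    sel = body & (dist >= 20.0)
    oracle = d[sel].max() / 15.0 * 100.0
    assert d2cm(d, gtv, body, g, 15.0) == pytest.approx(oracle, rel=1e-9)


def test_d2cm_not_applicable_flagged_nan():
    g, gtv, _ = _sphere_masks()
    assert np.isnan(d2cm(np.zeros(g.shape), gtv, gtv, g, 15.0))


# -- RTOG compliance --------------------------------------------------------


def test_rtog_pass_fail_and_strict_boundary():
    limits = RTOGLimits()
    measured = {
        "cord": {"dmax": 6.7},          # pass (Table-2-like value vs 14.0)
        "skin": {"dmax": 26.0, "d10cc": 5.0},  # exactly at limit -> fail
    }
    t = rtog_check(measured, limits)
    assert t.loc[(t.organ == "cord") & (t.metric == "dmax"), "status"].item() == "pass"
    assert t.loc[(t.organ == "skin") & (t.metric == "dmax"), "status"].item() == "fail"
    assert not t.attrs["overall_pass"]


def test_rtog_missing_structures_not_evaluated():
    t = rtog_check({}, RTOGLimits())
    assert (t.status == "not-evaluated").all()
    assert t.attrs["overall_pass"]  # not-evaluated does not fail the plan


def test_rtog_zero_dose_passes_everything():
    measured = {k: {"dmax": 0.0, "d1cc": 0.0, "d10cc": 0.0}
                for k in ("cord", "heart", "esophagus", "ribs", "skin", "stomach_bowel")}
    t = rtog_check(measured, RTOGLimits())
    assert t.attrs["overall_pass"]


def test_rtog_limits_validation():
    with pytest.raises(ValueError):
        RTOGLimits(cord_max=-1.0)
    with pytest.raises(ValueError):
        RTOGLimits(skin_10cc=30.0)  # DxCC above the max limit


# -- MU checks --------------------------------------------------------------


def _flat_model(tmr=0.785, scp=0.95):
    """Synthetic beam model with constant TMR/Sc,p and no kernel blur."""
    depths = np.array([0.0, 400.0])
    sides = np.array([20.0, 250.0])
    return BeamModel(
        energy_label="6MV", dmax_mm=15.0, mu_eff_per_mm=0.0,
        penumbra_sigma_mm=0.0, scatter_weight=0.0, scatter_sigma_mm=0.0,
        mlc_transmission=0.0, output_cgy_per_mu=1.0,
        depths_mm=depths, sides_mm=sides,
        tmr_table=np.full((2, 2), tmr), pdd_table=np.full((2, 2), 100.0),
        scp_table=np.full(2, scp),
    )


def test_tmr_mu_hand_calculation(small_case):
    """250 cGy with TMR 0.785 and Sc,p 0.95 needs 250/(0.785*0.95) = 335.2 MU."""
    _, vol, _ = small_case
    from gridfire.beams import BEVImage, fit_mlc

    u = np.arange(-60.0, 60.0, 0.5)
    mask = (np.abs(u)[:, None] <= 50) & (np.abs(u)[None, :] <= 50)
    ap = fit_mlc(BEVImage(mask, u, u))
    beam = gf.BeamSpec(gantry_deg=0.0, energy_label="6MV", isocenter_mm=(0.0, -50.0, 0.0))
    model = _flat_model()
    mu, _ = tmr_mu_check(vol, beam, ap, model, dose_at_iso_gy=2.50, mu_plan=335.0)
    assert mu == pytest.approx(250.0 / (0.785 * 0.95), abs=0.05)


def test_mu_check_zero_for_open_reference_field(model_open_field_check=None):
    """Engine and check share the calibration: %diff ~ 0 for a broad open field."""
    from gridfire.beams import BEVImage, BeamSpec, fit_mlc
    from gridfire.dose import beam_dose
    from gridfire.core import ImageVolume

    model = BeamModel.default("6MV")
    spacing = 2.0
    vol = ImageVolume(values=np.zeros((100, 80, 80)), spacing_mm=(spacing,) * 3,
                      origin_mm=(-79.0, 0.0, -99.0))
    iso = (0.0, 100.0, 0.0)
    u = np.arange(-80.0, 80.0, 0.5)
    mask = (np.abs(u)[:, None] <= 50) & (np.abs(u)[None, :] <= 50)
    ap = fit_mlc(BEVImage(mask, u, u))
    beam = BeamSpec(gantry_deg=0.0, energy_label="6MV", isocenter_mm=iso)
    d = beam_dose(vol, beam, ap, model, mu=100.0,
                  compute_mask=np.ones(vol.values.shape, bool), depth_steps=120)
    g = d.grid
    iso_dose = d.values[g.z_to_slice(0.0), 50, 40]
    mu_indep, pct = tmr_mu_check(vol, beam, ap, model, iso_dose, 100.0)
    assert abs(pct) < 1.0


def test_aperture_factor_is_one_for_broad_field():
    from gridfire.beams import BEVImage, fit_mlc

    u = np.arange(-100.0, 100.0, 0.5)
    mask = (np.abs(u)[:, None] <= 80) & (np.abs(u)[None, :] <= 80)
    ap = fit_mlc(BEVImage(mask, u, u))
    a = aperture_point_factor(ap, BeamModel.default("18MV"))
    assert a == pytest.approx(1.0, abs=0.01)


def test_mu_check_benchmark_within_3pct(benchmark_outcome):
    """Field-by-field TMR second check agrees with the engine within 3%."""
    assert np.abs(benchmark_outcome.mu_check_percent_diff).mean() <= 3.0


# -- GRID-block MU ----------------------------------------------------------


def test_gridblock_mu_arithmetic():
    assert gridblock_mu(1500.0, pdd_percent=100.0) == pytest.approx(1500.0)
    assert gridblock_mu(1500.0, pdd_percent=50.0) == pytest.approx(3000.0)
    mu = gridblock_mu(1500.0, pdd_percent=81.5)
    assert mu == pytest.approx(1840.5, abs=0.05)
    assert mu / 400.0 == pytest.approx(4.6, abs=0.005)  # minutes at 400 MU/min


def test_gridblock_mu_from_model_table():
    model = BeamModel.default("18MV")
    depth, size = 100.0, 144.0
    expected = 1500.0 / (model.output_cgy_per_mu * float(model.pdd(depth, size)[0]) / 100.0)
    assert gridblock_mu(1500.0, model, size, depth) == pytest.approx(expected)
    with pytest.raises(ValueError):
        gridblock_mu(1500.0, pdd_percent=0.0)


# -- escalation -------------------------------------------------------------


def _metrics(skin_dmax=5.0, dp=15.0):
    return gf.PlanMetrics(
        prescription_gy=dp, mean_gtv_dose_gy=13.0, pvdr=2.0,
        skin_dmax_gy=skin_dmax, skin_d5cc_gy=skin_dmax * 0.8,
        skin_d10cc_gy=skin_dmax * 0.7, d2cm_percent=65.0,
        oar_max_gy={"CORD": 1.0}, total_mu=2000.0, beam_on_time_min=5.0,
    )


def test_escalation_linearity_exact():
    table, _ = escalate(_metrics())
    v15 = table.loc[table.dp_gy == 15.0, "skin_dmax_gy"].item()
    v23 = table.loc[table.dp_gy == 23.0, "skin_dmax_gy"].item()
    assert v23 == pytest.approx(v15 * 23.0 / 15.0, rel=1e-12)
    assert len(table) == 9
    assert table.dp_gy.is_monotonic_increasing


def test_escalation_feasibility_cutoff():
    # skin Dmax 18 Gy at 15 Gy: fails the 26 Gy limit above Dp 21.67
    table, feasible = escalate(_metrics(skin_dmax=18.0))
    assert feasible == 21.0
    assert not table.loc[table.dp_gy == 22.0, "all_limits_pass"].item()


def test_escalation_degenerate_limits_infeasible():
    tiny = RTOGLimits(**{f: 1e-6 for f in RTOGLimits().__dict__})
    table, feasible = escalate(_metrics(), limits=tiny)
    assert feasible is None
    assert not table.all_limits_pass.any()


# -- cohort summary ---------------------------------------------------------


def test_summarize_single_plan_sd_zero():
    out = summarize_cohort([_metrics()])
    assert (out["sd"] == 0.0).all()
    assert (out["n"] == 1).all()


def test_summarize_sample_sd_and_range():
    ms = [_metrics(), _metrics(), _metrics()]
    for m, v in zip(ms, (1.7, 2.0, 2.4)):
        m.pvdr = v
    out = summarize_cohort(ms)
    assert out.loc["pvdr", "mean"] == pytest.approx(np.mean([1.7, 2.0, 2.4]))
    assert out.loc["pvdr", "sd"] == pytest.approx(np.std([1.7, 2.0, 2.4], ddof=1))
    assert out.loc["pvdr", "min"] == 1.7 and out.loc["pvdr", "max"] == 2.4


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize_cohort([])
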