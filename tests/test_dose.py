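"""Dose engine: model tables, depth tracing, calibration, physics invariants."""

import numpy as np
import pytest

import gridfire as gf
from gridfire.beams import BEVImage, BeamSpec, MLCGeometry, fit_mlc
from gridfire.core import ImageVolume
from gridfire.dose import BeamModel, beam_dose, beam_on_time, plan_dose, radiological_depth


@pytest.fixture(scope="module")
def model18():
    return BeamModel.default("18MV")


@pytest.fixture(scope="module")
def model6():
    return BeamModel.default("6MV")


def _water_slab(n=(90, 60, 60), spacing=4.0, hu=0.0):
    """Uniform slab volume; the anterior surface is at y = origin - spacing/2."""
    values = np.full(n, hu)
    origin = (-(n[2] - 1) / 2 * spacing, 0.0, -(n[0] - 1) / 2 * spacing)
    return ImageVolume(values=values, spacing_mm=(spacing,) * 3, origin_mm=origin)


def _open_square_aperture(side_mm=100.0):
    """A centered open square field built from an explicit BEV mask."""
    u = np.arange(-80.0, 80.0, 0.5)
    v = np.arange(-80.0, 80.0, 0.5)
    mask = (np.abs(u)[:, None] <= side_mm / 2) & (np.abs(v)[None, :] <= side_mm / 2)
    return fit_mlc(BEVImage(mask=mask, u_axis=u, v_axis=v), MLCGeometry())


# -- beam model tables ------------------------------------------------------


@pytest.mark.parametrize("energy", ["6MV", "18MV"])
def test_tmr_table_invariants(energy):
    m = BeamModel.default(energy)
    assert float(m.tmr(m.dmax_mm, 100.0)[0]) == pytest.approx(1.0, abs=1e-3)
    assert float(m.pdd(m.dmax_mm, 100.0)[0]) == pytest.approx(100.0, abs=0.1)
    depths = np.arange(m.dmax_mm, 390.0, 2.5)
    tmr = m.tmr(depths, 100.0)
    assert np.all(np.diff(tmr) < 0)  # strictly decreasing beyond dmax


def test_packaged_models_match_analytic():
    for energy in ("6MV", "18MV"):
        packaged = BeamModel.default(energy)
        analytic = BeamModel.analytic(energy)
        assert np.allclose(packaged.tmr_table, analytic.tmr_table, atol=1e-5)
        assert np.allclose(packaged.scp_table, analytic.scp_table, atol=1e-5)


def test_model_yaml_roundtrip(tmp_path, model18):
    model18.to_yaml(tmp_path / "m.yaml")
    back = BeamModel.from_yaml(tmp_path / "m.yaml")
    assert np.allclose(back.tmr_table, model18.tmr_table, atol=1e-5)
    assert back.penumbra_sigma_mm == model18.penumbra_sigma_mm
    assert back.mlc_transmission == model18.mlc_transmission


def test_depth_beyond_table_extended_with_mu_eff(model18):
    d = 450.0
    expected = float(model18.tmr(400.0, 100.0)[0]) * np.exp(-model18.mu_eff_per_mm * 50.0)
    assert float(model18.tmr(d, 100.0)[0]) == pytest.approx(expected, rel=1e-6)


# -- radiological depth -----------------------------------------------------


def test_radiological_depth_uniform_water():
    vol = _water_slab()
    src = np.array([0.0, -1000.0, 0.0])
    # density is sampled at voxel centers, so the water column starts at the
    # first center (y = 0); 80 mm of geometric path in water from there
    tgt = np.array([0.0, 80.0, 0.0])
    d = radiological_depth(vol, src, tgt)
    assert d == pytest.approx(80.0, abs=1.0)


def test_radiological_depth_lung_linearity():
    vol = _water_slab()
    # lung-like anterior half: first 40 mm of tissue at density 0.25
    vol.values[:, :10, :] = -750.0
    src = np.array([0.0, -1000.0, 0.0])
    tgt = np.array([0.0, 78.0, 0.0])
    d = radiological_depth(vol, src, tgt)
    assert d == pytest.approx(40.0 * 0.25 + 40.0, abs=1.0)


def test_radiological_depth_missing_body_is_zero():
    vol = _water_slab(hu=-1000.0)
    d = radiological_depth(vol, np.array([0, -500, 0.0]), np.array([0.0, 50.0, 0.0]))
    assert d == pytest.approx(0.0, abs=1e-6)


def test_radiological_depth_oblique_matches_fine_ray_march():
    """Oblique ray vs an independent 0.1 mm ray-march oracle, within 1 mm."""
    vol = _water_slab()
    vol.values[:, 5:10, 20:40] = -750.0  # lung block in the path
    src = np.array([130.0, -400.0, 60.0])
    tgt = np.array([-30.0, 90.0, -40.0])
    d = radiological_depth(vol, src, tgt)
    # oracle: straightforward fixed-step summation, 0.1 mm
    from gridfire.core import hu_to_density
    from gridfire.dose import _to_index_coords
    from scipy import ndimage
    length = np.linalg.norm(tgt - src)
    n = int(length / 0.1)
    s = (np.arange(n) + 0.5) / n
    pts = src + s[:, None] * (tgt - src)
    rho = ndimage.map_coordinates(hu_to_density(vol.values),
                                  _to_index_coords(pts, vol.grid).T,
                                  order=1, mode="constant", cval=0.0)
    oracle = rho.sum() * length / n
    assert d == pytest.approx(oracle, abs=1.0)


# -- single-beam dose -------------------------------------------------------


def test_closed_aperture_zero_dose(model18):
    vol = _water_slab()
    ap = fit_mlc(BEVImage(np.zeros((5, 5), bool), np.arange(5.0), np.arange(5.0)))
    beam = BeamSpec(gantry_deg=0.0, energy_label="18MV", isocenter_mm=(0.0, 100.0, 0.0))
    d = beam_dose(vol, beam, ap, model18, mu=100.0)
    assert d.values.max() == 0.0


def test_open_field_calibration_identity(model6):
    """10x10 open field, SAD setup with iso at dmax depth: 100 MU ~ 1 Gy."""
    vol = _water_slab(spacing=2.0, n=(100, 80, 80))
    iso_y = -2.0 + model6.dmax_mm  # dmax below the anterior surface
    beam = BeamSpec(gantry_deg=0.0, energy_label="6MV", isocenter_mm=(0.0, iso_y, 0.0))
    ap = _open_square_aperture(100.0)
    d = beam_dose(vol, beam, ap, model6, mu=100.0)
    iso_dose = d.values[d.grid.z_to_slice(0.0), int(round((iso_y - d.origin_mm[1]) / 2.0)),
                        d.values.shape[2] // 2]
    _, side = gf.aperture_open_area(ap)
    expected = 1.0 * model6.scp(side)  # 100 MU * 1 cGy/MU * Scp * TMR(dmax)=1
    assert iso_dose == pytest.approx(expected, rel=0.02)


def test_central_axis_matches_tmr_table(model18):
    """Relative CAX depth dose of an open field tracks the TMR table <= 0.5%."""
    vol = _water_slab(spacing=2.0, n=(100, 120, 80))
    iso_y = -2.0 + 150.0
    beam = BeamSpec(gantry_deg=0.0, energy_label="18MV", isocenter_mm=(0.0, iso_y, 0.0))
    ap = _open_square_aperture(100.0)
    d = beam_dose(vol, beam, ap, model18, mu=100.0)
    grid = d.grid
    k0 = grid.z_to_slice(0.0)
    i0 = d.values.shape[2] // 2
    _, side = gf.aperture_open_area(ap)
    y = grid.axis_coords()[1]
    depths = y + 2.0  # depth below surface
    sel = (depths >= model18.dmax_mm) & (depths <= 220.0)
    cax = d.values[k0, sel, i0]
    sad_dist = 1000.0 - iso_y + y[sel]
    expected = (model18.tmr(depths[sel], side) * (1000.0 / sad_dist) ** 2)
    ratio = cax / cax[0] / (expected / expected[0])
    assert np.abs(ratio - 1.0).max() < 0.005


def test_inverse_square_beyond_buildup_slab(model18):
    """At equal radiological depth, the CAX dose ratio is pure inverse-square.

    A thin water slab sits upstream and the points lie in air behind it, so
    both share the same water-equivalent depth and the TMR factor cancels.
    """
    vol = _water_slab(spacing=2.0, n=(100, 120, 80), hu=-1000.0)
    vol.values[:, :20, :] = 0.0  # 40 mm water entrance slab
    iso_y = 100.0
    beam = BeamSpec(gantry_deg=0.0, energy_label="18MV", isocenter_mm=(0.0, iso_y, 0.0))
    ap = _open_square_aperture(100.0)
    d = beam_dose(vol, beam, ap, model18,
                  mu=100.0, compute_mask=np.ones(vol.values.shape, bool))
    grid = d.grid
    k0, i0 = grid.z_to_slice(0.0), d.values.shape[2] // 2
    y = grid.axis_coords()[1]
    j1, j2 = 40, 100  # both beyond the slab, in air
    measured = d.values[k0, j1, i0] / d.values[k0, j2, i0]
    t1 = 1000.0 - iso_y + y[j1]
    t2 = 1000.0 - iso_y + y[j2]
    assert measured == pytest.approx((t2 / t1) ** 2, rel=0.005)


def test_dose_linear_in_mu(model18):
    vol = _water_slab()
    beam = BeamSpec(gantry_deg=90.0, energy_label="18MV", isocenter_mm=(0.0, 100.0, 0.0))
    ap = _open_square_aperture(60.0)
    d1 = beam_dose(vol, beam, ap, model18, mu=50.0, depth_steps=40)
    d2 = beam_dose(vol, beam, ap, model18, mu=150.0, depth_steps=40)
    assert np.allclose(d2.values, 3.0 * d1.values, rtol=1e-12, atol=1e-12)


# -- composite plans --------------------------------------------------------


def test_plan_normalization_and_superposition(small_case, model6):
    """max110 sets the global max exactly; composite = weighted beam sum."""
    _, vol, ss = small_case
    grid = vol.grid
    lat = gf.build_lattice(ss.mask("GTV"), grid, gf.LatticeSpec())
    beams = gf.make_crossfire_beams((0.0, -50.0, 0.0), "6MV", n=3, spacing_deg=120)
    aps = [fit_mlc(gf.project_bev(lat.mask, grid, b)) for b in beams]
    plan = plan_dose(vol, beams, aps, {"6MV": model6}, 15.0, depth_steps=40)
    assert plan.dose.values.max() == pytest.approx(16.5, rel=1e-9)
    # superposition oracle: recompute each beam at the final MU and sum
    total = np.zeros(grid.shape)
    for b, ap, mu in zip(beams, aps, plan.mu):
        total += beam_dose(vol, b, ap, model6, mu, depth_steps=40).values
    assert np.allclose(total, plan.dose.values, rtol=1e-9, atol=1e-9)


def test_plan_weight_scale_invariance(small_case, model6):
    _, vol, ss = small_case
    grid = vol.grid
    lat = gf.build_lattice(ss.mask("GTV"), grid, gf.LatticeSpec())
    import dataclasses
    beams1 = gf.make_crossfire_beams((0.0, -50.0, 0.0), "6MV", n=2, spacing_deg=180)
    beams2 = [dataclasses.replace(b, weight=2.0) for b in beams1]
    aps = [fit_mlc(gf.project_bev(lat.mask, grid, b)) for b in beams1]
    p1 = plan_dose(vol, beams1, aps, {"6MV": model6}, 15.0, depth_steps=30)
    p2 = plan_dose(vol, beams2, aps, {"6MV": model6}, 15.0, depth_steps=30)
    assert np.allclose(p1.dose.values, p2.dose.values, rtol=1e-12, atol=1e-12)


def test_plan_requires_beams(small_case, model6):
    _, vol, _ = small_case
    with pytest.raises(ValueError):
        plan_dose(vol, [], [], {"6MV": model6}, 15.0)


def test_opposed_pair_symmetry(model18):
    """Opposed open beams in a centered slab are symmetric about the iso plane."""
    vol = _water_slab(spacing=2.0, n=(100, 100, 80))
    iso = (0.0, 99.0, 0.0)  # slab center (y spans -1..199)
    ap = _open_square_aperture(80.0)
    b1 = BeamSpec(gantry_deg=0.0, energy_label="18MV", isocenter_mm=iso)
    b2 = BeamSpec(gantry_deg=180.0, energy_label="18MV", isocenter_mm=iso)
    d = (beam_dose(vol, b1, ap, model18, 100.0, depth_steps=80).values
         + beam_dose(vol, b2, ap, model18, 100.0, depth_steps=80).values)
    k0, i0 = vol.grid.z_to_slice(0.0), vol.values.shape[2] // 2
    cax = d[k0, :, i0]
    sel = cax > 0.3 * cax.max()  # interior, away from buildup edges
    prof = cax[sel]
    assert np.abs(prof - prof[::-1]).max() / prof.max() < 0.01


# -- beam-on time -----------------------------------------------------------


def test_beam_on_time_arithmetic():
    assert beam_on_time(2240.0, 400.0) == pytest.approx(5.6)
    assert beam_on_time(0.0, 400.0) == 0.0
    with pytest.raises(ValueError):
        beam_on_time(-1.0, 400.0)
    with pytest.raises(ValueError):
        beam_on_time(100.0, 0.0)


def test_beam_on_time_dose_rate_rescale():
    """A 5.6 min treatment at 400 MU/min takes 3.73 min at 600 MU/min."""
    mu = 5.6 * 400.0
    assert beam_on_time(mu, 600.0) == pytest.approx(3.7333, abs=1e-3)
    assert round(beam_on_time(mu, 600.0), 1) == 3.7
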