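"""Shared fixtures: phantoms and plans are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import gridfire as gf
from gridfire.core import Grid
from gridfire.pipeline import PlanSetup, build_plan


@pytest.fixture(scope="session")
def small_case():
    """Fast 5 mm phantom with a 6 cm GTV at 6 cm depth (6 MV territory)."""
    spec = gf.PhantomSpec(gtv_diameter_mm=60.0, gtv_center_depth_mm=60.0,
                          voxel_spacing_mm=(5.0, 5.0, 5.0), oar_kind="cord-cylinder")
    vol, ss = gf.make_phantom(spec)
    return spec, vol, ss


@pytest.fixture(scope="session")
def small_outcome(small_case):
    _, vol, ss = small_case
    return build_plan(vol, ss, PlanSetup(depth_steps=80))


@pytest.fixture(scope="session")
def benchmark_case():
    """The benchmark deep-seated case: 10 cm GTV at 9 cm depth, 2.5 mm grid."""
    spec = gf.benchmark_spec(voxel_mm=2.5)
    vol, ss = gf.make_phantom(spec)
    return spec, vol, ss


@pytest.fixture(scope="session")
def benchmark_outcome(benchmark_case):
    """Full six-field 18 MV crossfire plan on the benchmark phantom."""
    _, vol, ss = benchmark_case
    return build_plan(vol, ss, PlanSetup(energy="18MV"))


@pytest.fixture(scope="session")
def sphere_1mm():
    """10 cm sphere rasterized at 1 mm voxels (lattice parameter recovery)."""
    n = 112
    grid = Grid((n, n, n), (1.0, 1.0, 1.0),
                (-(n - 1) / 2.0, -(n - 1) / 2.0, -(n - 1) / 2.0))
    x, y, z = grid.axis_coords()
    mask = (x[None, None, :] ** 2 + y[None, :, None] ** 2
            + z[:, None, None] ** 2) <= 50.0**2
    return mask, grid


@pytest.fixture(scope="session")
def lattice_1mm(sphere_1mm):
    mask, grid = sphere_1mm
    return gf.build_lattice(mask, grid, gf.LatticeSpec()), grid
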