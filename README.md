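# gridfire

Planning toolkit for **MLC-based 3D-crossfire GRID therapy** — spatially
fractionated radiotherapy (SFRT) of bulky, deep-seated tumors, delivered as a
single high-dose fraction through a lattice of small open "tunnels" instead
of a physical Cerrobend GRID block.

It is written for medical physicists and method developers who want a
self-contained, testable implementation of the technique: synthetic patient
phantoms, DICOM CT/RTSTRUCT I/O, lattice-pattern generation inside the GTV,
static MLC aperture fitting for a six-field crossfire arrangement, a
simplified TMR-based forward dose engine, plan-quality metrics with
single-fraction organ-at-risk limits, an independent monitor-unit second
check, and prescription-escalation simulation.

## The technique

A hexagonal lattice of cylinders (hole diameter *d* = 10 mm, center-to-center
pitch *p* = 20 mm, axes parallel to the patient's superior-inferior axis) is
generated inside the GTV and exported as a structure. Six coplanar beams at
gantry 210°, 270°, 330°, 30°, 90°, 150° (each angle paired with its 180°
complement) view the lattice with a 90° collimator rotation, so 5 mm MLC
leaves travel along the patient axis and each lattice cylinder projects to a
single leaf-pair interval — a static, forward-planned 3D-conformal aperture
with no modulation. The crossfire of stripe-shaped fields reinforces dose in
the tunnels and spreads the entrance dose over six skin areas.

Dose per beam is computed as

```
D(x) = MU · output · Sc,p(s) · TMR(d_rad(x), s) · F(u, v) · (SAD / t(x))²
```

with `s` the equivalent-square side of the open aperture, `d_rad` the
ray-traced water-equivalent depth, `F` the aperture fluence blurred with a
dual-Gaussian (penumbra + phantom-scatter) kernel plus MLC transmission, and
`t` the source distance. Plans are normalized so the maximum point equals
110% of the prescription (`max110`). Plan quality is summarized by the mean
GTV dose, the peak-to-valley dose ratio PVDR = D_max/D_min inside the GTV,
skin Dmax/D5cc/D10cc, D2cm (maximum dose ≥ 2 cm from the target, % of
prescription), and single-fraction RTOG-style OAR limits.

## Worked example

```python
import gridfire as gf
from gridfire.pipeline import PlanSetup, build_plan

volume, structures = gf.make_phantom(gf.benchmark_spec())   # 10 cm GTV, 9 cm deep
outcome = build_plan(volume, structures, PlanSetup(energy="18MV"))
m = outcome.metrics
print(m.mean_gtv_dose_gy, m.pvdr, m.skin_dmax_gy)
```

Full-resolution output of `examples/03_plan_and_metrics.py` (2.5 mm dose
grid, a couple of minutes on one CPU):

```
energy: 18MV, beams at [210.0, 270.0, 330.0, 30.0, 90.0, 150.0] deg, collimator 90 deg
mean GTV dose: 12.73 Gy  (prescription 15 Gy, max 16.5 Gy)
PVDR (max/min in GTV): 2.37  — the peak-to-valley contrast that drives the GRID-therapy effect
skin Dmax / D5cc: 4.32 / 3.90 Gy
D2cm: 68.5% of prescription
total 3024 MU -> 7.6 min beam-on at 400 MU/min
MU second check per field (%): [1.18, 1.96, 1.31, 1.32, 1.96, 1.18]
```

The mean GTV dose shows the target coverage achievable despite the 9 cm
depth; the PVDR quantifies the spatial fractionation; the low skin doses are
what allows escalating the prescription toward 23 Gy (see
`examples/04_escalation.py`, which finds 23 Gy feasible against the 26 Gy
single-fraction skin limit).

The other examples cover phantom construction (`01`), lattice generation and
parameter-recovery QC (`02`), and GRID-block MU hand calculations (`05`).
A thin CLI wraps the same pipeline:

```bash
gridfire phantom --out ph --diameter 100 --depth 90
gridfire plan --ct ph/ct --structures ph/rtstruct.dcm --out plan
gridfire escalate --metrics plan/metrics.json
```

## Limitations

The dose engine is a documented simplification (TMR × fluence ×
inverse-square with an equivalent-path-length heterogeneity correction), not
a transport calculation; see `docs/methods.md` for the model, its
assumptions, and what the tests do and do not demonstrate.
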