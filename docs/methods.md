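# Methods

This note records the models and design choices behind `gridfire`, in the
spirit of an engine documentation page: what is computed, under which
assumptions, which parameters matter, and where the simplifications end.

## Coordinates and geometry

Patient coordinates are DICOM LPS (x left, y posterior, z superior), all in
millimetres. Machine angles are IEC 61217 for a head-first supine patient;
gantry 0° places the source anterior, angles increase clockwise seen from the
couch. With the collimator at 90° the MLC leaf-travel axis is parallel to the
patient's longitudinal axis for every coplanar beam. Beam's-eye-view (BEV)
coordinates are (u, v) at the isocenter plane — u along the leaf stack
(axial-plane transverse), v along leaf travel (longitudinal) — with
point-source magnification SAD/t, SAD = 1000 mm. Masks use
voxel-center-inside semantics; contours are closed planar polygons per axial
slice, traced at pixel-boundary resolution so mask → contours → mask is the
identity.

## Phantoms

The synthetic patient is an elliptical water-equivalent cylinder (default
semi-axes 160 × 110 mm, length 240 mm) in air, with a spherical GTV at a
prescribed depth below the anterior skin, a skin shell defined as the body
minus its 5 mm Euclidean erosion, and optionally a cord-like cylindrical OAR
posterior to the target. Cohort sampling draws tumor diameters uniformly from
60–150 mm and skin-to-center depths from 43–104 mm, the clinically reported
ranges for bulky deep-seated disease. The benchmark case used throughout the
tests is a 10 cm GTV centered 9 cm below the skin on a 2.5 mm isotropic grid
— a deep case; its lateral beams traverse ~16 cm of water.

What the phantom does **not** emulate: anatomical heterogeneity (a single
lung-density sphere is available for path-length tests), HU texture and
noise structure, irregular target shapes, and motion. Tests passing on these
phantoms therefore validate geometry, bookkeeping and the engine's stated
invariants — not clinical dosimetric accuracy on real anatomy.

## Lattice

Cell centers lie on a 2D lattice in the axial plane (hexagonal by default,
square optional; hole diameter 10 mm, pitch 20 mm), anchored at the GTV
centroid. Cells are cylinders parallel to the longitudinal axis, spanning and
clipped to the GTV; spheres are available for lattice-therapy-style
experiments. A cell is kept when ≥ 50% of its cross-section lies inside the
GTV cross-section on the centroid slice (ties kept).

Two open choices were fixed deliberately:

* **Cylinders, not spheres, by default.** With six coplanar beams at
  collimator 90°, a longitudinal cylinder projects to exactly one
  single-interval MLC opening at every gantry angle, so a static unmodulated
  aperture can realize the pattern and the crossfire reinforces dose in the
  cylinder "tunnels".
* **Lattice orientation.** One hexagonal primitive vector is aligned with
  the patient left-right axis. The six crossfire beam axes (30°/90°/150°
  modulo 180°) then all view the lattice along row-normal directions, so
  every BEV is a stripe pattern with period p·√3/2 ≈ 17.3 mm and ~10 mm open
  stripes — cleanly fittable with 5 mm leaves. Other orientations can
  collapse the projections into nearly contiguous openings and lose the
  spatial fractionation.

The QC report measures realized hole diameter (equivalent-circle diameter of
each cell's mid-slice cross-section) and pitch (nearest-neighbor center
distance); at 1 mm voxels both recover the design values within one voxel.

## MLC aperture fitting

Leaves are 5 mm wide at iso, 60 pairs (Millennium-120-like central bank).
For each beam the lattice mask is projected voxel-by-voxel (supersampled)
through the point source onto the isocenter plane at 0.5 mm resolution. A
leaf pair participates when the mask area in its strip is at least half of
the strip area spanned by the mask's travel-axis extent there; participating
pairs open over the covering interval of the mask in their strip — the
single-interval constraint a static MLC physically imposes — and the jaws
close on the open aperture's bounding box. With longitudinal cylinders the
covering interval is lossless. Tip margin defaults to 0: the lattice itself
defines the beamlet size.

## Dose engine

Per beam, on the CT grid (2.5 mm default), inside the patient only:

D(x) = MU · output · Sc,p(s) · TMR(d_rad(x), s) · F(u, v) · (SAD/t)²

* **Tables.** TMR(d, s), %DD(d, s) and Sc,p(s) are generated from a
  closed-form model — buildup B(d) = 1 − exp(−kd) with k = 4.6/dmax,
  exponential falloff exp(−μ(s)(d − dmax)) with μ(s) = μ_ref(1 − 0.10
  ln(s/100)), Sc,p = 1 + 0.045 log₂(s/100) — and shipped as YAML data files;
  the engine only interpolates the tables (bilinear; depths beyond the table
  decay with μ_eff and log a warning). Defaults: 6 MV dmax 15 mm,
  μ_ref 0.0049/mm; 18 MV dmax 33 mm, μ_ref 0.0035/mm; output 1 cGy/MU at
  dmax, 10 × 10 cm, SAD 100 cm. These reproduce textbook-typical MV
  depth-dose behavior (e.g. 18 MV TMR ≈ 0.79 at 10 cm) but are implementer
  defaults, not commissioning data.
* **Fluence kernel.** The binary aperture is convolved with a dual-Gaussian
  lateral kernel: a narrow penumbra component (σ 3.5/4.5 mm for 6/18 MV) plus
  a broad phantom-scatter component (weight 0.20/0.25, range 25/30 mm),
  values in the range of published dual-Gaussian pencil-beam-kernel fits.
  The broad component is what carries dose into the valleys of spatially
  fractionated fields, where phantom scatter dominates. Closed-leaf MLC
  transmission (1.7%) is added inside the penumbra-softened jaw rectangle.
  For a diverging beam the geometric penumbra, expressed in isocenter-plane
  coordinates, is magnification-independent, so the convolution is done once
  per beam.
* **Heterogeneity.** Water-equivalent (equivalent-path-length) depth: the
  line integral of HU-derived relative electron density from the volume
  boundary to the voxel along the ray from the source (midpoint rule, 160
  steps by default; the point-to-point utility uses a 0.25 mm march). The HU
  ramp is 1 + HU/1000 below water, 1 + HU/1950 above, clipped at 0.
* **Field size.** The equivalent square of the total open aperture area per
  beam feeds the Sc,p/TMR lookups. This underestimates the scatter deficit
  of a grid-shaped aperture relative to a solid field of the same area; a
  config-adjustable grid output factor (default 1.0) is exposed.
* **Normalization.** Per-beam MU ∝ beam weight (optionally × 1/TMR(depth to
  iso), the "equalize-iso" mode, since clinically the six fields are
  differentially weighted); a single global scale then sets the maximum
  point to 110% ("max110", default) or 100% of the prescription. Dose is
  exactly linear in MU and in the prescription.

This is **not** a transport calculation: no electron transport, no
depth-dependence of the lateral kernel, no tongue-and-groove or rounded
leaf ends, no couch attenuation. Accuracy claims are limited to the tested
invariants: calibration identity, CAX agreement with the TMR tables
(≤ 0.5%), inverse-square behavior, MU linearity and superposition,
opposed-beam symmetry, and whole-chain pitch recovery from the composite
dose. On the benchmark phantom the composite plan measures PVDR ≈ 2.4 and a
mean GTV dose ≈ 12.7 Gy at 15 Gy prescribed to 110% — a slightly colder
valley floor than clinical transport algorithms report on real patients,
which is the expected direction of the engine's main simplification (the
fixed-width scatter kernel); see the limitations below.

## Plan evaluation

* **PVDR** = max/min dose inside the full GTV mask (point values; optional
  1-voxel erosion, off by default, to suppress boundary artifacts). A zero
  minimum reports infinity with a logged flag.
* **DVH**: cumulative, volumes as voxel count × voxel volume; DxCC is the
  minimum dose of the hottest x cm³ from the sorted voxel doses.
* **D2cm**: maximum dose over body voxels at ≥ 20 mm Euclidean distance from
  the GTV, in % of prescription (the SBRT spillage convention; distances via
  an exact Euclidean distance transform).
* **Limits**: single-fraction OAR tolerances (cord < 14, heart < 22,
  esophagus < 15.4, ribs < 30 / 22 at 1 cc, skin < 26 / 23 at 10 cc,
  stomach-bowel < 12.4 / 11.2 at 10 cc Gy) with strict `<` semantics —
  a value at the limit fails; missing structures are reported not-evaluated
  rather than failed.
* **MU second check**: MU = D_iso·100 / [output · Sc,p(s) · TMR(d_iso, s) ·
  A], with d_iso ray-traced independently of the engine's volumetric depth
  and A the aperture factor at the isocenter computed by closed-form erf
  integration of the kernel over the open leaf rectangles (plus
  transmission) — the analytic counterpart of the engine's grid convolution.
  For a broad open field A = 1 and the classical formula is recovered. A
  grid-field second check without the aperture factor is meaningless here:
  the isocenter sits under a ~10 mm stripe whose peak fluence is ~0.7.
* **Escalation**: the engine's linearity makes escalation a pure rescale;
  the table reports skin metrics and limit compliance per prescription and
  the largest feasible prescription on the grid.
* Cohort summaries use sample (n−1) standard deviations.

## Problem sizes and numerical choices

Defaults: 2.5 mm dose grid (≈ 1.4 M voxels for the benchmark body), BEV
sampling 0.5 mm, 160 depth-integration steps, 0.25 mm ray march for the
point depth utility. The benchmark six-field plan computes in a couple of
minutes on one CPU; tests and the acceptance script run everything at these
sizes. Ties: cells exactly at the keep-fraction threshold are kept; leaf
pairs exactly at the overlap threshold open; limits use strict `<`.
Degenerate inputs (empty GTV, empty lattice, zero-dose plans, missing
structures) raise descriptive errors or flagged reports as documented in
the API.

## Known limitations

* The valley dose of spatially fractionated fields is governed by phantom
  scatter whose lateral spread grows with depth; the fixed-width scatter
  Gaussian underestimates it for deep targets, so PVDR runs slightly high
  and mean target dose slightly low compared to transport calculations.
* Sc,p/TMR lookups use the open-area equivalent square, which is only an
  approximation for grid apertures.
* RTSTRUCT I/O writes the minimal attribute set needed for interchange of
  geometry, not a complete clinical object; RT Plan / RT Dose DICOM export
  is out of scope (plans and dose grids use the package's own documented
  YAML/npz formats).
* Axial-slice contouring only; non-coplanar beams and couch rotations are
  not supported.
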