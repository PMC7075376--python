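"""DICOM CT / RTSTRUCT input-output and contour <-> voxel-mask conversion.

Contours are stored per axial slice as closed polygons in patient millimetres
(DICOM convention).  Masks use voxel-center-inside semantics with even-odd
filling for nested contours, which is how treatment planning systems
rasterize RTSTRUCT data.  Boundary tracing emits polygons at voxel-edge
(pixel-boundary) resolution — an exact trace of the mask's cracks, not a
smoothed curve — so a mask -> contours -> mask cycle is the identity.
"""

from __future__ import annotations

import datetime
from pathlib import Path as FsPath

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, RTStructureSetStorage, generate_uid
from shapely.geometry import Polygon as ShapelyPolygon

from .core import Grid, ImageVolume, Structure, StructureSet

__all__ = [
    "FormatError",
    "mask_to_contours",
    "contours_to_mask",
    "read_ct_series",
    "write_ct_series",
    "read_structures",
    "write_structures",
]


class FormatError(ValueError):
    """Malformed or inconsistent DICOM input."""


# ---------------------------------------------------------------------------
# mask <-> contours
# ---------------------------------------------------------------------------

# Crack-edge directions: each boundary edge of a filled pixel is directed so
# the filled region lies on its LEFT; outer loops then come out
# counter-clockwise and holes clockwise in the (x, y) plane.


def _trace_slice(mask2d: np.ndarray) -> list[np.ndarray]:
    """Trace closed pixel-boundary polygons of a 2D mask.

    Returns vertex arrays in (x_index, y_index) coordinates where integer
    values are pixel centers (pixel (j, i) spans +-0.5 around (i, j)).
    Diagonally touching pixels are kept in separate loops (4-connectivity).
    """
    m = np.asarray(mask2d, dtype=bool)
    if not m.any():
        return []
    ny, nx = m.shape
    pad = np.zeros((ny + 2, nx + 2), dtype=bool)
    pad[1:-1, 1:-1] = m

    # Doubled-integer corner keys: corner (i +- 0.5, j +- 0.5) -> (2i +- 1, 2j +- 1).
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(j: np.ndarray, i: np.ndarray, start_off, end_off) -> None:
        for jj, ii in zip(j, i):
            s = (2 * ii + start_off[0], 2 * jj + start_off[1])
            e = (2 * ii + end_off[0], 2 * jj + end_off[1])
            edges.setdefault(s, []).append(e)

    core = pad[1:-1, 1:-1]
    j, i = np.nonzero(core & ~pad[2:, 1:-1])   # empty above (+y): top edge, -x
    add(j, i, (1, 1), (-1, 1))
    j, i = np.nonzero(core & ~pad[:-2, 1:-1])  # empty below: bottom edge, +x
    add(j, i, (-1, -1), (1, -1))
    j, i = np.nonzero(core & ~pad[1:-1, 2:])   # empty right: right edge, +y
    add(j, i, (1, -1), (1, 1))
    j, i = np.nonzero(core & ~pad[1:-1, :-2])  # empty left: left edge, -y
    add(j, i, (-1, 1), (-1, -1))

    loops: list[np.ndarray] = []
    while edges:
        start = min(edges)  # deterministic loop ordering
        loop = [start]
        prev_dir = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs.pop(0)
            else:
                # Ambiguous corner (diagonal touch): take the left-most turn so
                # that 4-connected regions stay in separate loops.
                def cross(e):
                    d = (e[0] - cur[0], e[1] - cur[1])
                    return prev_dir[0] * d[1] - prev_dir[1] * d[0]

                nxt = max(outs, key=cross)
                outs.remove(nxt)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            if nxt == start:
                break
            loop.append(nxt)
            cur = nxt
        v = np.asarray(loop, dtype=float) / 2.0
        loops.append(_drop_collinear(v))
    return loops


def _drop_collinear(v: np.ndarray) -> np.ndarray:
    """Merge runs of collinear crack edges into single segments."""
    n = len(v)
    keep = np.ones(n, dtype=bool)
    for a in range(n):
        p, q, r = v[a - 1], v[a], v[(a + 1) % n]
        cross = (q[0] - p[0]) * (r[1] - q[1]) - (q[1] - p[1]) * (r[0] - q[0])
        if np.isclose(cross, 0.0):
            keep[a] = False
    return v[keep]


def mask_to_contours(mask: np.ndarray, grid: Grid) -> list[tuple[float, np.ndarray]]:
    """Per-slice boundary polygons of a voxel mask, in patient mm.

    One closed polygon per connected boundary per slice; outer boundaries are
    counter-clockwise in the axial (x, y) plane, holes clockwise.  An empty
    mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    dx, dy, _ = grid.spacing_mm
    x0, y0, _ = grid.origin_mm
    out: list[tuple[float, np.ndarray]] = []
    for k in range(mask.shape[0]):
        if not mask[k].any():
            continue
        z = grid.slice_z(k)
        for v in _trace_slice(mask[k]):
            mm = np.column_stack([x0 + v[:, 0] * dx, y0 + v[:, 1] * dy])
            out.append((z, mm))
    return out


def contours_to_mask(
    contours: list[tuple[float, np.ndarray]],
    grid: Grid,
    validate: bool = True,
) -> np.ndarray:
    """Rasterize closed planar polygons to a voxel mask (even-odd rule).

    A voxel belongs to the mask when its center lies inside an odd number of
    the slice's polygons, so nested contours carve holes.  Self-intersecting
    polygons are rejected (by index in the input list).
    """
    mask = np.zeros(grid.shape, dtype=bool)
    x, y, _ = grid.axis_coords()
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    for idx, (z, verts) in enumerate(contours):
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError(f"contour {idx}: need an (N>=3, 2) vertex array")
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if validate and not ShapelyPolygon(verts).is_valid:
            raise ValueError(f"contour {idx} on z={z} mm is self-intersecting")
        k = grid.z_to_slice(z)
        inside = MplPath(verts).contains_points(pts).reshape(grid.shape[1:])
        mask[k] ^= inside
    return mask


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------


def _file_meta(sop_class, sop_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(volume: ImageVolume, path: str | FsPath) -> list[FsPath]:
    """Write one CT DICOM file per slice; returns the file paths."""
    path = FsPath(path)
    path.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = volume.values.shape
    dx, dy, dz = volume.spacing_mm
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    now = datetime.datetime.now()
    files = []
    intercept = -1024.0
    pixels = np.clip(np.rint(volume.values - intercept), 0, 4095).astype(np.uint16)
    for k in range(nz):
        sop_uid = generate_uid()
        ds = FileDataset(None, {}, file_meta=_file_meta(CTImageStorage, sop_uid), preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "GRIDFIRE^PHANTOM"
        ds.PatientID = "GRIDFIRE"
        ds.PatientPosition = volume.patient_position_label
        ds.StudyDate = ds.SeriesDate = now.strftime("%Y%m%d")
        ds.StudyTime = ds.SeriesTime = now.strftime("%H%M%S")
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [float(volume.origin_mm[0]), float(volume.origin_mm[1]),
                                   float(volume.origin_mm[2] + k * dz)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(dy), float(dx)]  # row spacing, column spacing
        ds.SliceThickness = float(dz)
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = 1.0
        ds.PixelData = pixels[k].tobytes()
        f = path / f"CT.{k + 1:04d}.dcm"
        ds.save_as(f, enforce_file_format=True)
        files.append(f)
    return files


def read_ct_series(path: str | FsPath) -> ImageVolume:
    """Read a single CT series from a directory; slices sorted by z position."""
    path = FsPath(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise FormatError(f"no CT slices found under {path}")
    series = {s.SeriesInstanceUID for s in slices}
    if len(series) > 1:
        raise FormatError(f"directory holds {len(series)} CT series; expected one")
    for tag in ("ImagePositionPatient", "PixelSpacing"):
        if any(not hasattr(s, tag) for s in slices):
            raise FormatError(f"CT slice missing required geometry tag {tag}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    spac = {(float(s.PixelSpacing[0]), float(s.PixelSpacing[1])) for s in slices}
    if len(spac) > 1:
        raise FormatError(f"inconsistent in-plane pixel spacing across slices: {spac}")
    dy, dx = spac.pop()
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dzs = np.diff(zs)
        if np.ptp(dzs) > 0.01:
            raise FormatError("inconsistent slice spacing")
        dz = float(dzs.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    arrs = []
    for s in slices:
        a = s.pixel_array.astype(float)
        a = a * float(getattr(s, "RescaleSlope", 1.0)) + float(getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a)
    values = np.stack(arrs, axis=0)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return ImageVolume(
        values=values,
        spacing_mm=(dx, dy, dz),
        origin_mm=origin,
        patient_position_label=str(getattr(slices[0], "PatientPosition", "HFS")),
    )


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT
# ---------------------------------------------------------------------------


def write_structures(sset: StructureSet, reference: ImageVolume, path: str | FsPath) -> FsPath:
    """Write a StructureSet as a DICOM RTSTRUCT file."""
    path = FsPath(path)
    sop_uid = generate_uid()
    ds = FileDataset(None, {}, file_meta=_file_meta(RTStructureSetStorage, sop_uid),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = RTStructureSetStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "GRIDFIRE^PHANTOM"
    ds.PatientID = "GRIDFIRE"
    ds.StructureSetLabel = "gridfire"
    now = datetime.datetime.now()
    ds.StructureSetDate = now.strftime("%Y%m%d")
    ds.StructureSetTime = now.strftime("%H%M%S")
    frame_uid = generate_uid()

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    roi_seq, contour_seq, obs_seq = [], [], []
    for num, s in enumerate(sset, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ROIDisplayColor = list(s.color)
        cs = []
        for z, verts in s.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(verts)
            data = np.column_stack([verts, np.full(len(verts), z)]).ravel()
            c.ContourData = [f"{v:.3f}" for v in data]
            cs.append(c)
        rc.ContourSequence = cs
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.ROIObservationLabel = s.name
        obs.RTROIInterpretedType = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(path, enforce_file_format=True)
    return path


def read_structures(path: str | FsPath, reference: ImageVolume) -> StructureSet:
    """Read an RTSTRUCT; contours referencing slices outside the volume are rejected."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(f"{path} is not an RTSTRUCT file")
    grid = reference.grid
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out = StructureSet(reference_grid=grid)
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names[int(rc.ReferencedROINumber)]
        color = tuple(int(c) for c in getattr(rc, "ROIDisplayColor", [255, 0, 0]))
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(data[0, 2])
            try:
                grid.z_to_slice(z)
            except ValueError as err:
                raise FormatError(f"structure {name!r}: contour at z={z} mm "
                                  f"outside reference volume") from err
            contours.append((z, data[:, :2]))
        out.add(Structure(name=name, contours=contours, color=color))
    return out
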