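"""Readers and writers for plan delivery records and scalar volumes.

Plans travel in a small JSON dialect (schema in ``schemas/plan.schema.json``)
carrying exactly what the delivery log contributes to the analysis:
gantry angle, segment MU and the leaf-tip positions of both MLC stacks,
in cm at isocenter.  An equivalent long-format CSV (one row per
segment-leaf-pair) is also supported.  Volumes are read from DICOM RT
Dose files, DICOM CT series directories (returned in HU), or a
self-describing internal grid format (text header + little-endian raw
block) convenient for desk-scale fixtures.

All volume readers convert into the package's machine axes: x crossline,
y inline (superior-inferior, the magnetic-field axis), z beam axis at
gantry 0.  For identity-oriented axial DICOM data this maps patient
(L, P, S) to machine (x, z, y).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    GeometryMismatchError,
    Grid3D,
    MLCGeometry,
    Plan,
    Segment,
    ValidationError,
)

__all__ = ["read_plan", "write_plan", "read_grid", "write_grid", "SchemaError"]

PathLike = Union[str, os.PathLike]


class SchemaError(ValidationError):
    """A plan document is missing a field or has the wrong structure."""


# --------------------------------------------------------------------------
# plan JSON / CSV dialect
# --------------------------------------------------------------------------

_GEOMETRY_FIELDS = ("top_pairs", "bottom_pairs", "leaf_width_iso", "stack_offset", "sad")
_POSITION_FIELDS = ("top_left", "top_right", "bottom_left", "bottom_right")


def _require(doc: dict, key: str, pointer: str):
    if key not in doc:
        raise SchemaError(f"missing required field at JSON pointer {pointer}/{key}")
    return doc[key]


def _plan_from_document(doc: dict) -> Plan:
    plan_id = _require(doc, "plan_id", "")
    geo_doc = _require(doc, "geometry", "")
    geometry = MLCGeometry(
        **{k: _require(geo_doc, k, "/geometry") for k in _GEOMETRY_FIELDS}
    )
    seg_docs = _require(doc, "segments", "")
    if not isinstance(seg_docs, list) or not seg_docs:
        raise SchemaError("/segments must be a non-empty list")
    segments = []
    for i, sd in enumerate(seg_docs):
        ptr = f"/segments/{i}"
        seg = Segment(
            gantry_deg=_require(sd, "gantry_deg", ptr),
            mu=_require(sd, "mu", ptr),
            **{k: _require(sd, k, ptr) for k in _POSITION_FIELDS},
        )
        seg.validate_against(geometry)  # geometry-mismatch before Plan()
        segments.append(seg)
    return Plan(plan_id, segments, geometry)


def _plan_to_document(plan: Plan) -> dict:
    return {
        "plan_id": plan.plan_id,
        "geometry": {k: getattr(plan.geometry, k) for k in _GEOMETRY_FIELDS},
        "segments": [
            {
                "gantry_deg": s.gantry_deg,
                "mu": s.mu,
                **{k: getattr(s, k).tolist() for k in _POSITION_FIELDS},
            }
            for s in plan.segments
        ],
    }


def _plan_from_csv(path: Path) -> Plan:
    df = pd.read_csv(path)
    needed = {"plan_id", "segment", "gantry_deg", "mu", "stack", "pair", "left_cm", "right_cm"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"plan CSV missing columns: {sorted(needed - set(df.columns))}")
    counts = df.groupby("stack")["pair"].nunique()
    geometry = MLCGeometry(
        top_pairs=int(counts.get("top", 0)), bottom_pairs=int(counts.get("bottom", 0))
    )
    segments = []
    for _, g in df.sort_values(["segment", "stack", "pair"]).groupby("segment", sort=True):
        arrays = {}
        for stack, n in (("top", geometry.top_pairs), ("bottom", geometry.bottom_pairs)):
            sub = g[g["stack"] == stack]
            if len(sub) != n or not (sub["pair"].values == np.arange(n)).all():
                raise GeometryMismatchError(
                    f"segment {g['segment'].iloc[0]}: {stack} stack rows do not "
                    f"cover pairs 0..{n - 1}"
                )
            arrays[f"{stack}_left"] = sub["left_cm"].to_numpy()
            arrays[f"{stack}_right"] = sub["right_cm"].to_numpy()
        segments.append(
            Segment(g["gantry_deg"].iloc[0], g["mu"].iloc[0], **arrays)
        )
    return Plan(str(df["plan_id"].iloc[0]), segments, geometry)


def read_plan(path: PathLike) -> Plan:
    """Read a plan from the JSON dialect (or the long-format CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _plan_from_csv(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    return _plan_from_document(doc)


def write_plan(plan: Plan, path: PathLike) -> None:
    """Write a plan as JSON (or long-format CSV when path ends in .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for i, s in enumerate(plan.segments):
            for stack in ("top", "bottom"):
                left = getattr(s, f"{stack}_left")
                right = getattr(s, f"{stack}_right")
                for p in range(left.size):
                    rows.append(
                        {
                            "plan_id": plan.plan_id,
                            "segment": i,
                            "gantry_deg": s.gantry_deg,
                            "mu": s.mu,
                            "stack": stack,
                            "pair": p,
                            "left_cm": left[p],
                            "right_cm": right[p],
                        }
                    )
        pd.DataFrame(rows).to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        json.dump(_plan_to_document(plan), fh, indent=1)


# --------------------------------------------------------------------------
# internal grid format
# --------------------------------------------------------------------------

_GRID_MAGIC = b"GRID3D 1"


def write_grid(grid: Grid3D, path: PathLike) -> None:
    """Write the internal grid format: text header + raw little-endian block."""
    vals = np.asarray(grid.values, dtype="<f8")
    header = (
        f"{_GRID_MAGIC.decode()}\n"
        f"shape {vals.shape[0]} {vals.shape[1]} {vals.shape[2]}\n"
        f"spacing_mm {grid.spacing[0]!r} {grid.spacing[1]!r} {grid.spacing[2]!r}\n"
        f"origin_mm {grid.origin[0]!r} {grid.origin[1]!r} {grid.origin[2]!r}\n"
        f"dtype float64\n"
        f"data\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(vals.tobytes(order="C"))


def _read_internal_grid(path: Path) -> Grid3D:
    with open(path, "rb") as fh:
        if fh.readline().strip() != _GRID_MAGIC:
            raise ValidationError(f"{path} is not an internal grid file")
        fields = {}
        while True:
            line = fh.readline().strip().decode()
            if line == "data":
                break
            if not line:
                raise ValidationError("truncated grid header")
            key, *rest = line.split()
            fields[key] = rest
        shape = tuple(int(v) for v in fields["shape"])
        dtype = fields.get("dtype", ["float64"])[0]
        raw = fh.read()
    vals = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).reshape(shape)
    return Grid3D(
        vals.astype(float),
        tuple(float(v) for v in fields["spacing_mm"]),
        tuple(float(v) for v in fields["origin_mm"]),
    )


# --------------------------------------------------------------------------
# DICOM
# --------------------------------------------------------------------------


def _read_rtdose(path: Path) -> Grid3D:
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValidationError(f"unsupported modality {getattr(ds, 'Modality', None)!r}")
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz_patient = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz_patient, dz_patient[0], atol=1e-3):
        raise ValidationError("non-uniform dose grid frame spacing")
    frame_spacing = float(dz_patient[0]) if offsets.size > 1 else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    # (frame, row, col) = patient (S, P, L) order -> machine (x, y, z) = (col, frame, row)
    vals = np.transpose(arr, (2, 0, 1))
    return Grid3D(vals, (col_sp, frame_spacing, row_sp), (x0, z0 + offsets[0], y0))


def _read_ct_series(path: Path) -> Grid3D:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for p in files:
        if not p.is_file():
            continue
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", None) != "CT":
            raise ValidationError(f"unsupported modality {getattr(ds, 'Modality', None)!r}")
        slices.append(ds)
    if not slices:
        raise ValidationError(f"no CT slices found in {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if not np.allclose(gaps, gaps[0], atol=1e-3):
            raise ValidationError("non-uniform CT slice spacing")
        slice_spacing = float(gaps[0])
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    hu = np.stack(
        [
            ds.pixel_array.astype(float) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ]
    )  # (slice, row, col)
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    x0, y0, _ = (float(v) for v in slices[0].ImagePositionPatient)
    vals = np.transpose(hu, (2, 0, 1))  # -> machine (x, y, z)
    return Grid3D(vals, (col_sp, slice_spacing, row_sp), (x0, zs[0], y0))


def read_grid(path: PathLike) -> Grid3D:
    """Read a Grid3D from a DICOM RT Dose file, a DICOM CT series
    directory, or the internal grid format."""
    path = Path(path)
    if path.is_dir():
        return _read_ct_series(path)
    with open(path, "rb") as fh:
        head = fh.read(len(_GRID_MAGIC))
    if head == _GRID_MAGIC:
        return _read_internal_grid(path)
    return _read_rtdose(path)
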