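"""Reading and writing fascicle datasets and architecture summaries.

Canonical interchange formats (all plain text, ``#`` lines are comments):

* fascicle CSV — one row per digitized point,
  header ``fascicle_id,point_index,x_mm,y_mm,z_mm``;
* landmarks CSV — header ``name,x_mm,y_mm,z_mm`` with names
  ``origin`` and ``insertion`` (the muscle-tendon-complex endpoints);
* dataset JSON — one document bundling traces, fascicles, landmarks and
  metadata;
* summary CSV/JSON — flat key/value table of every architectural parameter,
  units embedded in the keys. Missing optional values (e.g. free tendon
  length without landmarks) are written as empty/null, never as 0.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    ArchitectureSummary,
    Fascicle,
    FascicleTrace,
    MuscleDataset,
    N_FASCICLE_POINTS,
    SUMMARY_FIELDS,
)

FASCICLE_CSV_COLUMNS = ("fascicle_id", "point_index", "x_mm", "y_mm", "z_mm")
LANDMARK_CSV_COLUMNS = ("name", "x_mm", "y_mm", "z_mm")

# %.12g round-trips through text stably: formatting, parsing and formatting
# again reproduces the byte-identical field.
_FLOAT_FMT = "%.12g"


def _fmt(value: float) -> str:
    return _FLOAT_FMT % value


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    df.columns = [c.strip() for c in df.columns]
    return df


def _numeric_column(df: pd.DataFrame, column: str, path) -> np.ndarray:
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() | raw.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column "
            f"{column!r} at data row {row}"
        )
    return values.to_numpy(dtype=float)


def read_fascicle_csv(path, landmarks_path=None, metadata_path=None) -> MuscleDataset:
    """Read a fascicle point CSV into a :class:`MuscleDataset` of raw traces.

    Traces with fewer than 3 points are rejected with a warning; the returned
    dataset carries raw traces pending preprocessing. An optional companion
    landmarks CSV and metadata JSON are merged into the dataset.
    """
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in FASCICLE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    coords = np.column_stack(
        [_numeric_column(df, c, path) for c in ("x_mm", "y_mm", "z_mm")]
    )
    order = _numeric_column(df, "point_index", path)
    ids = df["fascicle_id"].astype(str).to_numpy()

    traces = []
    rejected = []
    # preserve file order of first appearance per fascicle
    seen = {}
    for fid in ids:
        if fid not in seen:
            seen[fid] = len(seen)
    for fid in sorted(seen, key=seen.get):
        mask = ids == fid
        pts = coords[mask][np.argsort(order[mask], kind="stable")]
        if len(pts) < 3:
            rejected.append(fid)
            continue
        try:
            traces.append(FascicleTrace(fid, pts))
        except ValueError as exc:
            rejected.append(fid)
            warnings.warn(f"rejected trace {fid!r}: {exc}")
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} trace(s) with fewer than 3 "
            f"points or degenerate geometry: {rejected}"
        )

    ds = MuscleDataset(muscle_id=path.stem, traces=traces)
    if landmarks_path is not None:
        origin, insertion = read_landmarks_csv(landmarks_path)
        ds.mtc_origin = origin
        ds.mtc_insertion = insertion
    if metadata_path is not None:
        with open(metadata_path) as fh:
            ds.metadata = json.load(fh)
    return ds


def write_fascicle_csv(dataset: MuscleDataset, path, header_lines: Iterable[str] = ()) -> None:
    """Write processed fascicles (or raw traces if none) as a fascicle CSV."""
    path = Path(path)
    items = dataset.fascicles if dataset.fascicles else dataset.traces
    if not items:
        raise ValueError("dataset has neither fascicles nor traces to write")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(",".join(FASCICLE_CSV_COLUMNS) + "\n")
        for item in items:
            for k, p in enumerate(item.points):
                fh.write(
                    f"{item.fascicle_id},{k},{_fmt(p[0])},{_fmt(p[1])},{_fmt(p[2])}\n"
                )


def read_landmarks_csv(path):
    """Read MTC origin/insertion landmarks; returns (origin, insertion)."""
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in LANDMARK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    coords = np.column_stack(
        [_numeric_column(df, c, path) for c in ("x_mm", "y_mm", "z_mm")]
    )
    names = df["name"].astype(str).str.strip().str.lower().to_numpy()
    origin = insertion = None
    for name, xyz in zip(names, coords):
        if name == "origin":
            origin = xyz
        elif name == "insertion":
            insertion = xyz
        else:
            warnings.warn(f"{path}: ignoring unknown landmark {name!r}")
    return origin, insertion


def write_landmarks_csv(dataset: MuscleDataset, path, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(",".join(LANDMARK_CSV_COLUMNS) + "\n")
        for name, point in (
            ("origin", dataset.mtc_origin),
            ("insertion", dataset.mtc_insertion),
        ):
            if point is not None:
                fh.write(
                    f"{name},{_fmt(point[0])},{_fmt(point[1])},{_fmt(point[2])}\n"
                )


def write_dataset_json(dataset: MuscleDataset, path, meta: Optional[dict] = None) -> None:
    """Bundle fascicles, traces, landmarks and metadata into one JSON document."""
    doc = {
        "muscle_id": dataset.muscle_id,
        "metadata": dataset.metadata,
        "mtc_origin": None if dataset.mtc_origin is None else dataset.mtc_origin.tolist(),
        "mtc_insertion": None
        if dataset.mtc_insertion is None
        else dataset.mtc_insertion.tolist(),
        "traces": [
            {"fascicle_id": t.fascicle_id, "points_mm": t.points.tolist()}
            for t in dataset.traces
        ],
        "fascicles": [
            {"fascicle_id": f.fascicle_id, "points_mm": f.points.tolist()}
            for f in dataset.fascicles
        ],
    }
    if meta:
        doc["_meta"] = meta
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_dataset_json(path) -> MuscleDataset:
    with open(path) as fh:
        doc = json.load(fh)
    return MuscleDataset(
        muscle_id=doc.get("muscle_id", "muscle"),
        metadata=doc.get("metadata", {}),
        mtc_origin=doc.get("mtc_origin"),
        mtc_insertion=doc.get("mtc_insertion"),
        traces=[
            FascicleTrace(t["fascicle_id"], np.asarray(t["points_mm"]))
            for t in doc.get("traces", [])
        ],
        fascicles=[
            Fascicle(f["fascicle_id"], np.asarray(f["points_mm"]))
            for f in doc.get("fascicles", [])
        ],
    )


def write_summary(summary: ArchitectureSummary, path, fmt: Optional[str] = None,
                  header_lines: Iterable[str] = ()) -> None:
    """Write an architecture summary as a flat key/value CSV or JSON file.

    The dialect is inferred from the file suffix unless ``fmt`` ('csv' or
    'json') is given. Optional fields that are missing are emitted as an
    empty cell / JSON null, not as zero.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    data = summary.as_dict()
    if fmt == "json":
        doc = {k: (None if v is None else float(v)) for k, v in data.items()}
        if header_lines:
            doc["_meta"] = {"comments": list(header_lines)}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif fmt == "csv":
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("parameter,value\n")
            for key, value in data.items():
                fh.write(f"{key},{'' if value is None else _fmt(value)}\n")
    else:
        raise ValueError(f"unknown summary format {fmt!r}")


def read_summary(path, fmt: Optional[str] = None) -> ArchitectureSummary:
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        doc.pop("_meta", None)
        return ArchitectureSummary.from_dict(doc)
    if fmt == "csv":
        df = _read_csv(path)
        if "parameter" not in df.columns or "value" not in df.columns:
            raise ValueError(f"{path}: expected columns 'parameter' and 'value'")
        data = {}
        for key, value in zip(df["parameter"], df["value"]):
            if key not in SUMMARY_FIELDS:
                continue
            if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
                data[key] = None
            else:
                data[key] = float(value)
        return ArchitectureSummary.from_dict(data)
    raise ValueError(f"unknown summary format {fmt!r}")
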