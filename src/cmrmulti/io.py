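"""File formats: NIfTI volumes with JSON sidecars, CSV tables, JSON reports.

Conventions
-----------
* Multi-echo stacks are 4-D NIfTI (x, y, slice, echo) with a JSON sidecar
  carrying ``echo_times_ms`` and ``slice_labels``.
* T2 maps are 3-D NIfTI in ms, accompanied by an integer status map and a
  JSON fit report (method, per-slice sigma).
* Segment tables, cohort tables and contours are CSV with fixed schemas;
  units are encoded in the column names (``_ms``, ``_pct``, ``_per_s``).

Every writer/reader pair round-trips its object exactly (up to float64
representation).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .t2map import MultiEchoStack, T2Map

__all__ = [
    "SchemaError",
    "save_stack",
    "load_stack",
    "save_t2map",
    "load_t2map",
    "save_labels",
    "load_labels",
    "save_segment_table",
    "load_segment_table",
    "save_cohort",
    "load_cohort",
    "save_contour",
    "load_contour",
    "save_json",
    "load_json",
]

SEGMENT_COLUMNS = ["segment_id", "level", "mean_t2_ms", "pixel_sd_ms", "n_pixels", "flagged"]
COHORT_REQUIRED = ["subject_id", "group"]
CONTOUR_COLUMNS = ["point_id", "row", "col"]


class SchemaError(ValueError):
    """A table does not match its expected column schema."""


def _check_columns(df: pd.DataFrame, required: list[str], kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing required columns {missing}")


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_stack(stack: MultiEchoStack, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data, affine=np.eye(4)), path)
    _sidecar(path).write_text(
        json.dumps(
            {
                "echo_times_ms": list(stack.echo_times),
                "slice_labels": list(stack.slice_labels),
            },
            indent=2,
        )
    )


def load_stack(path: str | Path) -> MultiEchoStack:
    path = Path(path)
    data = np.asarray(nib.load(path).get_fdata())
    meta = json.loads(_sidecar(path).read_text())
    return MultiEchoStack(
        data=data,
        echo_times=tuple(meta["echo_times_ms"]),
        slice_labels=tuple(meta["slice_labels"]),
    )


def save_t2map(t2map: T2Map, path: str | Path) -> None:
    """Write T2 (ms) and S0 maps, the status map, and a JSON fit report."""
    path = Path(path)
    nib.save(nib.Nifti1Image(t2map.t2, affine=np.eye(4)), path)
    stem = str(path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    nib.save(nib.Nifti1Image(t2map.s0, affine=np.eye(4)), stem + "_s0.nii.gz")
    nib.save(
        nib.Nifti1Image(t2map.status.astype(np.int16), affine=np.eye(4)),
        stem + "_status.nii.gz",
    )
    _sidecar(path).write_text(
        json.dumps(
            {
                "method": t2map.method,
                "sigma_per_slice": [None if np.isnan(s) else float(s) for s in t2map.sigma],
                "slice_labels": list(t2map.slice_labels),
                "units": "ms",
            },
            indent=2,
        )
    )


def load_t2map(path: str | Path) -> T2Map:
    path = Path(path)
    stem = str(path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    t2 = np.asarray(nib.load(path).get_fdata())
    s0 = np.asarray(nib.load(stem + "_s0.nii.gz").get_fdata())
    status = np.asarray(nib.load(stem + "_status.nii.gz").get_fdata()).astype(np.int8)
    meta = json.loads(_sidecar(path).read_text())
    sigma = np.array(
        [np.nan if s is None else float(s) for s in meta["sigma_per_slice"]], dtype=float
    )
    return T2Map(
        t2=t2,
        s0=s0,
        status=status,
        sigma=sigma,
        method=meta["method"],
        slice_labels=tuple(meta["slice_labels"]),
    )


def save_labels(labels: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine=np.eye(4)), Path(path))


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).get_fdata()).astype(np.int16)


def save_segment_table(table: pd.DataFrame, path: str | Path) -> None:
    _check_columns(table, SEGMENT_COLUMNS, "segment table")
    table[SEGMENT_COLUMNS].to_csv(path, index=False)


def load_segment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SEGMENT_COLUMNS, "segment table")
    df["flagged"] = df["flagged"].astype(bool)
    return df


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    _check_columns(table, COHORT_REQUIRED, "cohort table")
    table.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COHORT_REQUIRED, "cohort table")
    bad = set(df["group"].unique()) - {"control", "patient"}
    if bad:
        raise SchemaError(f"cohort table: unknown group labels {sorted(bad)}")
    return df


def save_contour(points: np.ndarray, path: str | Path) -> None:
    pts = np.asarray(points, dtype=float)
    pd.DataFrame(
        {"point_id": np.arange(len(pts)), "row": pts[:, 0], "col": pts[:, 1]}
    ).to_csv(path, index=False)


def load_contour(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    _check_columns(df, CONTOUR_COLUMNS, "contour")
    return df.sort_values("point_id")[["row", "col"]].to_numpy(dtype=float)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
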