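"""AHA 16-segment parcellation of short-axis myocardial masks.

Three short-axis levels are split into angular sectors about the slice
centroid, anchored at the anterior right-ventricular insertion point:
six 60-degree sectors on the basal (segments 1-6) and mid-ventricular
(7-12) levels, four 90-degree sectors on the apical level (13-16).  The
true apex (segment 17) is not covered by a three-slice protocol.

Angles are measured clockwise in image-display coordinates (rows grow
downward), matching the orientation in which clinicians read a short-axis
view.  A pixel exactly on a sector boundary is assigned to the
counter-clockwise-following segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SliceGeometry",
    "SEGMENT_NAMES",
    "LEVEL_SEGMENT_IDS",
    "assign_segments",
    "segment_statistics",
    "DEFAULT_MIN_PIXELS",
]

DEFAULT_MIN_PIXELS = 10

#: Segment ids per level, in sector order starting at the anterior
#: RV-insertion ray and proceeding clockwise on screen.
LEVEL_SEGMENT_IDS: dict[str, tuple[int, ...]] = {
    "basal": (1, 2, 3, 4, 5, 6),
    "mid": (7, 8, 9, 10, 11, 12),
    "apical": (13, 14, 15, 16),
}

SEGMENT_NAMES: dict[int, str] = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
}


@dataclass
class SliceGeometry:
    """One short-axis slice: myocardial mask, centroid and RV insertion.

    ``rv_insertion`` is either an angle in degrees (clockwise image
    convention) or a pixel coordinate ``(row, col)`` from which the angle
    about the centroid is derived.  ``centroid`` defaults to the mask
    centroid.
    """

    mask: np.ndarray
    level: str
    rv_insertion: float | tuple[float, float] = 0.0
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.level not in LEVEL_SEGMENT_IDS:
            raise ValueError(f"level must be one of {tuple(LEVEL_SEGMENT_IDS)}")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.centroid is None:
            rows, cols = np.nonzero(self.mask)
            self.centroid = (float(rows.mean()), float(cols.mean()))

    @property
    def rv_insertion_angle(self) -> float:
        if isinstance(self.rv_insertion, (int, float)):
            return float(self.rv_insertion) % 360.0
        dr = self.rv_insertion[0] - self.centroid[0]
        dc = self.rv_insertion[1] - self.centroid[1]
        if dr == 0 and dc == 0:
            raise ValueError("rv_insertion coincides with the centroid")
        return math.degrees(math.atan2(dr, dc)) % 360.0


def assign_segments(geom: SliceGeometry) -> np.ndarray:
    """Label every masked pixel with its AHA segment id (0 = background).

    The angle of each pixel about the centroid, measured clockwise from
    the anterior RV-insertion ray, selects a sector; sectors map to
    segment ids in the standard order (anterior, anteroseptal,
    inferoseptal, inferior, inferolateral, anterolateral on basal/mid;
    anterior, septal, inferior, lateral on apical).  Boundary pixels go to
    the counter-clockwise-following segment, i.e. sector ``k`` covers the
    half-open angular interval ``(k*w, (k+1)*w]``.
    """
    ids = LEVEL_SEGMENT_IDS[geom.level]
    width = 360.0 / len(ids)
    rows, cols = np.nonzero(geom.mask)
    cr, cc = geom.centroid
    ang = np.degrees(np.arctan2(rows - cr, cols - cc))
    rel = np.mod(ang - geom.rv_insertion_angle, 360.0)
    # (k*w, (k+1)*w]: ceil(rel/w) - 1, with rel == 0 wrapping to the last sector
    sector = (np.ceil(rel / width).astype(int) - 1) % len(ids)
    labels = np.zeros(geom.mask.shape, dtype=np.int16)
    labels[rows, cols] = np.asarray(ids, dtype=np.int16)[sector]
    return labels


def segment_statistics(
    t2: np.ndarray,
    labels: np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> pd.DataFrame:
    """Segmental mean T2 and pixel-SD from a labelled T2 volume.

    Parameters
    ----------
    t2:
        3-D T2 values (x, y, slice), NaN where no valid fit exists.
    labels:
        3-D integer segment labels (0 background), e.g. stacked outputs of
        :func:`assign_segments` for the basal, mid and apical slices.
    min_pixels:
        Segments with fewer valid pixels are flagged; flagged rows are
        excluded from downstream subject-level statistics.

    Returns a 16-row table with columns ``segment_id``, ``level``,
    ``mean_t2_ms``, ``pixel_sd_ms`` (sample SD, n-1 denominator) and
    ``n_pixels``, plus a boolean ``flagged`` column.
    """
    t2 = np.asarray(t2, dtype=float)
    labels = np.asarray(labels)
    if t2.shape != labels.shape:
        raise ValueError("t2 and labels shapes differ")
    level_of = {sid: lvl for lvl, sids in LEVEL_SEGMENT_IDS.items() for sid in sids}
    records = []
    for sid in range(1, 17):
        vals = t2[labels == sid]
        vals = vals[np.isfinite(vals)]
        n = int(vals.size)
        mean = float(vals.mean()) if n else np.nan
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        records.append(
            {
                "segment_id": sid,
                "level": level_of[sid],
                "mean_t2_ms": mean,
                "pixel_sd_ms": sd,
                "n_pixels": n,
                "flagged": n < min_pixels,
            }
        )
    return pd.DataFrame.from_records(records)
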