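"""Feature tracking of endocardial contours and strain computation.

A manually drawn end-diastolic contour is propagated through the cine
cycle by normalized cross-correlation block matching: for each contour
point, a square template around its current position is searched for in
the next frame, the correlation peak is refined to sub-pixel precision by
parabolic interpolation, and low-confidence matches are interpolated from
neighbouring points.  Because frame-to-frame matching accumulates drift
over a full cycle, the net end-of-cycle displacement is redistributed
linearly across frames so the tracked contour closes back onto the
end-diastolic one (cyclic closure).

Strain is Lagrangian and perimeter-based: ``eps(t) = 100 * (L(t) - L(0)) /
L(0)`` with ``L`` the contour polyline length — circumferential strain on
closed short-axis contours, longitudinal strain on open four-chamber
polylines.  Strain rate is the time derivative of the strain fraction, in
1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

__all__ = [
    "TrackedContour",
    "StrainCurve",
    "StrainSummary",
    "track_contour",
    "strain_from_contour",
    "peak_value",
    "global_strain",
]


@dataclass
class TrackedContour:
    """Contour positions per frame, (n_frames, n_points, 2) in (row, col)."""

    points: np.ndarray
    frame_times: np.ndarray  # ms
    closed: bool = True
    low_confidence: np.ndarray | None = None  # (n_frames, n_points) bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must be (n_frames, n_points, 2)")
        if self.frame_times.shape[0] != self.points.shape[0]:
            raise ValueError("frame_times length must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")


@dataclass
class StrainCurve:
    """Lagrangian strain (%) and strain rate (1/s) over one cycle."""

    epsilon: np.ndarray
    strain_rate: np.ndarray
    frame_times: np.ndarray
    kind: str = "circumferential"  # or "longitudinal"
    chamber: str = "LV"
    slice_level: str | None = None


@dataclass
class StrainSummary:
    """Peak (signed-extremum) global strain and strain-rate parameters.

    Peaks keep their sign: contraction gives negative strain, so the peak
    is the most negative excursion.
    """

    gls_lv: float | None = None
    gcs_lv: float | None = None
    gls_rv: float | None = None
    gcs_rv: float | None = None
    peak_sr: dict[str, float] = field(default_factory=dict)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2 * c0 + cp1
    if denom >= 0:  # not a proper peak
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def _match_point(
    prev_img: np.ndarray,
    next_img: np.ndarray,
    pos: np.ndarray,
    template: int,
    search: int,
) -> tuple[np.ndarray, float]:
    """NCC displacement of one point between consecutive frames."""
    th, sh = template // 2, search // 2
    r0, c0 = int(round(pos[0])), int(round(pos[1]))
    H, W = prev_img.shape
    if not (th <= r0 < H - th and th <= c0 < W - th):
        return np.zeros(2), -1.0
    tpl = prev_img[r0 - th : r0 + th + 1, c0 - th : c0 + th + 1]
    rlo, rhi = r0 - sh, r0 + sh + 1
    clo, chi = c0 - sh, c0 + sh + 1
    if rlo < 0 or clo < 0 or rhi > H or chi > W:
        return np.zeros(2), -1.0
    win = next_img[rlo:rhi, clo:chi]
    if tpl.std() == 0 or win.std() == 0:
        return np.zeros(2), -1.0
    corr = match_template(win, tpl)  # (search-template+1)^2 valid map
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[peak])
    dr = peak[0] - (sh - th)
    dc = peak[1] - (sh - th)
    # parabolic sub-pixel refinement where the peak has interior neighbours;
    # an exact integer-lag match (score ~ 1) needs no refinement and would
    # only pick up noise from asymmetric neighbours
    sub = np.zeros(2)
    if score >= 1.0 - 1e-6:
        return np.array([float(dr), float(dc)]), score
    if 0 < peak[0] < corr.shape[0] - 1:
        sub[0] = _parabolic_offset(
            corr[peak[0] - 1, peak[1]], score, corr[peak[0] + 1, peak[1]]
        )
    if 0 < peak[1] < corr.shape[1] - 1:
        sub[1] = _parabolic_offset(
            corr[peak[0], peak[1] - 1], score, corr[peak[0], peak[1] + 1]
        )
    return np.array([dr + sub[0], dc + sub[1]]), score


def track_contour(
    frames: np.ndarray,
    ed_contour: np.ndarray,
    frame_times: np.ndarray | None = None,
    frame_interval_ms: float = 33.0,
    template: int = 15,
    search: int = 25,
    corr_threshold: float = 0.5,
    closed: bool = True,
    cyclic_closure: bool = True,
) -> TrackedContour:
    """Track an end-diastolic contour through a cine frame sequence.

    Parameters follow standard block-matching practice: a 15x15 template
    is searched within a 25x25 window (displacements up to +/-5 px per
    frame).  Matches whose correlation peak falls below
    ``corr_threshold`` are replaced by the average displacement of the
    two neighbouring contour points and flagged.  With ``cyclic_closure``
    the residual displacement after tracking once around the cycle is
    removed by linear redistribution over frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be (n_frames, H, W) with >= 2 frames")
    ed = np.asarray(ed_contour, dtype=float)
    if ed.ndim != 2 or ed.shape[1] != 2:
        raise ValueError("ed_contour must be (n_points, 2)")
    n_frames, n_points = frames.shape[0], ed.shape[0]
    if frame_times is None:
        frame_times = np.arange(n_frames) * frame_interval_ms

    pts = np.empty((n_frames, n_points, 2))
    pts[0] = ed
    flags = np.zeros((n_frames, n_points), dtype=bool)

    def step(prev_img, next_img, cur):
        disps = np.zeros((n_points, 2))
        ok = np.ones(n_points, dtype=bool)
        for i in range(n_points):
            d, score = _match_point(prev_img, next_img, cur[i], template, search)
            disps[i] = d
            ok[i] = score >= corr_threshold
        if not ok.all():
            good = np.nonzero(ok)[0]
            if good.size == 0:
                disps[:] = 0.0
            else:
                for i in np.nonzero(~ok)[0]:
                    # nearest good neighbours along the (cyclically) ordered contour
                    back = (i - good) % n_points
                    fwd = (good - i) % n_points
                    prev_i = good[np.argmin(np.where(back == 0, n_points, back))]
                    next_i = good[np.argmin(np.where(fwd == 0, n_points, fwd))]
                    disps[i] = (disps[prev_i] + disps[next_i]) / 2.0
        return disps, ok

    for t in range(n_frames - 1):
        disps, ok = step(frames[t], frames[t + 1], pts[t])
        pts[t + 1] = pts[t] + disps
        flags[t + 1] = ~ok

    if cyclic_closure:
        # wrap transition: last frame back onto frame 0
        disps, _ = step(frames[-1], frames[0], pts[-1])
        drift = (pts[-1] + disps) - pts[0]
        for t in range(1, n_frames):
            pts[t] -= drift * (t / n_frames)

    return TrackedContour(
        points=pts, frame_times=np.asarray(frame_times, dtype=float), closed=closed,
        low_confidence=flags,
    )


def _polyline_length(points: np.ndarray, closed: bool) -> float:
    seg = np.diff(points, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if closed:
        length += float(np.hypot(*(points[0] - points[-1])))
    return length


def strain_from_contour(
    tracked: TrackedContour,
    kind: str = "circumferential",
    chamber: str = "LV",
    slice_level: str | None = None,
) -> StrainCurve:
    """Perimeter-based Lagrangian strain and its rate from a tracked contour.

    Strain rate uses central differences on the frame times (one-sided at
    the endpoints), on the strain *fraction*, giving 1/s.
    """
    lengths = np.array(
        [_polyline_length(tracked.points[t], tracked.closed) for t in range(tracked.points.shape[0])]
    )
    if lengths[0] == 0:
        raise ValueError("zero initial contour length")
    eps = 100.0 * (lengths - lengths[0]) / lengths[0]
    t_s = tracked.frame_times / 1000.0
    sr = np.gradient(eps / 100.0, t_s)
    return StrainCurve(
        epsilon=eps,
        strain_rate=sr,
        frame_times=tracked.frame_times,
        kind=kind,
        chamber=chamber,
        slice_level=slice_level,
    )


def peak_value(values: np.ndarray) -> float:
    """Signed extremum: the value of largest magnitude, keeping its sign."""
    values = np.asarray(values, dtype=float)
    return float(values[np.argmax(np.abs(values))])


def global_strain(
    circumferential: list[StrainCurve] | None = None,
    longitudinal: dict[str, StrainCurve] | None = None,
    average_curves_first: bool = False,
) -> StrainSummary:
    """Combine per-slice/per-view strain curves into global parameters.

    Global circumferential strain is the arithmetic mean of the per-slice
    peak values over the (nominally three) short-axis slices; global
    longitudinal strain comes from the single four-chamber curve per
    chamber.  ``average_curves_first`` switches to averaging the curves
    pointwise and taking the peak of the mean curve instead.
    """
    summary = StrainSummary()
    circumferential = circumferential or []
    longitudinal = longitudinal or {}

    for chamber in ("LV", "RV"):
        curves = [c for c in circumferential if c.chamber == chamber]
        if not curves:
            continue
        if len(curves) != 3:
            warnings.warn(
                f"{chamber}: expected 3 short-axis curves, got {len(curves)}; "
                "averaging over the available slices",
                stacklevel=2,
            )
        if average_curves_first:
            peak_strain = peak_value(np.mean([c.epsilon for c in curves], axis=0))
            peak_sr = peak_value(np.mean([c.strain_rate for c in curves], axis=0))
        else:
            peak_strain = float(np.mean([peak_value(c.epsilon) for c in curves]))
            peak_sr = float(np.mean([peak_value(c.strain_rate) for c in curves]))
        if chamber == "LV":
            summary.gcs_lv = peak_strain
        else:
            summary.gcs_rv = peak_strain
        summary.peak_sr[f"circumferential_{chamber}"] = peak_sr

    for chamber, curve in longitudinal.items():
        peak_strain = peak_value(curve.epsilon)
        if chamber == "LV":
            summary.gls_lv = peak_strain
        elif chamber == "RV":
            summary.gls_rv = peak_strain
        summary.peak_sr[f"longitudinal_{chamber}"] = peak_value(curve.strain_rate)

    return summary
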