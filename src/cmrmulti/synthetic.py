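"""Synthetic data with known ground truth for every pipeline stage.

Four generators:

* :func:`simulate_decay` — mono-exponential multi-echo magnitudes under
  Rician noise (the raw substrate of T2 mapping);
* :func:`simulate_heart_phantom` — an annular short-axis "myocardium" with
  focal high-T2 lesions and a known per-pixel T2 field;
* :func:`simulate_cine` — a deforming contour phantom with a prescribed
  Lagrangian strain curve, rendered as speckle-textured frames;
* :func:`simulate_cohort` — two-group subject tables (controls vs.
  myocarditis patients) drawn from published group-level means and SDs.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .t2map import MultiEchoStack

__all__ = [
    "DecaySpec",
    "Lesion",
    "PhantomSpec",
    "HeartPhantom",
    "CineSpec",
    "CineResult",
    "CohortSpec",
    "GroupParams",
    "REFERENCE_COHORT_PARAMS",
    "circle_contour",
    "simulate_decay",
    "simulate_heart_phantom",
    "simulate_cine",
    "simulate_cohort",
]

DEFAULT_ECHO_TIMES = tuple(float(te) for te in range(16, 97, 16))
"""Six echo times (ms) typical of a GraSE T2-mapping acquisition."""


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# decay signals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecaySpec:
    """Mono-exponential decay ``S(TE) = s0 * exp(-TE / t2)`` plus Rician noise.

    Parameters
    ----------
    s0:
        Signal amplitude at TE = 0 (arbitrary units, > 0).
    t2:
        Transverse relaxation time in ms (> 0).
    echo_times:
        Strictly increasing echo times in ms, at least two.
    sigma:
        Rician noise scale in the units of ``s0`` (>= 0).  ``sigma = 0``
        reproduces the noiseless exponential exactly.
    """

    s0: float
    t2: float
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        if self.t2 <= 0:
            raise ValueError(f"t2 must be > 0, got {self.t2}")
        tes = np.asarray(self.echo_times, dtype=float)
        if tes.size < 2 or np.any(np.diff(tes) <= 0):
            raise ValueError("echo_times must contain >= 2 strictly increasing values")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def simulate_decay(
    spec: DecaySpec,
    n_pixels: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_pixels`` noisy magnitude decay curves.

    Each magnitude is the modulus of the noiseless signal perturbed by a
    complex Gaussian: ``m = sqrt((nu + g1)^2 + g2^2)`` with independent
    ``g1, g2 ~ N(0, sigma^2)`` — the standard Rician construction.  With
    ``nu = 0`` this reduces to a Rayleigh sample (pure background).

    Returns an ``(n_pixels, n_echoes)`` array.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    rng = _as_rng(seed)
    tes = np.asarray(spec.echo_times, dtype=float)
    nu = spec.s0 * np.exp(-tes / spec.t2)
    if spec.sigma == 0:
        return np.tile(nu, (n_pixels, 1))
    g1 = rng.normal(0.0, spec.sigma, size=(n_pixels, tes.size))
    g2 = rng.normal(0.0, spec.sigma, size=(n_pixels, tes.size))
    return np.sqrt((nu + g1) ** 2 + g2**2)


# ---------------------------------------------------------------------------
# heart phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lesion:
    """A focal high-T2 sector lesion within the annular myocardium.

    ``transmural_fraction`` measures lesion depth inward from the
    epicardial border (subepicardial placement, the typical myocarditis
    pattern).  ``t2_spread`` is the SD of per-pixel T2 jitter inside the
    lesion, modelling intra-lesion heterogeneity.
    """

    center_angle_deg: float
    extent_deg: float
    transmural_fraction: float = 0.5
    delta_t2: float = 20.0
    t2_spread: float = 0.0
    level: str = "basal"

    def __post_init__(self) -> None:
        if not 0 < self.extent_deg <= 360:
            raise ValueError("extent_deg must be in (0, 360]")
        if not 0 < self.transmural_fraction <= 1:
            raise ValueError("transmural_fraction must be in (0, 1]")
        if self.t2_spread < 0:
            raise ValueError("t2_spread must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Three-slice annular myocardium phantom.

    The annulus (endocardial radius ``r_endo``, epicardial radius
    ``r_epi``) is identical on the basal, mid and apical slices; lesions
    are placed per-slice via their ``level`` field.  Signal amplitude and
    noise describe the multi-echo acquisition used to render the stack.
    """

    grid_size: int = 96
    center: tuple[float, float] | None = None  # (row, col); None = grid centre
    r_endo: float = 16.0
    r_epi: float = 28.0
    base_t2: float = 55.0
    lesions: tuple[Lesion, ...] = ()
    rv_insertion_angle: float = 300.0
    s0: float = 1000.0
    sigma: float = 0.0
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_endo < self.r_epi:
            raise ValueError("need 0 < r_endo < r_epi")
        if self.r_epi >= self.grid_size / 2:
            raise ValueError("epicardial radius exceeds the grid")
        for les in self.lesions:
            if not 0 <= les.center_angle_deg % 360 < 360:
                raise ValueError("lesion angle out of range")


@dataclass
class HeartPhantom:
    """Rendered phantom: multi-echo stack, mask, ground-truth T2 field.

    ``t2_truth`` is NaN outside the myocardial mask and is independent of
    the signal amplitude by construction.  ``rv_insertion_angle`` is in the
    clockwise image-display convention used throughout the package.
    """

    stack: MultiEchoStack
    mask: np.ndarray  # (nx, ny, nslices) bool
    t2_truth: np.ndarray  # (nx, ny, nslices) float, NaN off-mask
    rv_insertion_angle: float
    rv_insertion_point: tuple[float, float]
    spec: PhantomSpec


def _pixel_angles(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Clockwise screen angle (deg, [0, 360)) of each pixel about ``center``.

    Image rows increase downward, so the mathematically positive
    ``atan2(drow, dcol)`` direction appears clockwise when the image is
    displayed — the convention clinicians see on a short-axis view.
    """
    rows, cols = np.indices(shape)
    ang = np.degrees(np.arctan2(rows - center[0], cols - center[1]))
    return np.mod(ang, 360.0)


def _angular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.mod(a - b, 360.0)
    return np.minimum(d, 360.0 - d)


def simulate_heart_phantom(spec: PhantomSpec) -> HeartPhantom:
    """Render a three-slice annulus phantom with known per-pixel T2.

    Every masked pixel's true T2 is ``base_t2`` plus the ``delta_t2`` of any
    lesion covering it (plus zero-mean Gaussian jitter of SD ``t2_spread``
    inside lesions).  Echo images are generated pixel-wise with
    :func:`simulate_decay`; background pixels carry pure Rician (Rayleigh)
    noise, so a background region can be used for noise-scale estimation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    center = spec.center or ((n - 1) / 2.0, (n - 1) / 2.0)
    rows, cols = np.indices((n, n))
    radius = np.hypot(rows - center[0], cols - center[1])
    annulus = (radius >= spec.r_endo) & (radius <= spec.r_epi)
    if not annulus.any():
        raise ValueError("annulus is empty on this grid")
    angles = _pixel_angles((n, n), center)

    levels = ("basal", "mid", "apical")
    mask = np.repeat(annulus[:, :, None], 3, axis=2)
    t2_truth = np.full((n, n, 3), np.nan)
    for k, level in enumerate(levels):
        field_k = np.where(annulus, spec.base_t2, np.nan)
        for les in spec.lesions:
            if les.level != level:
                continue
            in_sector = _angular_distance(angles, les.center_angle_deg) <= les.extent_deg / 2
            depth = spec.r_epi - les.transmural_fraction * (spec.r_epi - spec.r_endo)
            in_depth = radius >= depth
            hit = annulus & in_sector & in_depth
            field_k = np.where(hit, field_k + les.delta_t2, field_k)
            if les.t2_spread > 0:
                jitter = rng.normal(0.0, les.t2_spread, size=field_k.shape)
                field_k = np.where(hit, field_k + jitter, field_k)
        t2_truth[:, :, k] = field_k

    tes = np.asarray(spec.echo_times, dtype=float)
    data = np.zeros((n, n, 3, tes.size))
    for k in range(3):
        flat_t2 = t2_truth[:, :, k].ravel()
        nu = np.where(
            np.isnan(flat_t2)[:, None],
            0.0,
            spec.s0 * np.exp(-tes[None, :] / np.where(np.isnan(flat_t2), 1.0, flat_t2)[:, None]),
        )
        if spec.sigma > 0:
            g1 = rng.normal(0.0, spec.sigma, size=nu.shape)
            g2 = rng.normal(0.0, spec.sigma, size=nu.shape)
            mags = np.sqrt((nu + g1) ** 2 + g2**2)
        else:
            mags = nu
        data[:, :, k, :] = mags.reshape(n, n, tes.size)

    stack = MultiEchoStack(data=data, echo_times=tuple(tes), slice_labels=levels)
    theta = math.radians(spec.rv_insertion_angle)
    point = (center[0] + spec.r_epi * math.sin(theta), center[1] + spec.r_epi * math.cos(theta))
    return HeartPhantom(
        stack=stack,
        mask=mask,
        t2_truth=t2_truth,
        rv_insertion_angle=spec.rv_insertion_angle,
        rv_insertion_point=point,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cine phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CineSpec:
    """Deforming contour phantom for feature-tracking validation.

    The end-diastolic contour is scaled about its centroid each frame so
    that the perimeter follows the prescribed Lagrangian strain curve
    ``epsilon(t)`` (in %, ``epsilon(0) = 0``), then rigidly translated.
    Frames render the contour as a band of Gaussian speckle markers
    attached to the material points, giving the tracker texture to lock
    onto, plus additive Gaussian image noise.
    """

    n_frames: int
    contour: tuple[tuple[float, float], ...]  # (row, col) at end-diastole
    strain_curve: tuple[float, ...]  # percent, one per frame
    translation: tuple[tuple[float, float], ...] | None = None
    noise_sd: float = 0.0
    frame_interval_ms: float = 33.0
    image_size: int = 128
    marker_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.contour) < 16:
            raise ValueError("contour needs >= 16 points")
        if len(self.strain_curve) != self.n_frames:
            raise ValueError("strain_curve must have one value per frame")
        if self.strain_curve[0] != 0:
            raise ValueError("strain_curve must start at 0 (end-diastole)")
        if min(self.strain_curve) <= -100:
            raise ValueError("strain <= -100% collapses the contour")
        if self.translation is not None and len(self.translation) != self.n_frames:
            raise ValueError("translation must have one offset per frame")


@dataclass
class CineResult:
    frames: np.ndarray  # (n_frames, H, W)
    contours: np.ndarray  # (n_frames, n_points, 2) ground truth, (row, col)
    frame_times: np.ndarray  # ms
    spec: CineSpec


def circle_contour(center: tuple[float, float], radius: float, n_points: int = 48) -> tuple[tuple[float, float], ...]:
    """Convenience: a closed circular contour as (row, col) tuples."""
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return tuple((center[0] + radius * np.sin(t), center[1] + radius * np.cos(t)) for t in th)


def simulate_cine(spec: CineSpec) -> CineResult:
    """Render the cine phantom and return frames plus ground-truth contours.

    Scaling the contour about its centroid by ``1 + eps/100`` scales the
    perimeter by exactly the same factor, so the ground-truth perimeter
    series matches the prescribed strain to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    ed = np.asarray(spec.contour, dtype=float)
    centroid = ed.mean(axis=0)
    eps = np.asarray(spec.strain_curve, dtype=float)
    trans = (
        np.zeros((spec.n_frames, 2))
        if spec.translation is None
        else np.asarray(spec.translation, dtype=float)
    )

    contours = np.empty((spec.n_frames, ed.shape[0], 2))
    for t in range(spec.n_frames):
        scale = 1.0 + eps[t] / 100.0
        contours[t] = centroid + scale * (ed - centroid) + trans[t]

    # per-marker amplitudes fixed across frames: material speckle
    amps = 120.0 + 130.0 * rng.random(ed.shape[0])
    size = spec.image_size
    frames = np.zeros((spec.n_frames, size, size))
    half = int(math.ceil(4 * spec.marker_sigma))
    for t in range(spec.n_frames):
        img = frames[t]
        for (r, c), a in zip(contours[t], amps):
            r0, c0 = int(round(r)), int(round(c))
            rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, size)
            clo, chi = max(c0 - half, 0), min(c0 + half + 1, size)
            if rlo >= rhi or clo >= chi:
                continue
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            img[rlo:rhi, clo:chi] += a * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * spec.marker_sigma**2)
            )
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    frame_times = np.arange(spec.n_frames) * spec.frame_interval_ms
    return CineResult(frames=frames, contours=contours, frame_times=frame_times, spec=spec)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Per-parameter group-level Gaussian parameters (mean ± SD)."""

    mean_control: float
    sd_control: float
    mean_patient: float
    sd_patient: float

    def __post_init__(self) -> None:
        if self.sd_control < 0 or self.sd_patient < 0:
            raise ValueError("SDs must be >= 0")


#: Published two-group summary statistics (controls vs. acute-myocarditis
#: patients) used as generator defaults: strain in %, SR in 1/s, T2 in ms.
REFERENCE_COHORT_PARAMS: dict[str, GroupParams] = {
    "madSD_ms": GroupParams(1.7, 1.0, 2.9, 1.4),
    "maxT2_ms": GroupParams(69.0, 11.0, 79.0, 13.0),
    "meanT2_ms": GroupParams(58.0, 5.0, 63.0, 6.0),
    "GLS_LV_pct": GroupParams(-17.0, 5.0, -14.0, 6.0),
    "GCS_LV_pct": GroupParams(-29.0, 4.0, -26.0, 4.0),
    "SRlong_LV_per_s": GroupParams(-1.1, 0.3, -0.9, 0.4),
}

#: Parameters whose values cannot be negative; draws are truncated at zero
#: by rejection so means stay approximately calibrated.
NONNEGATIVE_PARAMS = ("madSD_ms",)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort generator (independent Gaussian parameters + LGE).

    Defaults reproduce the published study conditions: 17 controls, 67
    patients, parameter means/SDs from the reference table, LGE prevalence
    0.52 in patients and 0.00 in controls.  Inter-parameter correlations
    are not modelled (none are published); all draws are independent.
    """

    n_controls: int = 17
    n_patients: int = 67
    params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(REFERENCE_COHORT_PARAMS)
    )
    lge_rate_patient: float = 0.52
    lge_rate_control: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("both groups need at least one subject")
        for p in (self.lge_rate_patient, self.lge_rate_control):
            if not 0 <= p <= 1:
                raise ValueError("LGE rates must be probabilities")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Zero-truncated normal draws whose *truncated* mean equals ``mean``.

    Rejection sampling from N(mu, sd) with negatives resampled shifts the
    mean upward by ``sd * phi(mu/sd) / Phi(mu/sd)``; the underlying ``mu``
    is therefore solved so the post-truncation mean stays calibrated to
    the published group mean.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    def trunc_mean(mu: float) -> float:
        a = mu / sd
        return mu + sd * norm.pdf(a) / norm.cdf(a)

    mu = brentq(lambda m: trunc_mean(m) - mean, -10 * sd, mean + 10 * sd, xtol=1e-10)
    out = rng.normal(mu, sd, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def simulate_cohort(spec: CohortSpec):
    """Draw a per-subject cohort table as a pandas DataFrame.

    Columns: ``subject_id``, ``group`` ({control, patient}), one column per
    parameter, and a binary ``LGE`` flag.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rows = {}
    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    rows["subject_id"] = [f"S{i:04d}" for i in range(len(groups))]
    rows["group"] = groups
    for name, gp in spec.params.items():
        if gp.sd_control == 0:
            ctrl = np.full(spec.n_controls, gp.mean_control)
        elif name in NONNEGATIVE_PARAMS:
            ctrl = _truncated_normal(rng, gp.mean_control, gp.sd_control, spec.n_controls)
        else:
            ctrl = rng.normal(gp.mean_control, gp.sd_control, spec.n_controls)
        if gp.sd_patient == 0:
            pat = np.full(spec.n_patients, gp.mean_patient)
        elif name in NONNEGATIVE_PARAMS:
            pat = _truncated_normal(rng, gp.mean_patient, gp.sd_patient, spec.n_patients)
        else:
            pat = rng.normal(gp.mean_patient, gp.sd_patient, spec.n_patients)
        rows[name] = np.concatenate([ctrl, pat])
    lge_c = rng.random(spec.n_controls) < spec.lge_rate_control
    lge_p = rng.random(spec.n_patients) < spec.lge_rate_patient
    rows["LGE"] = np.concatenate([lge_c, lge_p]).astype(int)
    return pd.DataFrame(rows)
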