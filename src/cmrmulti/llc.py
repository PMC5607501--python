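"""Quantitative Lake Louise criteria (LLC) for CMR myocarditis diagnosis.

Three criteria, diagnosis positive when at least two are met:

1. edema — myocardium-to-skeletal-muscle signal-intensity ratio on
   T2-weighted black-blood images >= 1.9, and/or a visual edema read;
2. hyperemia — early gadolinium enhancement ratio (EGEr) >= 4, the
   myocardial relative enhancement normalized to skeletal muscle;
3. necrosis/fibrosis — a late gadolinium enhancement (LGE) pattern
   typical for myocarditis (entering here as a binary flag).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LLCInputs",
    "LLCResult",
    "T2_RATIO_THRESHOLD",
    "EGER_THRESHOLD",
    "t2_ratio",
    "ege_ratio",
    "llc_diagnosis",
    "evaluate_llc",
]

T2_RATIO_THRESHOLD = 1.9
EGER_THRESHOLD = 4.0


@dataclass(frozen=True)
class LLCInputs:
    """Signal intensities (arbitrary units) and flags feeding the LLC.

    ``si_myo_t2bb`` / ``si_sm_t2bb``: myocardial and skeletal-muscle mean
    signal on T2-weighted black-blood images.  The four pre/post values
    feed the EGE ratio.  ``visual_edema`` and ``lge_positive`` are visual
    reads supplied as flags.
    """

    si_myo_t2bb: float
    si_sm_t2bb: float
    si_myo_pre: float
    si_myo_post: float
    si_sm_pre: float
    si_sm_post: float
    visual_edema: bool = False
    lge_positive: bool = False


@dataclass(frozen=True)
class LLCResult:
    t2_ratio: float
    t2_ratio_positive: bool
    ege_ratio: float | None
    ege_undefined: bool
    ege_positive: bool
    edema_positive: bool
    lge_positive: bool
    n_positive: int
    diagnosis: bool


def t2_ratio(si_myo: float, si_sm: float) -> tuple[float, bool]:
    """Edema ratio; pathological when >= 1.9 (boundary inclusive)."""
    if si_sm <= 0:
        raise ValueError("skeletal-muscle signal must be > 0")
    ratio = si_myo / si_sm
    return ratio, ratio >= T2_RATIO_THRESHOLD


def ege_ratio(
    si_myo_pre: float, si_myo_post: float, si_sm_pre: float, si_sm_post: float
) -> tuple[float | None, bool]:
    """Early gadolinium enhancement ratio; pathological when >= 4.

    ``EGEr = rel. enhancement(myocardium) / rel. enhancement(muscle)``
    with relative enhancement ``(post - pre) / pre``.  When the muscle
    enhancement is zero or negative the ratio is undefined and flagged
    (returned as ``(None, False)``).
    """
    if si_myo_pre <= 0 or si_sm_pre <= 0:
        raise ValueError("pre-contrast intensities must be > 0")
    rel_myo = (si_myo_post - si_myo_pre) / si_myo_pre
    rel_sm = (si_sm_post - si_sm_pre) / si_sm_pre
    if rel_sm <= 0:
        return None, False
    ratio = rel_myo / rel_sm
    return ratio, ratio >= EGER_THRESHOLD


def llc_diagnosis(
    edema_positive: bool, ege_positive: bool, lge_positive: bool
) -> tuple[int, bool]:
    """Count positive criteria; diagnosis positive when >= 2 of 3."""
    count = int(bool(edema_positive)) + int(bool(ege_positive)) + int(bool(lge_positive))
    return count, count >= 2


def evaluate_llc(inputs: LLCInputs, edema_mode: str = "ratio_or_visual") -> LLCResult:
    """Full LLC evaluation from raw intensities and flags.

    ``edema_mode`` selects how the edema criterion combines the ratio and
    the visual read: ``"ratio_or_visual"`` (positive when either is, the
    default, since both assessments are performed) or ``"ratio_only"``.
    """
    if edema_mode not in ("ratio_or_visual", "ratio_only"):
        raise ValueError("edema_mode must be 'ratio_or_visual' or 'ratio_only'")
    ratio, ratio_pos = t2_ratio(inputs.si_myo_t2bb, inputs.si_sm_t2bb)
    eger, ege_pos = ege_ratio(
        inputs.si_myo_pre, inputs.si_myo_post, inputs.si_sm_pre, inputs.si_sm_post
    )
    edema = ratio_pos or (edema_mode == "ratio_or_visual" and inputs.visual_edema)
    count, diagnosis = llc_diagnosis(edema, ege_pos, inputs.lge_positive)
    return LLCResult(
        t2_ratio=ratio,
        t2_ratio_positive=ratio_pos,
        ege_ratio=eger,
        ege_undefined=eger is None,
        ege_positive=ege_pos,
        edema_positive=edema,
        lge_positive=inputs.lge_positive,
        n_positive=count,
        diagnosis=diagnosis,
    )
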