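"""Subject-level T2 statistics: meanT2, maxT2, meanSD, madSD.

maxT2 (the highest of the 16 segmental mean T2 values) and madSD (the mean
absolute deviation of the 16 segmental pixel-SDs about their mean) are
tissue-inhomogeneity statistics: focal inflammation raises T2 in a few
segments and inflates the spread of within-segment pixel-SDs, even when
the myocardium-wide mean T2 stays within the normal range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["T2Summary", "summarize", "group_comparison", "summarize_cohort"]


@dataclass(frozen=True)
class T2Summary:
    """The four subject-level T2 parameters (all in ms)."""

    mean_t2: float
    max_t2: float
    mean_sd: float
    mad_sd: float
    n_segments_used: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_t2": self.mean_t2,
            "max_t2": self.max_t2,
            "mean_sd": self.mean_sd,
            "mad_sd": self.mad_sd,
            "n_segments_used": self.n_segments_used,
        }


def summarize(segment_table: pd.DataFrame, center: str = "mean") -> T2Summary:
    """Reduce a 16-row segment table to the four subject-level statistics.

    Flagged (too-small) segments are excluded from all four statistics;
    the number of segments actually used is recorded.  ``center`` selects
    the madSD centring: ``"mean"`` (mean absolute deviation about the
    arithmetic mean, the default) or ``"median"``.
    """
    if segment_table.empty:
        raise ValueError("segment table is empty")
    usable = segment_table.loc[~segment_table["flagged"].astype(bool)]
    if usable.empty:
        raise ValueError("no unflagged segments")
    if len(usable) < 16:
        warnings.warn(
            f"only {len(usable)}/16 segments usable; statistics computed on those",
            stacklevel=2,
        )
    t2 = usable["mean_t2_ms"].to_numpy(dtype=float)
    sd = usable["pixel_sd_ms"].to_numpy(dtype=float)
    if center == "mean":
        mad = float(np.mean(np.abs(sd - sd.mean())))
    elif center == "median":
        mad = float(np.median(np.abs(sd - np.median(sd))))
    else:
        raise ValueError("center must be 'mean' or 'median'")
    return T2Summary(
        mean_t2=float(t2.mean()),
        max_t2=float(t2.max()),
        mean_sd=float(sd.mean()),
        mad_sd=mad,
        n_segments_used=int(len(usable)),
    )


def group_comparison(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    group_col: str = "group",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter descriptive statistics and control-vs-patient tests.

    For each parameter the test is chosen by a Shapiro-Wilk normality gate
    at ``alpha_normality`` on each group: Welch's unequal-variance t-test
    when both groups pass, otherwise the Wilcoxon rank-sum (Mann-Whitney)
    test.  Groups with fewer than three subjects skip testing (p = NaN).

    Returns one row per parameter with group means/SDs, the test used and
    the two-sided p-value, mirroring the usual "mean ± SD | p" cohort
    table layout.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = set(table[group_col].unique())
    if not {"control", "patient"} <= groups:
        raise ValueError("table must contain both 'control' and 'patient' subjects")
    if parameters is None:
        parameters = [
            c
            for c in table.columns
            if c not in (group_col, "subject_id") and pd.api.types.is_numeric_dtype(table[c])
        ]
    ctrl = table[table[group_col] == "control"]
    pat = table[table[group_col] == "patient"]
    rows = []
    for p in parameters:
        x = ctrl[p].dropna().to_numpy(dtype=float)
        y = pat[p].dropna().to_numpy(dtype=float)
        rec = {
            "parameter": p,
            "mean_control": x.mean() if x.size else np.nan,
            "sd_control": x.std(ddof=1) if x.size > 1 else np.nan,
            "mean_patient": y.mean() if y.size else np.nan,
            "sd_patient": y.std(ddof=1) if y.size > 1 else np.nan,
        }
        if x.size < 3 or y.size < 3:
            warnings.warn(f"{p}: fewer than 3 subjects in a group; test skipped", stacklevel=2)
            rec.update(test="none", p_value=np.nan)
        else:
            normal = all(
                np.ptp(g) == 0 or stats.shapiro(g).pvalue >= alpha_normality for g in (x, y)
            )
            if normal:
                res = stats.ttest_ind(x, y, equal_var=False)
                rec.update(test="welch_t", p_value=float(res.pvalue))
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                rec.update(test="wilcoxon_ranksum", p_value=float(res.pvalue))
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_cohort(
    summaries: list[T2Summary],
    labels: list[str],
) -> pd.DataFrame:
    """Group comparison of per-subject T2 summaries.

    ``labels`` holds 'control'/'patient' per subject, aligned with
    ``summaries``.
    """
    if len(summaries) != len(labels):
        raise ValueError("summaries and labels differ in length")
    df = pd.DataFrame([s.as_dict() for s in summaries])
    df["group"] = labels
    return group_comparison(df, ["mean_t2", "max_t2", "mean_sd", "mad_sd"])
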