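"""Study statistics: normality checks, one-way ANOVA, Bonferroni-corrected pairwise tests.

The quantitative metrics of a point-and-trace study (TRE, RMS TRE, ASSD, task
time, calibration time, NASA-TLX) are compared across guidance paradigms with
a Shapiro-Wilk normality check per group, a one-way ANOVA for a common mean,
and all pairwise two-sample comparisons with Bonferroni adjustment at a 0.05
family-wise threshold.  Pairwise comparisons use Welch's t (no equal-variance
assumption); repeat trials of the same user are averaged before group
comparison to avoid pseudo-replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateSampleError,
    InsufficientGroupsError,
    InvalidSubscaleError,
)
from .metrics import rms_from_mean_sd

__all__ = [
    "ALPHA",
    "ComparisonResult",
    "normality_check",
    "compare_paradigms",
    "nasa_tlx_raw",
    "summarize",
]

ALPHA = 0.05

_METRIC_COLUMNS = {
    "tre": "tre_mean_mm",
    "tre_rmse": "tre_rmse_mm",
    "assd": "assd_mm",
    "task_time": "task_time_s",
    "calibration_time": "calibration_time_s",
}


@dataclass
class ComparisonResult:
    metric: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, raw_p, adjusted_p, significant
    group_means: dict[str, float]

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


def normality_check(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Shapiro-Wilk W and p per group; flags groups with p below 0.05.

    Raises
    ------
    DegenerateSampleError
        For a constant group (the statistic is undefined).
    ValueError
        For a group with fewer than 3 observations.
    """
    rows = []
    for name, sample in groups.items():
        x = np.asarray(sample, dtype=float)
        if len(x) < 3:
            raise ValueError(f"group {name!r}: need at least 3 observations")
        if np.ptp(x) == 0:
            raise DegenerateSampleError(f"group {name!r} is constant")
        w, p = stats.shapiro(x)
        rows.append({"group": name, "n": len(x), "W": w, "p": p,
                     "non_normal": p < ALPHA})
    return pd.DataFrame(rows)


def _groups_from_table(
    table: pd.DataFrame, metric: str, mode: str
) -> dict[str, np.ndarray]:
    col = _METRIC_COLUMNS.get(metric, metric)
    groups: dict[str, np.ndarray] = {}
    for paradigm, sub in table.groupby("paradigm", sort=False):
        if mode == "pooled" and metric in ("tre", "tre_rmse"):
            vals = np.concatenate(
                [
                    np.array([float(v) for v in s.split(";") if v])
                    for s in sub["tre_samples_mm"]
                ]
            )
        else:
            # average repeats within user first (avoids pseudo-replication)
            vals = sub.groupby("user_id")[col].mean().to_numpy()
        vals = vals[np.isfinite(vals)]
        if len(vals):
            groups[paradigm] = vals
    return groups


def compare_paradigms(
    table: pd.DataFrame, metric: str = "tre", mode: str = "per_user"
) -> ComparisonResult:
    """Omnibus one-way ANOVA plus Bonferroni-adjusted pairwise Welch tests.

    ``mode="per_user"`` compares per-user trial means (repeats averaged);
    ``mode="pooled"`` pools per-point TRE samples across users.  Adjusted
    p-values are ``min(1, raw_p * m)`` with m the number of pairwise
    comparisons; a pair is flagged significant when the adjusted p is below
    0.05.

    Raises
    ------
    InsufficientGroupsError
        With fewer than two groups of at least two observations.
    """
    groups = {
        k: v for k, v in _groups_from_table(table, metric, mode).items() if len(v) >= 2
    }
    if len(groups) < 2:
        raise InsufficientGroupsError(f"{len(groups)} usable group(s) for {metric!r}")
    names = list(groups)
    samples = [groups[g] for g in names]
    if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
        f_stat, p_val = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = stats.f_oneway(*samples)
        if not np.isfinite(f_stat):  # identical constant groups
            f_stat, p_val = 0.0, 1.0
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
            raw = 1.0 if np.mean(groups[a]) == np.mean(groups[b]) else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        adj = min(1.0, raw * m)
        rows.append(
            {"group_a": a, "group_b": b, "raw_p": raw, "adjusted_p": adj,
             "significant": adj < ALPHA}
        )
    return ComparisonResult(
        metric=metric,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
        group_means={g: float(np.mean(groups[g])) for g in names},
    )


def nasa_tlx_raw(subscales: Sequence[float]) -> float:
    """Raw (unweighted) NASA-TLX: the mean of the six subscale scores.

    Raises
    ------
    InvalidSubscaleError
        If other than six values are given or any lies outside [0, 100].
    """
    x = np.asarray(subscales, dtype=float)
    if x.shape != (6,):
        raise InvalidSubscaleError(f"expected 6 subscales, got shape {x.shape}")
    if np.any(x < 0) or np.any(x > 100):
        raise InvalidSubscaleError("subscale scores must lie in [0, 100]")
    return float(np.mean(x))


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-paradigm summary: TRE mean +/- SD and RMS TRE, ASSD, times, raw TLX.

    TRE mean/SD pool the per-point samples across all trials of a paradigm
    (with the RMS TRE recomputed from the pooled mean and SD); ASSD and the
    times are summarized over trials.  Empty paradigms are omitted with a
    warning.  The output is invariant to the row order of the input.
    """
    if table.empty:
        raise ValueError("empty study table")
    tlx_cols = [c for c in table.columns if c.startswith("tlx_")]
    rows = []
    for paradigm in sorted(table["paradigm"].unique()):
        sub = table[table["paradigm"] == paradigm]
        pooled = (
            np.concatenate(
                [
                    np.array([float(v) for v in s.split(";") if v])
                    for s in sub["tre_samples_mm"]
                ]
            )
            if "tre_samples_mm" in sub
            else sub["tre_mean_mm"].to_numpy()
        )
        pooled = pooled[np.isfinite(pooled)]
        if len(pooled) == 0:
            warnings.warn(f"paradigm {paradigm!r} has no TRE samples; omitted")
            continue
        mean = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0
        assd = sub["assd_mm"].to_numpy()
        assd = assd[np.isfinite(assd)]
        row = {
            "paradigm": paradigm,
            "n_trials": len(sub),
            "tre_mean_mm": mean,
            "tre_sd_mm": sd,
            "tre_rmse_mm": rms_from_mean_sd(mean, sd),
            "assd_mm": float(np.mean(assd)) if len(assd) else float("nan"),
            "assd_sd_mm": float(np.std(assd, ddof=1)) if len(assd) > 1 else 0.0,
            "task_time_s": float(np.nanmean(sub["task_time_s"])),
            "calibration_time_s": float(np.nanmean(sub["calibration_time_s"]))
            if np.isfinite(sub["calibration_time_s"]).any() else float("nan"),
        }
        if tlx_cols:
            row["nasa_tlx_raw"] = float(
                np.mean([sub[c].mean() for c in tlx_cols])
            )
        rows.append(row)
    return pd.DataFrame(rows)
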