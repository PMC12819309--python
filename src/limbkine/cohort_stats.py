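"""Cohort-level aggregation: reference table, dispersion classes, dominance
tests and interval medians.

Per-trial parameter medians are pooled across all trials, separately for the
dominant and non-dominant leg, into median / IQR / %IQR rows (the normative
reference table). %IQR = 100 * IQR / median is the relative-dispersion
statistic, classified as small (<30%), moderate (30-59%), high (60-119%) or
very high (>=120%). Dominance differences are tested with a two-sided
Wilcoxon signed-rank test paired at the participant level.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

PCT_IQR_CLASSES = ("small", "moderate", "high", "very_high")
R2_CLASSES = ("negligible", "weak", "moderate", "strong", "very_strong")

#: switch from exact enumeration to the normal approximation above this n
WILCOXON_EXACT_MAX_N = 25


def classify_pct_iqr(pct: float) -> str:
    """Dispersion class of a %IQR value (bins at 30 / 60 / 120%)."""
    if pct < 0 or not np.isfinite(pct):
        raise ValueError(f"%IQR must be a finite non-negative value, got {pct!r}")
    if pct < 30.0:
        return "small"
    if pct < 60.0:
        return "moderate"
    if pct < 120.0:
        return "high"
    return "very_high"


def classify_r2(r2: float) -> str:
    """Strength class of a coefficient of determination.

    <0.10 negligible, 0.10-0.15 weak, 0.16-0.48 moderate, 0.49-0.79 strong,
    0.80-1.00 very strong.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"R^2 must be in [0, 1], got {r2!r}")
    if r2 < 0.10:
        return "negligible"
    if r2 < 0.16:
        return "weak"
    if r2 < 0.49:
        return "moderate"
    if r2 < 0.80:
        return "strong"
    return "very_strong"


def cohort_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Median, IQR and %IQR per (task, parameter, dominance) across trials.

    ``features`` is the long-format trial-feature table (columns
    participant_id, task, leg, dominant, trial_index, parameter, value).
    Quantiles use linear interpolation (type 7); values are not rounded —
    rounding belongs to report time. Empty groups are dropped with a
    warning.
    """
    rows = []
    for (task, parameter, dominant), grp in features.groupby(
            ["task", "parameter", "dominant"]):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        label = "dominant" if dominant else "non_dominant"
        if vals.size == 0:
            warnings.warn(
                f"no finite values for {task}/{parameter}/{label}; row omitted",
                stacklevel=2,
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        pct = 100.0 * iqr / med if med != 0 else np.nan
        rows.append({
            "task": task, "parameter": parameter, "dominance": label,
            "n_trials": int(vals.size), "median": med, "iqr": iqr,
            "pct_iqr": pct,
            "pct_iqr_class": classify_pct_iqr(pct) if np.isfinite(pct) and pct >= 0
            else "",
        })
    return pd.DataFrame(rows, columns=[
        "task", "parameter", "dominance", "n_trials", "median", "iqr",
        "pct_iqr", "pct_iqr_class",
    ])


@dataclasses.dataclass
class DominanceTest:
    """Two-sided Wilcoxon signed-rank result for one parameter."""

    parameter: str
    statistic: float  # W+ = sum of positive ranks
    p_value: float
    n_pairs: int
    n_used: int       # pairs remaining after dropping zero differences
    method: str       # "exact" | "normal_approx" | "undefined"

    @property
    def significant_at_0_05(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating the 2^n sign assignments via a
    convolution over doubled midranks (handles ties exactly)."""
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(round(2.0 * w_plus))
    p_ge = counts[w2:].sum()
    p_le = counts[:w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if var <= 0:
        return float("nan")
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(x, y) -> DominanceTest:
    """Paired two-sided Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped (Wilcoxon's rule) and ties are midranked.
    The exact permutation distribution is enumerated for n <= 25 usable
    pairs; the tie-corrected normal approximation with continuity correction
    is used above. All-zero differences leave the test undefined (p = NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    d = d[np.isfinite(d)]
    n_pairs = d.size
    d = d[d != 0.0]
    n_used = d.size
    if n_used == 0:
        return DominanceTest("", np.nan, np.nan, n_pairs, 0, "undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n_used <= WILCOXON_EXACT_MAX_N:
        p = _exact_signed_rank_p(w_plus, ranks)
        method = "exact"
    else:
        p = _approx_signed_rank_p(w_plus, ranks)
        method = "normal_approx"
    return DominanceTest("", w_plus, p, n_pairs, n_used, method)


def dominance_tests(features: pd.DataFrame, level: str = "participant"
                    ) -> pd.DataFrame:
    """Wilcoxon dominance tests for every (task, parameter).

    ``level="participant"`` (default) pairs each participant's median over
    their dominant-leg trials with the median over their non-dominant-leg
    trials; ``level="trial"`` pairs trial k dominant vs trial k
    non-dominant within participants.
    """
    if level not in ("participant", "trial"):
        raise ValueError(f"unknown pairing level {level!r}")
    keys = (["participant_id"] if level == "participant"
            else ["participant_id", "trial_index"])
    rows = []
    for (task, parameter), grp in features.groupby(["task", "parameter"]):
        wide = (grp.groupby(keys + ["dominant"])["value"].median()
                .unstack("dominant"))
        if True not in wide.columns or False not in wide.columns:
            continue
        wide = wide.dropna()
        if len(wide) < 2:
            continue
        res = wilcoxon_signed_rank(wide[True].to_numpy(), wide[False].to_numpy())
        rows.append({
            "task": task, "parameter": parameter, "statistic": res.statistic,
            "p_value": res.p_value, "n_pairs": res.n_pairs,
            "n_used": res.n_used, "method": res.method,
            "significant_at_0_05": res.significant_at_0_05,
        })
    return pd.DataFrame(rows, columns=[
        "task", "parameter", "statistic", "p_value", "n_pairs", "n_used",
        "method", "significant_at_0_05",
    ])


def interval_medians(
    cycle_features: pd.DataFrame,
    value_columns: tuple[str, ...] = ("angle", "frequency"),
    n_intervals: int = 4,
) -> pd.DataFrame:
    """Per-(trial, interval) parameter medians for the interval models.

    One row per trial x interval 1..n_intervals with the median of each
    value column over the cycles starting in that interval, plus the cycle
    count; intervals without cycles carry NaN.
    """
    keys = ["participant_id", "task", "leg", "dominant", "trial_index"]
    cf = cycle_features[cycle_features["interval_index"].between(1, n_intervals)]
    rows = []
    for meta, grp in cf.groupby(keys):
        for interval in range(1, n_intervals + 1):
            sub = grp[grp["interval_index"] == interval]
            row = dict(zip(keys, meta))
            row["interval"] = interval
            row["n_cycles"] = int(len(sub))
            for col in value_columns:
                vals = sub[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[col] = float(np.median(vals)) if vals.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["interval", "n_cycles",
                                              *value_columns])
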