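"""Gene-group summaries, WT/mutant ratios, resampling null and group tests.

The group-level statistic is the ratio of the wild-type group mean (or
median) index to the mutant group mean (or median) — a ratio of group
summaries, not a summary of per-gene ratios.  Its null distribution is
built by drawing random gene sets of the target-group size from the
nuclear control group and recording the same ratio per set; the empirical
p-value uses the add-one correction (1 + #{null >= observed}) / (1 + n_sets)
so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    """Five-number summary plus mean per sample, and WT/mut summary ratios."""

    group: str
    n: int
    stats_wt: dict[str, float]
    stats_mut: dict[str, float]
    ratio_mean: float
    ratio_median: float


@dataclass
class ResamplingResult:
    """Null distributions of WT/mut summary ratios over random gene sets."""

    source_group: str
    set_size: int
    n_sets: int
    null_ratio_means: np.ndarray
    null_ratio_medians: np.ndarray
    observed_group: str
    observed_ratio_mean: float
    observed_ratio_median: float
    max_null_mean: float
    max_null_median: float
    p_mean: float
    p_median: float
    seed: int
    fraction_both_above_one: Optional[float] = None


def _passing(table: pd.DataFrame, group: Optional[str] = None) -> pd.DataFrame:
    sel = table[table["pass"]]
    if group is not None:
        sel = sel[sel["group"] == group]
    return sel


def _five_number(values: np.ndarray) -> dict[str, float]:
    # quartiles by linear interpolation (the numpy default)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
    }


def summarize_group(table: pd.DataFrame, group: str) -> GroupSummary:
    """Box-plot summary of a group's indices and the WT/mut ratios.

    ``ratio_mean`` is mean(wt indices) / mean(mut indices) over the group's
    passing transcripts; ``ratio_median`` likewise for medians.
    """
    sel = _passing(table, group)
    if sel.empty:
        raise ValueError(f"group {group!r} has no passing transcripts")
    wt = sel["index_wt"].to_numpy(float)
    mut = sel["index_mut"].to_numpy(float)
    return GroupSummary(
        group=group,
        n=len(sel),
        stats_wt=_five_number(wt),
        stats_mut=_five_number(mut),
        ratio_mean=float(wt.mean() / mut.mean()),
        ratio_median=float(np.median(wt) / np.median(mut)),
    )


def _ratio_stats(wt: np.ndarray, mut: np.ndarray) -> tuple[float, float]:
    return float(wt.mean() / mut.mean()), float(np.median(wt) / np.median(mut))


def resample_null(
    table: pd.DataFrame,
    source_group: str = "control",
    set_size: int = 68,
    n_sets: int = 1000,
    seed: int = 0,
    observed_group: str = "exosome_target",
) -> ResamplingResult:
    """Null distribution of the WT/mut ratio over random control gene sets.

    ``n_sets`` sets of ``set_size`` genes are drawn without replacement
    (within a set; independently across sets) from the passing transcripts
    of ``source_group``; for each, the ratio of means and of medians
    between samples is recorded.  The observed statistic comes from the
    whole ``observed_group``.  Deterministic under ``seed``.
    """
    src = _passing(table, source_group)
    if len(src) < set_size:
        raise ValueError(
            f"source group {source_group!r} has {len(src)} passing transcripts, "
            f"fewer than set_size {set_size}"
        )
    obs = _passing(table, observed_group)
    if obs.empty:
        raise ValueError(f"observed group {observed_group!r} has no passing transcripts")
    wt = src["index_wt"].to_numpy(float)
    mut = src["index_mut"].to_numpy(float)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_sets)
    null_medians = np.empty(n_sets)
    for i in range(n_sets):
        pick = rng.choice(len(src), size=set_size, replace=False)
        null_means[i], null_medians[i] = _ratio_stats(wt[pick], mut[pick])
    obs_mean, obs_median = _ratio_stats(
        obs["index_wt"].to_numpy(float), obs["index_mut"].to_numpy(float)
    )
    p_mean = (1 + int((null_means >= obs_mean).sum())) / (1 + n_sets)
    p_median = (1 + int((null_medians >= obs_median).sum())) / (1 + n_sets)
    return ResamplingResult(
        source_group=source_group,
        set_size=set_size,
        n_sets=n_sets,
        null_ratio_means=null_means,
        null_ratio_medians=null_medians,
        observed_group=observed_group,
        observed_ratio_mean=obs_mean,
        observed_ratio_median=obs_median,
        max_null_mean=float(null_means.max()),
        max_null_median=float(null_medians.max()),
        p_mean=p_mean,
        p_median=p_median,
        seed=seed,
    )


def target_set_stability(
    table: pd.DataFrame,
    target_group: str = "exosome_target",
    subset_size: int = 10,
    n_sets: int = 59,
    seed: int = 0,
) -> ResamplingResult:
    """Stability of the target-group trend under small random subsets.

    Draws random subsets of the target group itself and additionally
    reports the fraction of subsets in which both the mean and the median
    WT/mut ratio exceed 1 (a consistently stabilised 3' end in the mutant).
    """
    result = resample_null(
        table,
        source_group=target_group,
        set_size=subset_size,
        n_sets=n_sets,
        seed=seed,
        observed_group=target_group,
    )
    both = (result.null_ratio_means > 1) & (result.null_ratio_medians > 1)
    result.fraction_both_above_one = float(both.mean())
    return result


SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_annotation(p: float) -> str:
    """Map a p-value to the conventional asterisk annotation."""
    for threshold, stars in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return stars
    return "n.s."


def compare_groups(
    table: pd.DataFrame, group_a: str, group_b: str, sample: str = "wt"
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test between two groups' index values.

    Chosen because index distributions are heavy-tailed; ties are handled
    by scipy's normal approximation with tie correction (exact enumeration
    for small tie-free samples).  Returns (U, p, annotation).
    """
    a = _passing(table, group_a)[f"index_{sample}"].to_numpy(float)
    b = _passing(table, group_b)[f"index_{sample}"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two passing index values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), significance_annotation(res.pvalue)


def resampling_frame(result: ResamplingResult) -> pd.DataFrame:
    """One row per resampled set, for TSV export."""
    return pd.DataFrame(
        {
            "set": np.arange(result.n_sets),
            "ratio_mean": result.null_ratio_means,
            "ratio_median": result.null_ratio_medians,
        }
    )


def resampling_report(result: ResamplingResult) -> dict:
    """JSON-serialisable summary of a resampling run."""
    report = {
        "source_group": result.source_group,
        "set_size": result.set_size,
        "n_sets": result.n_sets,
        "observed_group": result.observed_group,
        "observed_ratio_mean": result.observed_ratio_mean,
        "observed_ratio_median": result.observed_ratio_median,
        "max_null_mean": result.max_null_mean,
        "max_null_median": result.max_null_median,
        "p_mean": result.p_mean,
        "p_median": result.p_median,
        "seed": result.seed,
    }
    if result.fraction_both_above_one is not None:
        report["fraction_both_above_one"] = result.fraction_both_above_one
    return report
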