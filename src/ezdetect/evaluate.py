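"""Voxel-level metrics and cohort statistics for disruption detection.

Sensitivity, specificity and balanced accuracy are computed from the
voxel-level confusion counts restricted to the EZ volume of interest (the
classifier is only defined there):

    SEN = 100 * TP / (TP + FN)
    SPE = 100 * TN / (TN + FP)
    BAR = (SEN + SPE) / 2

For eyes without any true disruption SEN (and hence BAR) is undefined and
reported as NaN rather than an arbitrary value.  Cohort-level agreement
between detected and true disruption volumes uses Pearson correlation with
a Fisher-z confidence interval, Bland–Altman limits of agreement, and a
two-sample Student's t-test (pooled variance by default, Welch optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume_model import VoxelMask

__all__ = [
    "confusion",
    "sen_spe_bar",
    "bar",
    "cohort_stats",
    "correlation_with_ci",
    "bland_altman",
    "two_sample_ttest",
    "EyeReport",
]


@dataclass
class EyeReport:
    """Per-eye confusion counts, rates (%), and volumes (mm^3)."""

    eye_id: str
    group: str
    tp: int
    fp: int
    tn: int
    fn: int
    sen: float
    spe: float
    bar: float
    detected_volume_mm3: float
    truth_volume_mm3: float
    voi_volume_mm3: float


def confusion(pred: VoxelMask, truth: VoxelMask, voi: VoxelMask):
    """(TP, FP, TN, FN) counted over VOI voxels only."""
    if not (pred.shape == truth.shape == voi.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}, voi {voi.shape}"
        )
    v = voi.values
    p = pred.values & v
    t = truth.values & v
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int(v.sum()) - tp - fp - fn
    return tp, fp, tn, fn


def bar(sen: float, spe: float) -> float:
    """Balanced accuracy rate: the arithmetic mean of SEN and SPE."""
    return (sen + spe) / 2.0


def sen_spe_bar(tp: int, fp: int, tn: int, fn: int):
    """(SEN %, SPE %, BAR %); a metric with a zero denominator is NaN.

    SEN needs TP+FN > 0 (some true disruption), SPE needs TN+FP > 0.  Both
    zero is an error (empty VOI).
    """
    if tp + fn == 0 and tn + fp == 0:
        raise ValueError("no voxels to evaluate: both denominators are zero")
    sen = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
    spe = 100.0 * tn / (tn + fp) if tn + fp > 0 else math.nan
    b = bar(sen, spe) if not (math.isnan(sen) or math.isnan(spe)) else math.nan
    return sen, spe, b


def cohort_stats(values):
    """(mean, sample std, 95% CI) with the Student-t quantile.

    CI = mean ± t_{0.975, n-1} * std / sqrt(n).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return mean, sd, (mean - half, mean + half)


def correlation_with_ci(x, y):
    """Pearson r with Fisher-z 95% CI and two-sided p (t distribution)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / math.sqrt(x.size - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return r, (float(lo), float(hi)), p


def bland_altman(x, y):
    """Mean difference and 1.96-SD limits of agreement of paired measurements.

    Returns ``(mean_diff, (lower, upper), table)`` where ``table`` is the
    plotting frame (pair means vs differences, d = x - y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean_d - 1.96 * sd, mean_d + 1.96 * sd
    table = pd.DataFrame({"mean": (x + y) / 2.0, "difference": d})
    return mean_d, (lo, hi), table


def two_sample_ttest(a, b, welch: bool = False):
    """Two-sided two-sample Student's t-test (pooled variance unless welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bland_altman_plot(x, y, path):
    """Write a Bland–Altman scatter with limit lines to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_d, (lo, hi), table = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["mean"], table["difference"], s=18)
    for val, style in ((mean_d, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(val, linestyle=style, color="gray")
    ax.set_xlabel("mean of detected and truth volume (mm$^3$)")
    ax.set_ylabel("difference (mm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return mean_d, (lo, hi)
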