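"""Observer-agreement and group-comparison statistics.

Implements the agreement machinery used for paired observer measurements —
Pearson correlation, Bland-Altman bias with the 95% CI of the mean
difference and classical 95% limits of agreement — plus paired t-tests and
mean +/- SD group tables with Welch two-sample comparisons and star
annotations.  Between-group comparisons use Welch's unpaired t because the
groups are distinct animals; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import TracheaPatError

#: significance-star convention
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return "ns"


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement summary for paired measurements."""

    r: float  # Pearson correlation of the pairs
    bias: float  # mean(x - y)
    bias_ci_low: float  # 95% CI of the mean difference
    bias_ci_high: float
    loa_low: float  # bias -/+ 1.96 sd(d): 95% limits of agreement
    loa_high: float
    n: int


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    n: int
    degenerate: bool = False  # zero-variance differences with nonzero mean


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TracheaPatError("inputs must be equal-length 1-D sequences")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; requires n >= 3 and nonzero variance."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise TracheaPatError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise TracheaPatError("degenerate input: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(x, y) -> AgreementStats:
    """Bland-Altman agreement of paired measurements x and y.

    bias = mean(d) with d = x - y; the bias CI is the 95% t-interval of the
    mean difference; limits of agreement are bias +/- 1.96 sd(d).
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise TracheaPatError("Bland-Altman analysis requires n >= 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    try:
        r = pearson_r(x, y)
    except TracheaPatError:
        r = 1.0 if np.array_equal(x, y) else float("nan")
    return AgreementStats(r=r, bias=bias, bias_ci_low=bias - half,
                          bias_ci_high=bias + half, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd, n=n)


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test on x - y.

    Degenerate inputs: all-zero differences give p = 1 by convention;
    zero-variance nonzero differences set the ``degenerate`` flag (the
    statistic is undefined).
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise TracheaPatError("paired t-test requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(t=0.0, p=1.0, n=n)
        return PairedTResult(t=float("nan"), p=float("nan"), n=n, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, p=p, n=n)


def welch_t(x, y) -> tuple:
    """Welch's unpaired two-sample t-test (t, two-sided p)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_table(df: pd.DataFrame, metrics, group_col: str = "group",
                value_cols=None) -> "GroupComparison":
    """Per-group mean +/- SD and all pairwise Welch comparisons.

    ``df`` holds one row per specimen with a group label column and one
    column per metric.  Between-animal groups are compared with Welch's
    unpaired t and annotated with the star convention.
    """
    metrics = list(metrics)
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise TracheaPatError("need at least 2 groups")
    summaries = []
    for g in groups:
        sub = df[df[group_col] == g]
        if len(sub) < 2:
            raise TracheaPatError(f"group {g!r} has fewer than 2 specimens")
        for m in metrics:
            summaries.append({"group": g, "metric": m,
                              "mean": float(sub[m].mean()),
                              "sd": float(sub[m].std(ddof=1)),
                              "n": int(len(sub))})
    comparisons = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for m in metrics:
                a = df.loc[df[group_col] == ga, m].to_numpy(float)
                b = df.loc[df[group_col] == gb, m].to_numpy(float)
                if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
                    t, p = 0.0, 1.0
                else:
                    t, p = welch_t(a, b)
                comparisons.append({"group_a": ga, "group_b": gb, "metric": m,
                                    "t": t, "p": p, "stars": stars(p)})
    return GroupComparison(summary=pd.DataFrame(summaries),
                           comparisons=pd.DataFrame(comparisons))


@dataclass
class GroupComparison:
    """Mean +/- SD per group per metric plus pairwise Welch tests."""

    summary: pd.DataFrame  # group, metric, mean, sd, n
    comparisons: pd.DataFrame  # group_a, group_b, metric, t, p, stars


# ---------------------------------------------------------------------------
# presentation helpers (numbers above are the tested surface; plots are not)

def bland_altman_plot(x, y, ax=None, title=""):
    """Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    agr = bland_altman(x, y)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=12)
    ax.axhline(agr.bias, color="k")
    for v in (agr.bias_ci_low, agr.bias_ci_high):
        ax.axhline(v, color="k", linestyle=":")
    for v in (agr.loa_low, agr.loa_high):
        ax.axhline(v, color="r", linestyle="--")
    ax.set_xlabel("mean of observers")
    ax.set_ylabel("difference")
    ax.set_title(title)
    return ax


def group_bar_plot(comp: GroupComparison, metric: str, ax=None):
    """Mean +/- SD bars for one metric."""
    import matplotlib.pyplot as plt

    sub = comp.summary[comp.summary.metric == metric]
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(sub.group, sub["mean"], yerr=sub.sd, capsize=4)
    ax.set_ylabel(metric)
    return ax
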