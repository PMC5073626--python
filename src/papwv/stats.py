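"""Agreement and group-comparison statistics for paired PWV estimates.

Bland–Altman analysis with ±2SD limits of agreement, dependent-sample
t-tests, one-way ANOVA, and the reproducibility table that compares every
(method, site, sequence) configuration by the spread of its paired
replicate differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatisticsError(ValueError):
    """Raised for degenerate statistical inputs (n too small, zero variance)."""


#: Limits of agreement multiplier; 2·SD, not 1.96·SD.
DEFAULT_LOA_MULTIPLIER = 2.0

#: Pairing designs → the StudyRecord label that distinguishes pair members.
PAIRING_LABELS = {
    "within_scan": "replicate",
    "interscan": "visit",
    "intraobserver": "analysis",
    "interobserver": "observer",
}


@dataclass
class AgreementResult:
    """Bland–Altman summary of paired differences (measure1 − measure2)."""

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci95_mean_diff: tuple
    degenerate: bool = False  # zero-variance differences: CI not meaningful


@dataclass
class GroupStats:
    """Per-group descriptives (mean ± SEM convention)."""

    label: str
    n: int
    mean: float
    sem: float


@dataclass
class AnovaResult:
    groups: list
    f_statistic: float
    p_value: float


@dataclass
class PairedTTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_diff: float
    ci95: tuple


def bland_altman(measure1, measure2,
                 loa_multiplier: float = DEFAULT_LOA_MULTIPLIER) -> AgreementResult:
    """Bland–Altman agreement between two paired measurement series.

    Differences are ``measure1 − measure2``; limits of agreement are the
    mean difference ± ``loa_multiplier``·SD (sample SD, n−1); the 95% CI of
    the mean difference uses the t distribution with n−1 df.
    """
    x = np.asarray(measure1, dtype=float)
    y = np.asarray(measure2, dtype=float)
    if x.shape != y.shape:
        raise StatisticsError("paired series must have equal length")
    n = x.size
    if n < 2:
        raise StatisticsError("need at least 2 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        ci = (mean, mean)
    else:
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    return AgreementResult(
        n_pairs=n, mean_diff=mean, sd_diff=sd,
        loa_low=mean - loa_multiplier * sd, loa_high=mean + loa_multiplier * sd,
        ci95_mean_diff=ci, degenerate=degenerate,
    )


def paired_ttest(measure1, measure2) -> PairedTTestResult:
    """Two-sided dependent-sample t-test on paired measurements."""
    x = np.asarray(measure1, dtype=float)
    y = np.asarray(measure2, dtype=float)
    if x.shape != y.shape:
        raise StatisticsError("paired series must have equal length")
    n = x.size
    if n < 2:
        raise StatisticsError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise StatisticsError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    mean = float(np.mean(d))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PairedTTestResult(
        t_statistic=float(res.statistic), df=n - 1, p_value=float(res.pvalue),
        mean_diff=mean, ci95=(mean - half, mean + half),
    )


def group_anova(values_by_group: dict) -> AnovaResult:
    """One-way ANOVA across labelled groups (mean ± SEM per group).

    With exactly two groups F equals the square of the unpaired (pooled)
    t statistic.
    """
    if len(values_by_group) < 2:
        raise StatisticsError("need at least 2 groups")
    groups = []
    samples = []
    for label, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise StatisticsError(f"group {label!r} has n < 2")
        samples.append(v)
        groups.append(GroupStats(label=str(label), n=v.size,
                                 mean=float(v.mean()),
                                 sem=float(v.std(ddof=1) / np.sqrt(v.size))))
    if np.ptp(np.concatenate(samples)) == 0:
        # identical data everywhere: F = 0, p = 1 rather than scipy's nan
        return AnovaResult(groups=groups, f_statistic=0.0, p_value=1.0)
    f, p = sps.f_oneway(*samples)
    return AnovaResult(groups=groups, f_statistic=float(f), p_value=float(p))


def _paired_records(records, pairing: str, method: str, site: str,
                    sequence: str):
    """Valid estimate pairs for one configuration under a pairing design."""
    label = PAIRING_LABELS[pairing]
    by_subject: dict = {}
    for rec in records:
        if rec.site != site or rec.sequence != sequence:
            continue
        est = rec.estimate(method)
        if est is None:
            continue
        by_subject.setdefault(rec.subject, {})[getattr(rec, label)] = est
    first, second = [], []
    for ests in by_subject.values():
        a, b = ests.get(1), ests.get(2)
        # pairwise-complete deletion: both members must be valid
        if a is not None and b is not None and a.valid and b.valid:
            first.append(a.value)
            second.append(b.value)
    return np.asarray(first), np.asarray(second)


def variability_table(records, pairing: str = "within_scan",
                      loa_multiplier: float = DEFAULT_LOA_MULTIPLIER) -> pd.DataFrame:
    """Reproducibility of every (method, site, sequence) configuration.

    One Bland–Altman row per configuration with ≥2 complete valid pairs,
    sorted so the most precise configuration (smallest SD of paired
    differences) comes first; ``rank`` is that precision ranking.
    """
    if pairing not in PAIRING_LABELS:
        raise StatisticsError(
            f"unknown pairing {pairing!r}; expected one of {sorted(PAIRING_LABELS)}"
        )
    records = list(records)
    configs = sorted(
        {(e.method, r.site, r.sequence) for r in records for e in r.estimates}
    )
    rows = []
    for method, site, sequence in configs:
        m1, m2 = _paired_records(records, pairing, method, site, sequence)
        if m1.size < 2:
            continue
        res = bland_altman(m1, m2, loa_multiplier=loa_multiplier)
        rows.append({
            "method": method, "site": site, "sequence": sequence,
            "pairing": pairing, "n_pairs": res.n_pairs,
            "mean_diff": res.mean_diff, "sd_diff": res.sd_diff,
            "loa_low": res.loa_low, "loa_high": res.loa_high,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("sd_diff", kind="mergesort").reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    return table


def bland_altman_plot(measure1, measure2, ax=None,
                      loa_multiplier: float = DEFAULT_LOA_MULTIPLIER,
                      label: str = ""):
    """Standard Bland–Altman plot: pair means vs differences with LoA lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    res = bland_altman(measure1, measure2, loa_multiplier=loa_multiplier)
    x = (np.asarray(measure1, float) + np.asarray(measure2, float)) / 2.0
    d = np.asarray(measure1, float) - np.asarray(measure2, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, d, s=18, alpha=0.7)
    ax.axhline(res.mean_diff, color="k", lw=1)
    ax.axhline(res.loa_low, color="k", lw=1, ls="--")
    ax.axhline(res.loa_high, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of pair (m/s)")
    ax.set_ylabel("difference (m/s)")
    if label:
        ax.set_title(label)
    return ax, res
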