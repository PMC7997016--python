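"""Bland–Altman repeatability analysis.

Agreement between two repeat exams is summarized on percent differences
(100 x (second - first) / pairwise mean): mean difference, SD, limits of
agreement d_bar +/- 1.96 s with their 95% CIs (the classical variance
approximation var(LoA) ~ 3 s^2 / n), and the coefficient of
repeatability CoR = 1.96 sqrt(sum d_i^2 / n) on the absolute
differences, with a chi-square confidence interval for the
root-mean-square difference.  The percent-scale CoR is emitted
alongside; absolute units are primary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ValidationError

__all__ = ["RepeatPair", "BlandAltmanResult", "percent_difference", "bland_altman",
           "bland_altman_plot"]


@dataclass(frozen=True)
class RepeatPair:
    """One subject's two repeat measurements of one metric."""

    subject_id: str
    metric: str
    first: float
    second: float
    interval_days: float | None = None

    def __post_init__(self) -> None:
        if not (self.first > 0 and self.second > 0):
            raise ValidationError(
                f"{self.subject_id}/{self.metric}: values must be > 0 for "
                f"percent differences, got ({self.first}, {self.second})")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman summary for one metric."""

    metric: str
    n: int
    mean_diff_pct: float
    mean_diff_ci: tuple[float, float]
    sd_diff_pct: float
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    cor: float
    cor_ci: tuple[float, float]
    cor_pct: float
    cor_pct_ci: tuple[float, float]

    def __post_init__(self) -> None:
        assert self.loa_lower <= self.mean_diff_pct <= self.loa_upper
        assert self.cor >= 0


def percent_difference(pair: RepeatPair) -> float:
    """100 x (second - first) / mean(first, second)."""
    mean = 0.5 * (pair.first + pair.second)
    return 100.0 * (pair.second - pair.first) / mean


def bland_altman(pairs: Sequence[RepeatPair], loa_multiplier: float = 1.96,
                 ci_level: float = 0.95, direction: str = "second-first") -> BlandAltmanResult:
    """Bland–Altman analysis of a set of repeat pairs (one metric).

    Parameters
    ----------
    pairs
        One pair per subject; all must share the metric name.
    loa_multiplier
        Multiplier of the SD for the limits of agreement (1.96 = 95%).
    direction
        "second-first" (default) or "first-second" difference sign.
    """
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"Bland–Altman needs at least 3 pairs, got {n}")
    metrics = {p.metric for p in pairs}
    if len(metrics) > 1:
        raise ValidationError(f"pairs mix metrics: {sorted(metrics)}")
    sign = 1.0 if direction == "second-first" else -1.0

    pct = sign * np.array([percent_difference(p) for p in pairs])
    abs_diff = sign * np.array([p.second - p.first for p in pairs])

    d_bar = float(pct.mean())
    s = float(pct.std(ddof=1))
    alpha = 1.0 - ci_level
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    se_mean = s / np.sqrt(n)
    se_loa = s * np.sqrt(3.0 / n)

    loa_lo = d_bar - loa_multiplier * s
    loa_hi = d_bar + loa_multiplier * s

    cor, cor_ci = _cor_chi2(abs_diff, loa_multiplier, alpha)
    cor_pct, cor_pct_ci = _cor_chi2(pct, loa_multiplier, alpha)

    return BlandAltmanResult(
        metric=pairs[0].metric, n=n,
        mean_diff_pct=d_bar,
        mean_diff_ci=(d_bar - t_crit * se_mean, d_bar + t_crit * se_mean),
        sd_diff_pct=s,
        loa_lower=loa_lo, loa_lower_ci=(loa_lo - t_crit * se_loa, loa_lo + t_crit * se_loa),
        loa_upper=loa_hi, loa_upper_ci=(loa_hi - t_crit * se_loa, loa_hi + t_crit * se_loa),
        cor=cor, cor_ci=cor_ci, cor_pct=cor_pct, cor_pct_ci=cor_pct_ci,
    )


def _cor_chi2(diffs: np.ndarray, multiplier: float,
              alpha: float) -> tuple[float, tuple[float, float]]:
    """CoR = multiplier * sqrt(mean d^2) with a chi-square CI on sum d^2."""
    n = diffs.size
    ss = float(np.square(diffs).sum())
    cor = multiplier * np.sqrt(ss / n)
    if ss == 0.0:
        return 0.0, (0.0, 0.0)
    lo = multiplier * np.sqrt(ss / float(stats.chi2.ppf(1.0 - alpha / 2.0, n)))
    hi = multiplier * np.sqrt(ss / float(stats.chi2.ppf(alpha / 2.0, n)))
    return float(cor), (float(lo), float(hi))


def bland_altman_plot(pairs: Sequence[RepeatPair], result: BlandAltmanResult,
                      path: str | Path, direction: str = "second-first"):
    """Mean-vs-percent-difference plot with mean and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sign = 1.0 if direction == "second-first" else -1.0
    means = np.array([0.5 * (p.first + p.second) for p in pairs])
    pct = sign * np.array([percent_difference(p) for p in pairs])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, pct, s=18, alpha=0.8, edgecolor="none")
    for y, style, label in ((result.mean_diff_pct, "-", "mean"),
                            (result.loa_lower, "--", "-1.96 SD"),
                            (result.loa_upper, "--", "+1.96 SD")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(f"{label}: {y:.1f}%", xy=(1.0, y), xycoords=("axes fraction", "data"),
                    fontsize=7, ha="right", va="bottom")
    ax.set_xlabel(f"mean {result.metric}")
    ax.set_ylabel("percent difference (%)")
    ax.set_title(f"{result.metric} (n={result.n})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
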