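"""Nonparametric group comparisons and BMI-matched cohort selection.

Regional and sex/age contrasts use the Kruskal–Wallis omnibus test
followed by Conover–Iman pairwise comparisons on ranks (pooled-rank t
statistics with the (N - 1 - H)/(N - k) variance scaling and N - k
degrees of freedom), Holm-adjusted by default.  Cohort matching pairs
the sexes by nearest BMI within each age decade (greedy, with a
caliper), and balance is confirmed per decade with a Wilcoxon
signed-rank test plus a Hodges–Lehmann CI of the paired difference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

DECADES = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79")


def decade_label(age: float) -> str:
    """Closed decade bins: age 9 -> "0-9", age 10 -> "10-19"; capped at 70-79."""
    if age < 0:
        raise ValidationError("age must be >= 0")
    d = min(int(age) // 10, 7)
    return f"{d * 10}-{d * 10 + 9}"


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Conover–Iman

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with df = k - 1 and chi-square p.

    All observations identical is a defined degenerate case: H = 0, p = 1.
    """
    _check_groups(groups)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    k = len(groups)
    if np.ptp(pooled) == 0:
        return 0.0, k - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), k - 1, float(p)


@dataclass
class GroupComparisonResult:
    """Omnibus + pairwise comparison of k groups."""

    h: float
    df: int
    p: float
    pairwise: pd.DataFrame
    adjust: str

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_adj"] < 0.05]
        return list(zip(sig["group_a"], sig["group_b"]))


def conover_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Conover–Iman pairwise rank comparisons after a Kruskal–Wallis omnibus.

    Returns k(k-1)/2 rows with columns group_a, group_b, t, df, p_raw,
    p_adj and a ``significant`` flag at ``alpha`` on the adjusted p.
    """
    _check_groups(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels length must match the number of groups")

    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    mean_ranks = np.array([r.mean() for r in split])

    h, _, _ = kruskal_wallis(groups)
    s2 = (np.square(ranks).sum() - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    df = n_total - k
    scale = s2 * (n_total - 1 - h) / df if df > 0 else 0.0

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = scale * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
            p_raw = 2.0 * float(stats.t.sf(abs(t_stat), df))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "t": float(t_stat), "df": df, "p_raw": min(p_raw, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method=adjust)[1]
    table["significant"] = table["p_adj"] < alpha
    return table


def compare_groups(groups: Sequence[Sequence[float]], labels: Sequence[str],
                   alpha: float = 0.05, adjust: str = "holm") -> GroupComparisonResult:
    """Kruskal–Wallis omnibus followed by Conover–Iman pairwise comparisons."""
    h, df, p = kruskal_wallis(groups)
    pairwise = conover_pairwise(groups, labels, alpha=alpha, adjust=adjust)
    return GroupComparisonResult(h, df, p, pairwise, adjust)


def squared_ranks_variance_test(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Conover squared-ranks test for equality of variances (diagnostic).

    Ranks |x - group mean| over the pooled sample; the statistic is a
    chi-square on the group sums of squared ranks.
    """
    _check_groups(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    absdev = [np.abs(a - a.mean()) for a in arrays]
    pooled = np.concatenate(absdev)
    n_total = pooled.size
    r2 = np.square(stats.rankdata(pooled))
    split = np.split(r2, np.cumsum([a.size for a in arrays])[:-1])
    s_i = np.array([s.sum() for s in split])
    sizes = np.array([a.size for a in arrays])
    rbar = r2.mean()
    d2 = (np.square(r2).sum() - n_total * rbar**2) / (n_total - 1)
    if d2 <= 0:
        return 0.0, len(groups) - 1, 1.0
    t_stat = float(np.sum(np.square(s_i - sizes * rbar) / sizes) / d2)
    df = len(groups) - 1
    return t_stat, df, float(stats.chi2.sf(t_stat, df))


def _check_groups(groups: Sequence[Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(groups)}")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValidationError(f"group {i} has no observations")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank balance check with Hodges–Lehmann CI

@dataclass(frozen=True)
class WilcoxonCheck:
    """Signed-rank balance check of paired values."""

    n: int
    w: float
    p: float
    hl_estimate: float
    ci: tuple[float, float]


def wilcoxon_bmi_check(first: Sequence[float], second: Sequence[float],
                       ci_level: float = 0.95) -> WilcoxonCheck:
    """Wilcoxon signed-rank test of paired differences (first - second).

    Exact null distribution for n <= 25 (no ties/zeros), normal
    approximation otherwise; the CI of the median paired difference is
    the Hodges–Lehmann interval from the ordered Walsh averages.  Fewer
    than 5 pairs gives p = NaN with a warning; all-zero differences give
    p = 1 and CI = [0, 0] by convention.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    n = a.size
    diffs = a - b
    if n < 5:
        warnings.warn(f"only {n} pairs: signed-rank p reported as NaN", stacklevel=2)
        hl = float(np.median(_walsh_averages(diffs))) if n else float("nan")
        return WilcoxonCheck(n, float("nan"), float("nan"), hl, (float("nan"), float("nan")))
    if np.all(diffs == 0):
        return WilcoxonCheck(n, 0.0, 1.0, 0.0, (0.0, 0.0))
    method = "exact" if (n <= 25 and not _has_ties_or_zeros(diffs)) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
    walsh = np.sort(_walsh_averages(diffs))
    hl = float(np.median(walsh))
    k = _signrank_ci_rank(n, 1.0 - ci_level)
    m = walsh.size
    ci = (float(walsh[k - 1]), float(walsh[m - k]))
    return WilcoxonCheck(n, float(res.statistic), float(res.pvalue), hl, ci)


def _has_ties_or_zeros(diffs: np.ndarray) -> bool:
    nz = diffs[diffs != 0]
    return nz.size < diffs.size or np.unique(np.abs(nz)).size < nz.size


def _walsh_averages(diffs: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(diffs.size)
    return (diffs[i] + diffs[j]) / 2.0


def signed_rank_cdf(n: int) -> np.ndarray:
    """Exact null distribution of the signed-rank sum W+ for n pairs.

    Returns the CDF over W+ = 0..n(n+1)/2 by polynomial counting of the
    2^n sign patterns.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return np.cumsum(counts) / 2.0**n


def _signrank_ci_rank(n: int, alpha: float) -> int:
    """Walsh-average rank k for the (1 - alpha) Hodges–Lehmann interval."""
    if n <= 50:
        cdf = signed_rank_cdf(n)
        # largest k with P(W+ <= k - 1) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        k = int(np.floor(n * (n + 1) / 4.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    return max(k, 1)


# ---------------------------------------------------------------------------
# BMI-matched cohort selection

def match_cohort(
    candidates: pd.DataFrame,
    caliper: float = 2.0,
    seed: int = 0,
    bmi_col: str = "bmi",
) -> tuple[pd.DataFrame, Mapping[str, WilcoxonCheck]]:
    """Select an age- and BMI-matched cross-sex cohort.

    ``candidates`` needs one row per exam with columns ``sex`` ("M"/"F"),
    ``age`` and ``bmi``.  Within each age decade, male/female pairs are
    formed greedily by smallest BMI distance (ties broken reproducibly
    by seed), subject to the caliper; both members of every accepted
    pair are returned, so the output is balanced per decade.  The
    balance report runs the signed-rank check per decade.
    """
    required = {"sex", "age", bmi_col}
    if not required.issubset(candidates.columns):
        raise ValidationError(f"candidates table needs columns {sorted(required)}")
    df = candidates.copy()
    df["_decade"] = df["age"].map(decade_label)

    rng = np.random.default_rng(seed)
    kept_idx: list = []
    balance: dict[str, WilcoxonCheck] = {}
    for decade in DECADES:
        cell = df[df["_decade"] == decade]
        males = cell[cell["sex"] == "M"]
        females = cell[cell["sex"] == "F"]
        if cell.empty:
            continue
        if males.empty or females.empty:
            missing = "M" if males.empty else "F"
            raise ValidationError(f"decade cell {decade!r} has no sex-{missing} candidates")
        pairs = _greedy_pairs(males[bmi_col].to_numpy(), females[bmi_col].to_numpy(),
                              caliper, rng)
        if not pairs:
            raise ValidationError(f"decade cell {decade!r}: no BMI pair within "
                                  f"caliper {caliper}")
        m_idx = males.index.to_numpy()
        f_idx = females.index.to_numpy()
        m_bmi, f_bmi = [], []
        for mi, fi in pairs:
            kept_idx.extend([m_idx[mi], f_idx[fi]])
            m_bmi.append(males[bmi_col].to_numpy()[mi])
            f_bmi.append(females[bmi_col].to_numpy()[fi])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            balance[decade] = wilcoxon_bmi_check(m_bmi, f_bmi)
    matched = df.loc[kept_idx].drop(columns="_decade")
    return matched, balance


def _greedy_pairs(a: np.ndarray, b: np.ndarray, caliper: float,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Greedy nearest-distance cross pairing with a caliper."""
    dist = np.abs(a[:, None] - b[None, :])
    order = np.argsort(dist, axis=None, kind="stable")
    # reproducible tie-break: shuffle equal-distance runs
    flat = dist.ravel()[order]
    start = 0
    order = order.copy()
    for end in range(1, order.size + 1):
        if end == order.size or flat[end] != flat[start]:
            if end - start > 1:
                rng.shuffle(order[start:end])
            start = end
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for idx in order:
        i, j = divmod(int(idx), b.size)
        if used_a[i] or used_b[j] or dist[i, j] > caliper:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    return pairs
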