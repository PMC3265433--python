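"""Group comparison of the pi-P8 deviation across sleep surfaces.

Deviation angles measured on soft, firm and custom-made surfaces form
groups with heterogeneous variances, so alongside the classical one-way
ANOVA the Welch-modified F test is provided (heteroscedastic weighted-means
formulation), Levene's test for homogeneity of variances, and Tamhane's T2
post hoc procedure (pairwise Welch t tests with Welch-Satterthwaite degrees
of freedom and Sidak-adjusted significance levels).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample", "AnovaResult", "PairwiseResult", "GroupComparison",
    "GroupStatsError", "DegenerateVarianceError",
    "welch_anova", "classic_anova", "levene_test", "tamhane_t2",
    "compare_groups",
]


class GroupStatsError(ValueError):
    """Invalid group data for a variance-based test."""


class DegenerateVarianceError(GroupStatsError):
    """Zero within-group variance makes the test undefined."""


@dataclass(frozen=True)
class GroupSample:
    """One surface condition's deviation-angle sample (degrees)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) < 2:
            raise GroupStatsError(
                f"group {self.label!r} needs >= 2 observations")
        if not np.isfinite(vals).all():
            raise GroupStatsError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def var(self) -> float:
        return float(self.values.var(ddof=1))


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """Full comparison report: classical + Welch ANOVA, Levene, post hoc."""

    classic: AnovaResult
    welch: AnovaResult
    levene: AnovaResult
    pairwise: tuple[PairwiseResult, ...]
    alpha: float


def _check_groups(groups: Sequence[GroupSample], need_variance: bool = True,
                  ) -> list[GroupSample]:
    groups = list(groups)
    if len(groups) < 2:
        raise GroupStatsError("need at least 2 groups")
    if need_variance:
        for g in groups:
            if g.var <= 0:
                raise DegenerateVarianceError(
                    f"group {g.label!r} has zero within-group variance")
    return groups


def welch_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA (weighted-means formulation).

    With weights ``w_i = n_i / s_i^2``, the statistic is

        F_w = [sum w_i (xbar_i - xbar_w)^2 / (k - 1)]
              / [1 + 2 (k - 2) / (k^2 - 1) * A]

    where ``A = sum (1 - w_i / sum w)^2 / (n_i - 1)`` and the denominator
    degrees of freedom are ``df2 = (k^2 - 1) / (3 A)``; ``df1 = k - 1``.
    """
    groups = _check_groups(groups)
    k = len(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    v = np.array([g.var for g in groups])
    w = n / v
    sw = w.sum()
    mw = float((w * m).sum() / sw)
    a = float((((1.0 - w / sw) ** 2) / (n - 1.0)).sum())
    num = float((w * (m - mw) ** 2).sum() / (k - 1))
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1.0) * a
    fw = num / den
    df1 = k - 1.0
    df2 = (k ** 2 - 1.0) / (3.0 * a)
    p = float(sps.f.sf(fw, df1, df2))
    return AnovaResult(statistic=fw, df1=df1, df2=df2, p_value=p)


def classic_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Classical one-way ANOVA (between / within mean squares)."""
    groups = _check_groups(groups)
    k = len(groups)
    all_vals = np.concatenate([g.values for g in groups])
    grand = all_vals.mean()
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.mean) ** 2).sum() for g in groups)
    df1 = k - 1.0
    df2 = float(len(all_vals) - k)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult(statistic=float(f), df1=df1, df2=df2, p_value=p)


def levene_test(groups: Sequence[GroupSample], center: str = "mean",
                ) -> AnovaResult:
    """Levene's homogeneity-of-variance test.

    A one-way ANOVA on absolute deviations from each group's center
    (mean by default; median gives the Brown-Forsythe variant).
    """
    groups = _check_groups(groups, need_variance=False)
    if center not in ("mean", "median"):
        raise GroupStatsError("center must be 'mean' or 'median'")
    centered = []
    for g in groups:
        c = g.values.mean() if center == "mean" else np.median(g.values)
        centered.append(np.abs(g.values - c))
    k = len(centered)
    all_vals = np.concatenate(centered)
    grand = all_vals.mean()
    ss_between = sum(len(z) * (z.mean() - grand) ** 2 for z in centered)
    ss_within = sum(((z - z.mean()) ** 2).sum() for z in centered)
    df1 = k - 1.0
    df2 = float(len(all_vals) - k)
    if ss_within == 0:
        if np.all(all_vals == 0):
            raise DegenerateVarianceError("all absolute deviations are zero")
        if ss_between == 0:
            # Every deviation identical across groups: no dispersion signal.
            return AnovaResult(statistic=0.0, df1=df1, df2=df2, p_value=1.0)
        raise DegenerateVarianceError(
            "zero within-group spread of absolute deviations")
    w = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(statistic=float(w), df1=df1, df2=df2,
                       p_value=float(sps.f.sf(w, df1, df2)))


def _welch_t(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    """Two-sided Welch t test: (t, Welch-Satterthwaite df, p)."""
    va, vb = a.var / a.n, b.var / b.n
    se2 = va + vb
    if se2 <= 0:
        raise DegenerateVarianceError(
            f"pair ({a.label}, {b.label}) has zero variance")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def tamhane_t2(groups: Sequence[GroupSample], alpha: float = 0.05,
               ) -> tuple[PairwiseResult, ...]:
    """Tamhane's T2 post hoc: pairwise Welch t with Sidak adjustment.

    Each of the ``m = k (k - 1) / 2`` pairs is tested at the Sidak level
    ``alpha' = 1 - (1 - alpha)^(1/m)``; adjusted p values are reported as
    ``min(1, 1 - (1 - p)^m)``.
    """
    groups = _check_groups(groups)
    if not 0 < alpha < 1:
        raise GroupStatsError("alpha must lie in (0, 1)")
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    alpha_per_pair = 1.0 - (1.0 - alpha) ** (1.0 / m)
    out = []
    for i, j in pairs:
        t, df, p = _welch_t(groups[i], groups[j])
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        out.append(PairwiseResult(
            pair=(groups[i].label, groups[j].label),
            t=t, df=df, p_raw=p, p_adjusted=p_adj,
            significant=p < alpha_per_pair))
    return tuple(out)


def compare_groups(groups: Sequence[GroupSample], alpha: float = 0.05,
                   levene_center: str = "mean") -> GroupComparison:
    """Run the full comparison battery on the surface groups."""
    return GroupComparison(
        classic=classic_anova(groups),
        welch=welch_anova(groups),
        levene=levene_test(groups, center=levene_center),
        pairwise=tamhane_t2(groups, alpha=alpha),
        alpha=alpha,
    )
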