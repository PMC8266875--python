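"""Descriptive and nonparametric statistics for infusion measurements.

Covers the study's analysis stage: size-weighted overall means and pooled SDs
reconstructed from per-group (n, mean, sd) digests, Shapiro-Wilk normality
gating, exact/tie-corrected Mann-Whitney comparisons for the small brand
groups, and Spearman rank correlation in the presence of values censored
below a detection limit.

Censoring enters only through an explicit policy:

``substitute_dl``
    Use the detection limit itself as the value. Multiple censored entries
    become ties at the limit and are average-ranked (the default: with three
    censored waters it reproduces the published rank pattern).
``substitute_half_dl``
    Use half the detection limit; identical tie structure, different level.
``drop_censored``
    Remove the pair entirely.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import GroupSummary, InfusionDataset, Measurement
from .errors import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "CENSOR_POLICIES",
    "weighted_overall_mean",
    "pooled_sd",
    "normality_check",
    "compare_groups",
    "spearman_censored",
    "group_summaries",
    "pairwise_type_comparisons",
]

CENSOR_POLICIES = ("substitute_dl", "substitute_half_dl", "drop_censored")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p_value must lie in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    """Outcome of a rank-correlation analysis."""

    rho: float
    p_value: float
    n: int
    tie_policy: str
    censor_policy: str

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValidationError(f"|rho| must be <= 1, got {self.rho}")


def _groups_at(summaries: Iterable[GroupSummary], brew_time_min: float) -> list[GroupSummary]:
    groups = [g for g in summaries if g.brew_time_min == brew_time_min]
    if not groups:
        raise InsufficientDataError(f"no group summaries at brew time {brew_time_min} min")
    return groups


def weighted_overall_mean(summaries: Iterable[GroupSummary], brew_time_min: float) -> float:
    """Size-weighted grand mean over the groups at one brewing time:
    sum(n_i * mean_i) / sum(n_i), in mg/L."""
    groups = _groups_at(summaries, brew_time_min)
    total_n = sum(g.n_brands for g in groups)
    return sum(g.n_brands * g.mean_mg_per_L for g in groups) / total_n


def pooled_sd(summaries: Iterable[GroupSummary], brew_time_min: float) -> float:
    """Sample SD of the combined population reconstructed from group digests.

    With group sizes n_i, means m_i and sample SDs s_i (n-1 denominator), the
    total sum of squares about the grand mean decomposes as

        SS_within  = sum (n_i - 1) s_i^2
        SS_between = sum n_i (m_i - m_grand)^2

    and the pooled sample variance is (SS_within + SS_between) / (N - 1).
    """
    groups = _groups_at(summaries, brew_time_min)
    total_n = sum(g.n_brands for g in groups)
    if total_n < 2:
        raise InsufficientDataError(f"need a combined n of >= 2 to pool SDs, got {total_n}")
    grand = weighted_overall_mean(groups, brew_time_min)
    ss_within = sum((g.n_brands - 1) * g.sd_mg_per_L**2 for g in groups)
    ss_between = sum(g.n_brands * (g.mean_mg_per_L - grand) ** 2 for g in groups)
    return math.sqrt((ss_within + ss_between) / (total_n - 1))


def normality_check(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test; gate for choosing nonparametric methods."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InsufficientDataError("Shapiro-Wilk p-values are unreliable beyond n = 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError(
            "all values identical: normality is undefined for a zero-variance sample"
        )
    res = sps.shapiro(x)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="Shapiro-Wilk",
        n_per_group=(int(x.size),),
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    Uses the exact null distribution when the combined sample size is <= 20
    and there are no ties across the pooled data (the study's brand groups
    hold 2-5 products, well inside the exact regime); otherwise the normal
    approximation with tie correction. The reported U is the number of
    (a, b) pairs in which the a-value wins (so a = [1,2,3] vs b = [4,5,6]
    gives U = 0).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(
            statistic=float(x.size * y.size / 2),
            p_value=1.0,
            method="Mann-Whitney U, degenerate (all ties)",
            n_per_group=(int(x.size), int(y.size)),
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
        label = "Mann-Whitney U, exact"
    else:
        method = "asymptotic"
        label = "Mann-Whitney U, normal approximation (tie-corrected)"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=label,
        n_per_group=(int(x.size), int(y.size)),
    )


def _apply_censor_policy(
    x: Sequence[float | Measurement],
    y: Sequence[float],
    censor_policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    if censor_policy not in CENSOR_POLICIES:
        raise ValidationError(
            f"unknown censor_policy {censor_policy!r}; expected one of {CENSOR_POLICIES}"
        )
    xs: list[float] = []
    ys: list[float] = []
    for xi, yi in zip(x, y, strict=True):
        if isinstance(xi, Measurement) and xi.censored:
            if censor_policy == "drop_censored":
                continue
            value = xi.value if censor_policy == "substitute_dl" else xi.value / 2.0
        else:
            value = xi.value if isinstance(xi, Measurement) else float(xi)
        xs.append(value)
        ys.append(float(yi))
    return np.asarray(xs), np.asarray(ys)


def spearman_censored(
    x: Sequence[float | Measurement],
    y: Sequence[float],
    censor_policy: str = "substitute_dl",
) -> CorrelationResult:
    """Spearman rank correlation tolerating left-censored x-values.

    The chosen censor policy is applied first; rho is then the Pearson
    correlation of average ranks (substitution policies create ties at the
    substituted value, which average ranking handles). At least 3 pairs must
    survive the policy.
    """
    xs, ys = _apply_censor_policy(x, y, censor_policy)
    if xs.size < 3:
        raise InsufficientDataError(
            f"need >= 3 pairs after applying {censor_policy!r}, got {xs.size}"
        )
    res = sps.spearmanr(xs, ys)
    return CorrelationResult(
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(xs.size),
        tie_policy="average-rank",
        censor_policy=censor_policy,
    )


# ---------------------------------------------------------------------------
# Dataset-level helpers


def group_summaries(dataset: InfusionDataset, leaf_state: str = "uncrushed") -> list[GroupSummary]:
    """Summarize a long-format dataset into per (type, brew time) digests.

    Replicates are first averaged within each brand, then the summary carries
    the count, mean and sample SD across brand means — the construction used
    by the study's type-level table (replicate noise is much smaller than
    between-brand spread, so its SD reflects brand variation).
    """
    df = dataset.to_frame()
    df = df[(df["leaf_state"] == leaf_state) & (~df["censored"])]
    if df.empty:
        raise InsufficientDataError("dataset holds no uncensored records for that leaf state")
    brand_means = (
        df.groupby(["product_type", "brew_time_min", "brand_id"], sort=True)["fluoride_mg_per_L"]
        .mean()
        .reset_index()
    )
    out = []
    for (ptype, t), grp in brand_means.groupby(["product_type", "brew_time_min"], sort=True):
        vals = grp["fluoride_mg_per_L"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(GroupSummary(str(ptype), float(t), int(vals.size), float(np.mean(vals)), sd))
    return out


def pairwise_type_comparisons(
    dataset: InfusionDataset,
    brew_time_min: float = 5.0,
    leaf_state: str = "uncrushed",
    holm_adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of brand-mean fluoride between
    product types at one brewing time, as a tidy table.

    No multiplicity adjustment is applied by default (each comparison is
    reported marginally); ``holm_adjust`` adds a Holm-corrected column.
    """
    df = dataset.to_frame()
    df = df[
        (df["leaf_state"] == leaf_state)
        & (df["brew_time_min"] == brew_time_min)
        & (~df["censored"])
    ]
    brand_means = df.groupby(["product_type", "brand_id"])["fluoride_mg_per_L"].mean()
    rows = []
    types = sorted(brand_means.index.get_level_values("product_type").unique())
    for ta, tb in itertools.combinations(types, 2):
        res = compare_groups(
            brand_means.loc[ta].to_numpy(), brand_means.loc[tb].to_numpy()
        )
        rows.append(
            {
                "group_a": ta,
                "group_b": tb,
                "n_a": res.n_per_group[0],
                "n_b": res.n_per_group[1],
                "U": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    table = pd.DataFrame(rows)
    if holm_adjust and not table.empty:
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    return table
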