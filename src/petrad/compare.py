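"""Cross-condition comparison statistics for a paired feature cohort.

The study design is a complete block: every subject is measured under
every imaging condition, so condition effects are tested with a one-way
repeated-measures ANOVA that removes between-subject variance from the
error term:

    SS_total = SS_subjects + SS_conditions + SS_error
    F = [SS_cond / (k - 1)] / [SS_err / ((n - 1)(k - 1))]

with n subjects and k conditions; sphericity is assumed (no
Greenhouse–Geisser correction) and the report flags that assumption.
Pairwise agreement between conditions is quantified by Pearson's r and
by signed/absolute percent differences; post-hoc pairwise comparisons
are paired two-sided t-tests with a configurable multiplicity
adjustment (Bonferroni by default).

Input is a long-form table of (subject, condition, bins, feature,
value) records, one row per measurement, as written by the feature
extraction stage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "AnovaResult",
    "ComparisonResult",
    "DesignError",
    "DegenerateDataError",
    "UndefinedCorrelationError",
    "pearson_r",
    "percent_difference",
    "abs_percent_difference",
    "rm_anova",
    "rm_anova_from_matrix",
    "posthoc_pairwise",
    "stability_report",
]

REQUIRED_COLUMNS = ("subject", "condition", "bins", "feature", "value")


class DesignError(ValueError):
    """Raised when the block design is incomplete or too small."""


class DegenerateDataError(ValueError):
    """Raised when the ANOVA error term vanishes with a nonzero effect."""


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation input is constant or too short."""


@dataclass(frozen=True)
class CohortTable:
    """Long-form feature records across subjects x conditions x bins."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    @property
    def conditions(self) -> List[str]:
        return list(pd.unique(self.data["condition"]))

    @property
    def features(self) -> List[str]:
        return list(pd.unique(self.data["feature"]))

    @property
    def bin_configs(self) -> List[int]:
        return sorted(pd.unique(self.data["bins"]))

    def matrix(self, feature: str, bins: int) -> pd.DataFrame:
        """Wide n_subjects x k_conditions block for one (feature, bins).

        Raises :class:`DesignError` unless every subject has every
        condition exactly once.
        """
        sub = self.data[
            (self.data["feature"] == feature) & (self.data["bins"] == bins)
        ]
        if sub.empty:
            raise DesignError(f"no records for feature={feature!r}, bins={bins}")
        wide = sub.pivot_table(
            index="subject", columns="condition", values="value", aggfunc="count"
        )
        if wide.isna().any().any() or (wide != 1).any().any():
            raise DesignError(
                f"incomplete block design for feature={feature!r}, bins={bins}"
            )
        return sub.pivot(index="subject", columns="condition", values="value")[
            self.conditions
        ]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def percent_difference(a: float, b: float) -> float:
    """Signed percent change 100 (b - a) / a of b relative to baseline a."""
    if a == 0:
        raise ZeroDivisionError("percent difference undefined for baseline 0")
    return 100.0 * (b - a) / a


def abs_percent_difference(a: float, b: float) -> float:
    """|percent difference|, the quantity quoted in case reports."""
    return abs(percent_difference(a, b))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_condition: int
    df_error: int
    p: float
    ss_subjects: float
    ss_conditions: float
    ss_error: float
    sphericity_assumed: bool = True


def rm_anova_from_matrix(matrix: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n_subjects x k_conditions block."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions block")
    n, k = x.shape
    if n < 2 or k < 2:
        raise DesignError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_err = max(ss_total - ss_subj - ss_cond, 0.0)
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    tol = 1e-12 * max(ss_total, 1.0)
    if ss_cond <= tol:
        # no condition effect at all: F = 0 regardless of the error term
        return AnovaResult(0.0, df_cond, df_err, 1.0, ss_subj, ss_cond, ss_err)
    if ss_err <= tol:
        raise DegenerateDataError(
            "zero error sum of squares with a nonzero condition effect"
        )
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_cond, df_err))
    return AnovaResult(float(f), df_cond, df_err, p, ss_subj, ss_cond, ss_err)


def rm_anova(table: CohortTable, feature: str, bins: int) -> AnovaResult:
    """RM-ANOVA for one feature at one bin configuration."""
    return rm_anova_from_matrix(table.matrix(feature, bins).to_numpy())


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.ptp(diff) == 0 and diff[0] == 0:
        return 1.0  # identical conditions: no evidence of a difference
    return float(stats.ttest_rel(a, b).pvalue)


def _adjust(p_values: Dict[Tuple[str, str], float], method: str) -> Dict[Tuple[str, str], float]:
    if method == "none":
        return dict(p_values)
    m = len(p_values)
    if method == "bonferroni":
        return {pair: min(1.0, m * p) for pair, p in p_values.items()}
    if method == "holm":
        ordered = sorted(p_values.items(), key=lambda item: item[1])
        adjusted: Dict[Tuple[str, str], float] = {}
        running = 0.0
        for rank, (pair, p) in enumerate(ordered):
            running = max(running, (m - rank) * p)
            adjusted[pair] = min(1.0, running)
        return adjusted
    raise ValueError(f"unknown adjustment {method!r}")


def posthoc_pairwise(
    table: CohortTable, feature: str, bins: int, method: str = "bonferroni"
) -> Dict[Tuple[str, str], float]:
    """Adjusted p per condition pair from paired two-sided t-tests."""
    wide = table.matrix(feature, bins)
    raw: Dict[Tuple[str, str], float] = {}
    for a, b in itertools.combinations(wide.columns, 2):
        raw[(a, b)] = _paired_t_p(wide[a].to_numpy(), wide[b].to_numpy())
    return _adjust(raw, method)


@dataclass(frozen=True)
class ComparisonResult:
    """All comparison statistics for one (feature, bins) cell."""

    feature: str
    bins: int
    condition_means: Dict[str, float]
    condition_sds: Dict[str, float]
    pearson: Dict[Tuple[str, str], Tuple[float, float]]
    anova: Optional[AnovaResult]
    posthoc: Dict[Tuple[str, str], float]
    mean_abs_percent_difference: Dict[Tuple[str, str], float]
    error: Optional[str] = None

    @property
    def overall_abs_percent_difference(self) -> float:
        values = list(self.mean_abs_percent_difference.values())
        return float(np.mean(values)) if values else float("nan")


def _compare_cell(
    table: CohortTable, feature: str, bins: int, posthoc_method: str
) -> ComparisonResult:
    wide = table.matrix(feature, bins)
    means = {c: float(wide[c].mean()) for c in wide.columns}
    sds = {c: float(wide[c].std(ddof=1)) for c in wide.columns}
    pearson: Dict[Tuple[str, str], Tuple[float, float]] = {}
    pct: Dict[Tuple[str, str], float] = {}
    for a, b in itertools.combinations(wide.columns, 2):
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        try:
            pearson[(a, b)] = pearson_r(xa, xb)
        except UndefinedCorrelationError:
            pearson[(a, b)] = (float("nan"), float("nan"))
        with np.errstate(divide="ignore", invalid="ignore"):
            per_subject = [
                abs_percent_difference(va, vb)
                for va, vb in zip(xa, xb)
                if va != 0 and np.isfinite(va) and np.isfinite(vb)
            ]
        pct[(a, b)] = float(np.mean(per_subject)) if per_subject else float("nan")
    error: Optional[str] = None
    anova: Optional[AnovaResult] = None
    posthoc: Dict[Tuple[str, str], float] = {}
    try:
        anova = rm_anova(table, feature, bins)
        posthoc = posthoc_pairwise(table, feature, bins, posthoc_method)
    except (DegenerateDataError, DesignError) as exc:
        error = str(exc)
    return ComparisonResult(
        feature=feature,
        bins=bins,
        condition_means=means,
        condition_sds=sds,
        pearson=pearson,
        anova=anova,
        posthoc=posthoc,
        mean_abs_percent_difference=pct,
        error=error,
    )


def stability_report(
    table: CohortTable, posthoc_method: str = "bonferroni"
) -> Tuple[List[ComparisonResult], pd.DataFrame]:
    """Full comparison over every (feature, bins) cell, continuing past
    degenerate cells, plus a tidy summary frame.

    The summary has one row per (feature, bins) with per-condition
    mean +/- SD columns, the ANOVA F and p, the smallest adjusted
    post-hoc p, and the mean absolute percent difference across
    condition pairs, which also orders the stability ranking (smaller =
    more stable across scanners/protocols).
    """
    results: List[ComparisonResult] = []
    rows: List[Dict[str, object]] = []
    for bins in table.bin_configs:
        for feature in table.features:
            cell = _compare_cell(table, feature, int(bins), posthoc_method)
            results.append(cell)
            row: Dict[str, object] = {"feature": feature, "bins": int(bins)}
            for cond in table.conditions:
                row[f"mean_{cond}"] = cell.condition_means.get(cond)
                row[f"sd_{cond}"] = cell.condition_sds.get(cond)
            row["anova_F"] = cell.anova.F if cell.anova else float("nan")
            row["anova_p"] = cell.anova.p if cell.anova else float("nan")
            row["min_posthoc_p"] = (
                min(cell.posthoc.values()) if cell.posthoc else float("nan")
            )
            row["mean_abs_pct_diff"] = cell.overall_abs_percent_difference
            row["error"] = cell.error
            rows.append(row)
    summary = pd.DataFrame(rows)
    summary["stability_rank"] = (
        summary.groupby("bins")["mean_abs_pct_diff"].rank(method="min")
    )
    return results, summary
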