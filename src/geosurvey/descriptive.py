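"""Descriptive layer: prevalence tables, cumulative age-at-cutting,
baseline characteristic tables and unadjusted marginal odds ratios.

All computations are unweighted.  The report layer rounds (1 decimal for
percents); the computation layer keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic import SurveyDataset

__all__ = [
    "ContingencyTable",
    "ORResult",
    "prevalence_table",
    "cumulative_age_at_cutting",
    "unadjusted_or",
    "or_from_table",
    "baseline_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (exposed-cut, exposed-uncut, unexposed-cut, unexposed-uncut)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class ORResult:
    level: str
    reference: str
    or_: float
    ci_low: float | None
    ci_high: float | None
    alpha: float = 0.05
    corrected: bool = False  # Haldane-Anscombe 0.5 applied

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("interval must contain the point estimate")


def prevalence_table(dataset: SurveyDataset, by: list[str] | None = None) -> pd.DataFrame:
    """Unweighted prevalence: n, cut count and percent per group.

    With ``by=None`` a single overall row is returned.  Groups with no
    observations are omitted (they never appear under observed grouping).
    """
    df = dataset.df
    if len(df) == 0:
        raise ValueError("empty dataset")
    if by:
        missing = [c for c in by if c not in df.columns]
        if missing:
            raise KeyError(f"grouping fields not in dataset: {missing}")
        grp = df.groupby(by, observed=True)["outcome"]
        out = grp.agg(n="size", cut="sum").reset_index()
    else:
        out = pd.DataFrame({"n": [len(df)], "cut": [int(df["outcome"].sum())]})
    out["percent"] = 100.0 * out["cut"] / out["n"]
    return out


def cumulative_age_at_cutting(category_percents) -> list[float]:
    """Running sums of per-age-band percentages, rounded to 1 decimal for
    report output.  Monotone nondecreasing by construction."""
    vec = [float(v) for v in category_percents]
    if any(v < 0 for v in vec):
        raise ValueError("percentages must be non-negative")
    out: list[float] = []
    total = 0.0
    for v in vec:
        total += v
        out.append(round(total, 1))
    return out


def or_from_table(table: ContingencyTable, level: str, reference: str,
                  alpha: float = 0.05) -> ORResult:
    """Cross-product odds ratio with a Wald interval.

    Zero cells get the Haldane-Anscombe 0.5 continuity correction on all
    four cells, flagged via ``corrected``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = table.has_zero_cell
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - alpha / 2))
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return ORResult(level=level, reference=reference, or_=or_, ci_low=lo,
                    ci_high=hi, alpha=alpha, corrected=corrected)


def unadjusted_or(dataset: SurveyDataset, covariate: str, reference: str,
                  alpha: float = 0.05) -> list[ORResult]:
    """Marginal level-vs-reference odds ratios from 2x2 tables.

    For each non-reference level the 2x2 table against the reference level
    is formed; the cross-product ratio coincides with the coefficient
    exponential of a marginal logistic fit.  The reference level itself is
    reported as OR = 1 with no interval.
    """
    df = dataset.df
    if covariate not in df.columns:
        raise KeyError(f"covariate {covariate!r} not in dataset")
    levels = list(pd.unique(df[covariate].dropna()))
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} has a single level")
    ref_str = reference
    lev_map = {str(l): l for l in levels}
    if ref_str not in lev_map:
        raise ValueError(f"reference level {reference!r} not present in {covariate!r}")
    ref = lev_map[ref_str]
    y = df["outcome"].to_numpy()
    x = df[covariate]
    c = int(((x == ref) & (y == 1)).sum())
    d = int(((x == ref) & (y == 0)).sum())
    results = [ORResult(level=str(ref), reference=str(ref), or_=1.0,
                        ci_low=None, ci_high=None, alpha=alpha)]
    for lev in levels:
        if lev == ref:
            continue
        a = int(((x == lev) & (y == 1)).sum())
        b = int(((x == lev) & (y == 0)).sum())
        results.append(or_from_table(ContingencyTable(a, b, c, d),
                                     level=str(lev), reference=str(ref), alpha=alpha))
    return results


_CATEGORICAL_FIELDS = ("urban", "married", "education", "partner_education",
                       "wealth", "family_size", "ethnicity", "religion", "region")


def baseline_table(dataset: SurveyDataset) -> pd.DataFrame:
    """Characteristics table: means/SDs for ages, percents for categorical
    fields, overall and split by outcome.

    SD uses the n-1 denominator.  Returned long-format with columns
    ``variable, level, overall, cut, uncut, stat``.
    """
    df = dataset.df
    cut = df[df["outcome"] == 1]
    uncut = df[df["outcome"] == 0]
    rows: list[dict] = []

    def _mean_sd(sub: pd.DataFrame, col: str) -> tuple[float, float]:
        vals = pd.to_numeric(sub[col], errors="coerce").dropna()
        if len(vals) == 0:
            return float("nan"), float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        return float(vals.mean()), sd

    for col, label in (("age", "age_respondent"), ("partner_age", "age_partner")):
        for stat_idx, stat in enumerate(("mean", "sd")):
            rows.append({
                "variable": label, "level": stat, "stat": stat,
                "overall": _mean_sd(df, col)[stat_idx],
                "cut": _mean_sd(cut, col)[stat_idx],
                "uncut": _mean_sd(uncut, col)[stat_idx],
            })

    for col in _CATEGORICAL_FIELDS:
        if col not in df.columns:
            continue
        levels = list(pd.unique(df[col].dropna()))
        for lev in levels:
            row = {"variable": col, "level": str(lev), "stat": "percent"}
            for name, sub in (("overall", df), ("cut", cut), ("uncut", uncut)):
                denom = int(sub[col].notna().sum())
                row[name] = (100.0 * float((sub[col] == lev).sum()) / denom
                             if denom else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "level", "stat",
                                       "overall", "cut", "uncut"])
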