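"""Cohort summary statistics and group comparisons.

Summaries mirror the cohort table's final "mean values" row: numeric
columns are averaged over the non-invasive (non-bracketed) values and
printed to one decimal with round-half-up; invasive-component means are
reported separately from the ``*_inv`` columns.  Group comparisons use the
pooled-variance Student's t-test by default (Welch behind a flag); no
multiple-testing correction is applied by default (Holm behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import PHENOTYPES

NUMERIC_SUMMARY_COLUMNS = (
    "age_years",
    "size_cm",
    "CD3",
    "CD4",
    "CD8",
    "CD20",
    "PD1",
    "TPS",
    "CPS",
    "CD68",
    "CD163",
)

CATEGORICAL_SUMMARY_COLUMNS = ("gender", "duct_type", "site")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (not banker's rounding)."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def summarize_cohort(cases: pd.DataFrame) -> dict:
    """Cohort summary: per-column means (1 decimal, round-half-up) and
    categorical fractions (percent, 1 decimal).

    Returns ``{"means": {column: mean}, "invasive_means": {...},
    "fractions": {column: {level: percent}}}``.  Missing columns are
    reported as NA with a warning.
    """
    if len(cases) == 0:
        raise ValueError("empty cohort")
    means: dict[str, float] = {}
    for col in NUMERIC_SUMMARY_COLUMNS:
        if col not in cases.columns:
            warnings.warn(f"cohort table lacks column {col!r}", stacklevel=2)
            means[col] = float("nan")
            continue
        means[col] = round_half_up(float(cases[col].mean()))
    invasive_means: dict[str, float] = {}
    for col in cases.columns:
        if col.endswith("_inv") and cases[col].notna().any():
            invasive_means[col] = round_half_up(float(cases[col].mean()))
    fractions: dict[str, dict[str, float]] = {}
    for col in CATEGORICAL_SUMMARY_COLUMNS:
        if col not in cases.columns:
            continue
        counts = cases[col].value_counts()
        fractions[col] = {
            str(level): round_half_up(100.0 * n / len(cases))
            for level, n in counts.items()
        }
    return {"means": means, "invasive_means": invasive_means, "fractions": fractions}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(x, y, variant: str = "student") -> TTestResult:
    """Two-sided Student's t-test.

    ``variant="student"`` is the pooled-variance unpaired test (the
    default for independent groups, e.g. component comparisons);
    ``variant="welch"`` drops the equal-variance assumption;
    ``variant="paired"`` is the paired Student's t on per-case
    differences — the appropriate form for marker-vs-marker comparisons
    within the same cohort of cases.  Degenerate zero-variance equal-mean
    samples return t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2 if variant == "student" else float("nan")
        return TTestResult(0.0, df, 1.0)
    if variant == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
    elif variant == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    elif variant == "paired":
        if len(x) != len(y):
            raise ValueError("paired test needs samples of equal length")
        res = stats.ttest_rel(x, y)
        df = len(x) - 1
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def compare_marker_scores(
    cohort: pd.DataFrame, marker_a: str, marker_b: str
) -> TTestResult:
    """Within-cohort comparison of two marker score columns.

    Scores of different markers are measured on the same cases, so the
    paired Student's t is used; this form reproduces the published
    significance levels of the T-vs-B (CD3 vs CD20) and CD8-vs-CD4
    comparisons, which the unpaired pooled test does not for CD8 vs CD4.
    """
    return two_sample_t(cohort[marker_a], cohort[marker_b], variant="paired")


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def compare_components(
    neighborhoods: pd.DataFrame,
    components: tuple[str, str] = ("intraductal", "invasive"),
    phenotypes=PHENOTYPES,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-phenotype neighborhood-fraction comparison between components.

    For each phenotype, reports the mean per-neighborhood fraction in each
    component, their difference (second minus first), and the two-sided
    t-test p-value.  A component with fewer than 2 populated neighborhoods
    yields NA for its test.
    """
    a_name, b_name = components
    sub = neighborhoods[neighborhoods["populated"]]
    a = sub[sub["component"] == a_name]
    b = sub[sub["component"] == b_name]
    rows = []
    for p in phenotypes:
        col = f"frac_{p}"
        xa, xb = a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float)
        row = {
            "phenotype": p,
            f"mean_frac_{a_name}": float(np.mean(xa)) if len(xa) else float("nan"),
            f"mean_frac_{b_name}": float(np.mean(xb)) if len(xb) else float("nan"),
        }
        row["difference"] = row[f"mean_frac_{b_name}"] - row[f"mean_frac_{a_name}"]
        if len(xa) >= 2 and len(xb) >= 2:
            res = two_sample_t(xa, xb, variant=variant)
            row["t"], row["p"] = res.t, res.p
        else:
            row["t"], row["p"] = float("nan"), float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def immune_infiltration_summary(
    cells: pd.DataFrame,
    immune_phenotypes=("CD4", "CD8", "CD20", "CD68", "CD163"),
) -> pd.DataFrame:
    """Percent of each immune phenotype among all immune cells, overall
    (whole slide) and per component — the infiltration bar-chart data."""
    immune = cells[cells["phenotype"].isin(immune_phenotypes)]
    scopes = {"WSI": immune}
    for comp in pd.unique(immune["component"]):
        scopes[str(comp)] = immune[immune["component"] == comp]
    rows = []
    for scope, sub in scopes.items():
        n = len(sub)
        for p in immune_phenotypes:
            rows.append(
                {
                    "scope": scope,
                    "phenotype": p,
                    "percent_of_immune": (
                        100.0 * float((sub["phenotype"] == p).sum()) / n if n else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
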