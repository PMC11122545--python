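"""Baseline clinical-characteristics statistics for two response groups.

Implements the univariate tests behind a typical "Table of baseline
characteristics": Pearson chi-square (no continuity correction) on printed
contingency tables for categorical variables, and pooled two-sample t-tests
reconstructed from mean +/- SD summaries for continuous variables.  Ordinal
severity scores are summarized by medians, with an optional rank-sum test
labelled as an extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "SummaryStats",
    "TestResult",
    "chi_square_test",
    "pooled_t_from_summary",
    "build_baseline_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of categories (columns) per group (rows)."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / SD summary of one continuous variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must be in (0, 1]")


def chi_square_test(
    table: ContingencyTable | list | tuple | np.ndarray,
    correction: bool = False,
) -> TestResult:
    """Pearson chi-square test of independence, df = (r-1)(c-1).

    No Yates continuity correction by default (matching how published
    2x2 baseline comparisons are normally computed); pass
    ``correction=True`` to apply it.  A zero row or column total is fatal;
    expected counts below 1 trigger a warning since the asymptotic
    p-value is then unreliable.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(map(tuple, np.asarray(table, dtype=int))))
    arr = table.to_array()
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row/column marginal; test undefined")
    res = stats.chi2_contingency(arr, correction=correction)
    if (res.expected_freq < 1).any():
        warnings.warn(
            "expected counts < 1; chi-square approximation unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(max(res.pvalue, np.nextafter(0.0, 1.0))),
        method="pearson-chi-square" + ("-yates" if correction else ""),
    )


def pooled_t_from_summary(
    a: SummaryStats, b: SummaryStats, equal_var: bool = True
) -> TestResult:
    """Two-sided two-sample t-test from n/mean/SD summaries.

    Pooled (equal-variance) by default: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) /
    (n1+n2-2), t = (m1-m2) / (sp*sqrt(1/n1+1/n2)), df = n1+n2-2.  With both
    SDs zero the test degenerates: equal means give p = 1, unequal means
    the smallest positive p with a warning.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult(0.0, a.n + b.n - 2, 1.0, "pooled-t-degenerate")
        warnings.warn(
            "zero pooled SD with unequal means; p underflows",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestResult(
            np.inf, a.n + b.n - 2, np.nextafter(0.0, 1.0), "pooled-t-degenerate"
        )
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    df = a.n + b.n - 2 if equal_var else float(res.df) if hasattr(res, "df") else np.nan
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(max(res.pvalue, np.nextafter(0.0, 1.0))),
        method="pooled-t" if equal_var else "welch-t",
    )


def build_baseline_table(
    records: pd.DataFrame,
    group_col: str = "group",
    categorical: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
    ordinal: tuple[str, ...] = (),
    rank_test_ordinal: bool = False,
) -> pd.DataFrame:
    """Per-variable group summaries with the appropriate univariate test.

    ``records`` holds one row per sample.  Categorical variables get
    count (%) summaries and a chi-square test; continuous variables get
    mean (SD) and a pooled t-test; ordinal variables get medians and, only
    if ``rank_test_ordinal`` is set, a Wilcoxon rank-sum test flagged as an
    extension of the usual descriptive treatment.  Variables that are
    entirely missing are skipped with a warning.
    """
    groups = sorted(records[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []

    def block(g):
        return records.loc[records[group_col] == g]

    for var in categorical:
        sub = records[[group_col, var]].dropna()
        if sub.empty:
            warnings.warn(f"variable {var} all-missing; skipped", RuntimeWarning)
            continue
        counts = pd.crosstab(sub[group_col], sub[var]).reindex(groups)
        result = chi_square_test(counts.to_numpy())
        summary = {
            g: ", ".join(
                f"{cat}: {int(counts.at[g, cat])} "
                f"({100 * counts.at[g, cat] / counts.loc[g].sum():.1f}%)"
                for cat in counts.columns
            )
            for g in groups
        }
        rows.append(
            {
                "variable": var, "type": "categorical",
                ga: summary[ga], gb: summary[gb],
                "test": result.method, "p_value": result.p_value,
            }
        )
    for var in continuous:
        xa = block(ga)[var].dropna()
        xb = block(gb)[var].dropna()
        if xa.empty or xb.empty:
            warnings.warn(f"variable {var} all-missing; skipped", RuntimeWarning)
            continue
        sa = SummaryStats(len(xa), float(xa.mean()), float(xa.std(ddof=1)))
        sb = SummaryStats(len(xb), float(xb.mean()), float(xb.std(ddof=1)))
        result = pooled_t_from_summary(sa, sb)
        rows.append(
            {
                "variable": var, "type": "continuous",
                ga: f"{sa.mean:.2f} ({sa.sd:.2f})",
                gb: f"{sb.mean:.2f} ({sb.sd:.2f})",
                "test": result.method, "p_value": result.p_value,
            }
        )
    for var in ordinal:
        xa = block(ga)[var].dropna()
        xb = block(gb)[var].dropna()
        if xa.empty or xb.empty:
            warnings.warn(f"variable {var} all-missing; skipped", RuntimeWarning)
            continue
        entry = {
            "variable": var, "type": "ordinal",
            ga: f"median {xa.median():g}", gb: f"median {xb.median():g}",
            "test": "none (descriptive)", "p_value": np.nan,
        }
        if rank_test_ordinal:
            mwu = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            entry["test"] = "rank-sum (extension)"
            entry["p_value"] = float(mwu.pvalue)
        rows.append(entry)
    return pd.DataFrame(rows)
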