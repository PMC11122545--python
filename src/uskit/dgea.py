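"""Delta-delta-Ct differential expression for the two response groups.

Pipeline: within-sample normalization against the arithmetic mean of the
housekeeping Ct values (``2^-dCt``), group-mean fold change of non-responders
over responders (``2^-ddCt`` on group averages, the convention of the array
vendor's analysis software), signed fold-regulation display transform, and a
per-gene two-sample Student's t-test on the normalized expression values.

Candidate genes are flagged by two deliberately independent filters: nominal
significance (p < 0.05, no multiple-testing correction by default) and an
absolute fold-regulation threshold of 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NON_RESPONDER, RESPONDER, CtMatrix
from .panel import GenePanel

__all__ = [
    "NormalizedExpression",
    "normalize_delta_ct",
    "fold_change",
    "fold_regulation",
    "gene_t_test",
    "run_dgea",
    "select_candidates",
    "figure_scale_transform",
]

P_THRESHOLD = 0.05
FOLD_REGULATION_THRESHOLD = 2.0


@dataclass
class NormalizedExpression:
    """Per-sample relative expression ``2^-dCt`` for target genes only.

    ``values`` rows are samples, columns target genes; all entries are
    strictly positive.  ``groups`` carries the response label per sample.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not (self.values.to_numpy() > 0).all():
            raise ValueError("normalized expression must be strictly positive")
        if not self.groups.index.equals(self.values.index):
            raise ValueError("group labels do not match sample ids")

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values.loc[self.groups == group]


def normalize_delta_ct(ct: CtMatrix, panel: GenePanel) -> NormalizedExpression:
    """Within-sample normalization: ``2^-(Ct_gene - mean HK Ct)``.

    The housekeeping aggregate is the arithmetic mean of the sample's five
    reference-gene Ct values (equivalently the geometric mean of their
    expression).  A masked (undetermined) housekeeping well is fatal since
    the sample then has no valid reference.
    """
    ct.require_panel(panel)
    hk = list(panel.housekeeping_genes)
    hk_masked = ct.undetermined[hk]
    if hk_masked.to_numpy().any():
        sample, gene = next(
            (s, g) for s in hk_masked.index for g in hk if hk_masked.at[s, g]
        )
        raise ValueError(
            f"housekeeping gene {gene} undetermined in sample {sample}; "
            "cannot normalize"
        )
    mean_hk = ct.ct[hk].mean(axis=1)
    delta_ct = ct.ct[list(panel.target_genes)].sub(mean_hk, axis=0)
    return NormalizedExpression(values=np.exp2(-delta_ct), groups=ct.groups)


def fold_change(norm: NormalizedExpression) -> pd.Series:
    """Group-mean expression ratio, non-responders over responders."""
    mean_nr = norm.group_values(NON_RESPONDER).mean(axis=0)
    mean_r = norm.group_values(RESPONDER).mean(axis=0)
    if (mean_r <= 0).any() or (mean_nr <= 0).any():
        raise ArithmeticError("group mean expression must be positive")
    fc = mean_nr / mean_r
    fc.name = "fold_change"
    return fc


def fold_regulation(fc):
    """Signed display transform: ``fc`` if >= 1, else ``-1/fc``.

    Accepts a scalar or an array/Series; always has magnitude >= 1.
    """
    arr = np.asarray(fc, dtype=float)
    if (arr <= 0).any():
        raise ValueError("fold change must be positive")
    out = np.where(arr >= 1, arr, -1.0 / arr)
    if np.isscalar(fc) or arr.ndim == 0:
        return float(out)
    if isinstance(fc, pd.Series):
        return pd.Series(out, index=fc.index, name="fold_regulation")
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Vectorized two-sided two-sample t-test p-values per column.

    Degenerate zero-variance columns: equal means give p = 1, unequal means
    the smallest positive float (with a warning) — infinitely strong
    evidence in the noiseless limit.
    """
    with warnings.catch_warnings():
        # near-constant columns trip scipy's precision-loss warning; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float).copy()
    degenerate = ~np.isfinite(p) | (p <= 0)
    if degenerate.any():
        diff = a.mean(axis=0) - b.mean(axis=0)
        zero_diff = np.isclose(diff, 0.0)
        p[degenerate & zero_diff] = 1.0
        n_sep = int((degenerate & ~zero_diff).sum())
        if n_sep:
            warnings.warn(
                f"{n_sep} gene(s) with zero within-group variance and "
                "unequal means; reporting the smallest positive p-value",
                RuntimeWarning,
                stacklevel=3,
            )
        p[degenerate & ~zero_diff] = np.nextafter(0.0, 1.0)
    return p


def gene_t_test(
    norm: NormalizedExpression, gene: str, equal_var: bool = True
) -> float:
    """Two-sided Student's t-test on one gene's ``2^-dCt`` values.

    Pooled (equal-variance) by default; pass ``equal_var=False`` for Welch.
    """
    a = norm.group_values(NON_RESPONDER)[gene].to_numpy()[:, None]
    b = norm.group_values(RESPONDER)[gene].to_numpy()[:, None]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    return float(_pooled_t(a, b, equal_var)[0])


def run_dgea(
    ct: CtMatrix,
    panel: GenePanel,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full differential-expression table, one row per target gene.

    Columns: ``fold_change``, ``fold_regulation``, ``p_value``,
    ``significant`` (p < 0.05; on the BH-adjusted ``q_value`` when
    ``fdr=True``), ``dysregulated`` (|fold regulation| >= 2).  Panel gene
    order is preserved.
    """
    norm = normalize_delta_ct(ct, panel)
    fc = fold_change(norm)
    fr = fold_regulation(fc)
    a = norm.group_values(NON_RESPONDER).to_numpy()
    b = norm.group_values(RESPONDER).to_numpy()
    p = pd.Series(_pooled_t(a, b, equal_var), index=norm.values.columns, name="p_value")
    table = pd.DataFrame(
        {"fold_change": fc, "fold_regulation": fr, "p_value": p}
    ).loc[list(panel.target_genes)]
    if fdr:
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["q_value"] < P_THRESHOLD
    else:
        table["significant"] = table["p_value"] < P_THRESHOLD
    table["dysregulated"] = (
        table["fold_regulation"].abs() >= FOLD_REGULATION_THRESHOLD
    )
    table.index.name = "gene"
    return table


def select_candidates(
    table: pd.DataFrame, force_include: tuple[str, ...] = ()
) -> list[str]:
    """Genes passing the |fold regulation| >= 2 filter, plus forced extras.

    ``force_include`` mirrors the study's manual rescue of a significant
    but modestly regulated gene (TNFSF14); order follows the table (panel
    order), with forced genes in place.
    """
    missing = [g for g in force_include if g not in table.index]
    if missing:
        raise KeyError(f"force_include genes absent from table: {missing}")
    keep = set(table.index[table["dysregulated"]]) | set(force_include)
    return [g for g in table.index if g in keep]


def figure_scale_transform(delta_ct):
    """``log2(1/dCt)`` display transform used in some report figures.

    Kept for plotting parity only; dimensionally odd (the conventional
    log-scale expression measure is ``-dCt`` itself, i.e. ``log2`` of
    ``2^-dCt``) and never used in any computation here.
    """
    arr = np.asarray(delta_ct, dtype=float)
    if (arr <= 0).any():
        raise ValueError("transform defined only for positive dCt")
    return np.log2(1.0 / arr)
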