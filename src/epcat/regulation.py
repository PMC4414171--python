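"""Regulatory screens: treatment response, driver coexpression and peak support."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .epcat_grouping import Epcat, Gene

UP = "up"
DOWN = "down"
NS = "ns"

DEFAULT_FLANK_BP = 50_000
MIN_FOLD = 1.5
ALPHA = 0.05


@dataclass
class RegulationResult:
    epcat: str
    fold_change: float
    p_value: float
    q_value: float
    call: str


def epcat_expression(matrix: pd.DataFrame, tc_ids: Sequence[str]) -> pd.Series:
    """Per-sample mean of the member feature rows (log2 scale)."""
    missing = [t for t in tc_ids if t not in matrix.index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing}")
    return matrix.loc[list(tc_ids)].mean(axis=0)


def expressed_mask(values: pd.DataFrame, threshold: float) -> pd.Series:
    """Row-wise expression filter: mean over all samples above ``threshold``."""
    return values.mean(axis=1) > threshold


def androgen_response(
    expr_treated: pd.DataFrame,
    expr_untreated: pd.DataFrame,
    *,
    alpha: float = ALPHA,
    min_fold: float = MIN_FOLD,
) -> pd.DataFrame:
    """Welch's t-test per locus between conditions, BH-corrected.

    Fold change is ``2 ** (mean_treated - mean_untreated)``; a locus is
    called ``up`` when ``q < alpha`` and fold > ``min_fold``, ``down`` when
    ``q < alpha`` and fold < ``1 / min_fold``, else ``ns``.
    """
    if not expr_treated.index.equals(expr_untreated.index):
        raise ValueError("treated/untreated tables must index the same loci")
    if expr_treated.shape[1] < 2 or expr_untreated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    treated = expr_treated.to_numpy(dtype=float)
    untreated = expr_untreated.to_numpy(dtype=float)
    delta = treated.mean(axis=1) - untreated.mean(axis=1)
    fold = np.power(2.0, delta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(treated, untreated, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = fdr_bh(p)
    call = np.full(len(p), NS, dtype=object)
    call[(q < alpha) & (fold > min_fold)] = UP
    call[(q < alpha) & (fold < 1.0 / min_fold)] = DOWN
    return pd.DataFrame(
        {
            "fold_change": fold,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=expr_treated.index,
    )


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def coexpression(
    epcat_values: Sequence[float],
    driver_values: Sequence[float],
    *,
    min_rho: float = 0.5,
    alpha: float = ALPHA,
) -> tuple[float, float, bool]:
    """Spearman correlation with a driver; flag = (rho >= min_rho, p < alpha)."""
    x = np.asarray(epcat_values, dtype=float)
    y = np.asarray(driver_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 5:
        raise ValueError("coexpression needs n >= 5 paired samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return (float("nan"), float("nan"), False)
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    return (rho, p, bool(rho >= min_rho and p < alpha))


def peak_overlap(
    epcat: Epcat,
    peaks: Sequence[tuple[str, int, int]],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> bool:
    """True iff at least one peak intersects the locus span +/- ``flank_bp``."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    lo = max(epcat.start - flank_bp, 0)
    hi = epcat.end + flank_bp
    for chrom, start, end in peaks:
        if chrom == epcat.chrom and start < hi and lo < end:
            return True
    return False


def overlapping_gene_coexpression(
    epcat: Epcat,
    genes: Sequence[Gene],
    gene_expression: Mapping[str, pd.Series],
    epcat_values: pd.Series,
) -> dict[str, float]:
    """Spearman rho between the locus and each same-strand overlapping gene.

    ``gene_expression`` maps gene name to its per-sample representative
    expression (median over the gene's member features).
    """
    result: dict[str, float] = {}
    for gene in genes:
        if gene.chrom != epcat.chrom or gene.strand != epcat.strand:
            continue
        if not (gene.start < epcat.end and epcat.start < gene.end):
            continue
        values = gene_expression.get(gene.name)
        if values is None:
            continue
        aligned = values.loc[epcat_values.index]
        rho = stats.spearmanr(
            epcat_values.to_numpy(dtype=float), aligned.to_numpy(dtype=float)
        ).statistic
        result[gene.name] = float(rho)
    return result


def median_gene_expression(
    matrix: pd.DataFrame, gene_tc_ids: Mapping[str, Sequence[str]]
) -> dict[str, pd.Series]:
    """Median per-sample expression of each gene's member features."""
    return {
        gene: matrix.loc[list(ids)].median(axis=0)
        for gene, ids in gene_tc_ids.items()
    }
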