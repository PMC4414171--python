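"""Diagnostic panels: empirical AUC, AUC-maximized marker weighting,
binary in-situ score panels, Fisher's exact enrichment and positivity rates."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

CASE = "cancer"
CONTROL = "benign"


@dataclass
class PanelMetrics:
    sensitivity_by_marker: dict[str, float]
    combined_sensitivity: float
    specificity: float
    auc: float
    n_cases: int
    n_controls: int


def empirical_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: P(case score > control score) + half the tie mass."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("empirical_auc requires both classes present")
    ranks = stats.rankdata(scores)
    rank_sum = float(ranks[labels].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _normalize(w: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(w)
    return w if norm == 0 else w / norm


def optimize_panel_weights(
    train: pd.DataFrame,
    labels: Sequence[bool],
    seed: int | None = None,
    *,
    n_starts: int = 12,
) -> np.ndarray:
    """Linear panel weights maximizing the empirical training AUC.

    Multi-start Nelder-Mead over unit-norm weight vectors; both signed unit
    basis vectors are always evaluated, so the returned panel's training
    AUC is never below the best single-marker AUC.  Deterministic for a
    fixed seed.  ``train`` is samples x markers.
    """
    labels = np.asarray(labels, dtype=bool)
    X = train.to_numpy(dtype=float)
    n_samples, n_markers = X.shape
    if n_markers < 2:
        raise ValueError("optimize_panel_weights needs >= 2 markers")
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both classes")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: constant marker matrix")

    def neg_auc(w: np.ndarray) -> float:
        w = _normalize(np.asarray(w, dtype=float))
        if not np.any(w):
            return 0.0
        return -empirical_auc(X @ w, labels)

    candidates: list[np.ndarray] = []
    for k in range(n_markers):
        for sign in (1.0, -1.0):
            e = np.zeros(n_markers)
            e[k] = sign
            candidates.append(e)
    candidates.append(_normalize(np.ones(n_markers)))
    rng = np.random.default_rng(seed)
    starts = list(candidates) + [
        _normalize(rng.standard_normal(n_markers)) for _ in range(n_starts)
    ]
    best_w, best_val = None, np.inf
    for w0 in starts:
        res = optimize.minimize(
            neg_auc, w0, method="Nelder-Mead",
            options={"maxiter": 200 * n_markers, "xatol": 1e-4, "fatol": 1e-6},
        )
        for cand in (w0, _normalize(res.x)):
            val = neg_auc(cand)
            if val < best_val - 1e-12:
                best_val, best_w = val, np.asarray(cand, dtype=float)
    assert best_w is not None
    return _normalize(best_w)


def apply_panel(
    weights: Sequence[float], validation: pd.DataFrame, labels: Sequence[bool]
) -> float:
    """Empirical AUC of the fixed weighted score on held-out samples."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != validation.shape[1]:
        raise ValueError(
            f"weight/marker mismatch: {len(weights)} weights for "
            f"{validation.shape[1]} markers"
        )
    scores = validation.to_numpy(dtype=float) @ weights
    return empirical_auc(scores, labels)


def binary_panel_metrics(
    table: pd.DataFrame,
    markers: Sequence[str],
    case_categories: Sequence[str],
    control_categories: Sequence[str],
    *,
    category_column: str = "category",
) -> PanelMetrics:
    """Binary staining-panel metrics from integer score columns.

    Positivity is score > 0; the combined call is positive iff any marker
    is positive.  Sensitivity is computed on the case categories,
    specificity on the control categories, and the AUC is the Mann-Whitney
    AUC of the binary combined score.
    """
    if not list(case_categories) or not list(control_categories):
        raise ValueError("case and control category sets must be non-empty")
    for m in markers:
        if (table[m] < 0).any():
            raise ValueError(f"marker {m!r} has negative scores")
    cases = table[table[category_column].isin(case_categories)]
    controls = table[table[category_column].isin(control_categories)]
    if cases.empty or controls.empty:
        raise ValueError("no rows in case or control categories")
    positive_cases = (cases[list(markers)] > 0).any(axis=1)
    positive_controls = (controls[list(markers)] > 0).any(axis=1)
    sens_by_marker = {
        m: float((cases[m] > 0).mean()) for m in markers
    }
    combined_sens = float(positive_cases.mean())
    specificity = float((~positive_controls).mean())
    scores = np.concatenate(
        [positive_cases.to_numpy(dtype=float), positive_controls.to_numpy(float)]
    )
    labels = np.concatenate(
        [np.ones(len(cases), dtype=bool), np.zeros(len(controls), dtype=bool)]
    )
    return PanelMetrics(
        sensitivity_by_marker=sens_by_marker,
        combined_sensitivity=combined_sens,
        specificity=specificity,
        auc=empirical_auc(scores, labels),
        n_cases=len(cases),
        n_controls=len(controls),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p (point-probability / minlike method)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def positivity_rate(n_positive: int, n_total: int, decimals: int = 1) -> float:
    """Percentage ``100 * n_positive / n_total`` rounded half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    pct = Decimal(100) * Decimal(n_positive) / Decimal(n_total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
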