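"""Prognostic analyses: k=2 medoid dichotomization, label-permutation
association p-values, BH correction and Kaplan-Meier/log-rank testing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .regulation import fdr_bh  # noqa: F401  (re-exported: shared procedure)

HIGH = "high"
LOW = "low"

N_ITER = 10_000


@dataclass
class PrognosticResult:
    epcat: str
    endpoint: str
    n_high: int
    n_low: int
    observed_positive_high: int
    permutation_p: float
    q_value: float | None = None
    logrank_p: float | None = None


def pam_two_groups(values: pd.Series) -> pd.Series:
    """Partition samples into high/low by exact k=2 medoid search.

    Dissimilarity is the absolute difference on the one-dimensional values;
    all medoid pairs are scanned and cost ties break toward the
    lexicographically smaller medoid-value pair.  The group with the larger
    medoid value is labelled ``"high"``.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 4:
        raise ValueError("pam_two_groups needs n >= 4 samples")
    x = values.to_numpy()
    if np.all(x == x[0]):
        raise ValueError("all values equal: no two-group partition exists")
    candidates = np.unique(x)
    # exact search over all medoid pairs; distances to candidates precomputed
    dist = np.abs(x[:, None] - candidates[None, :])
    best: tuple[float, float, float] | None = None  # (cost, medoid_lo, medoid_hi)
    for i in range(len(candidates) - 1):
        costs = np.minimum(dist[:, i : i + 1], dist[:, i + 1 :]).sum(axis=0)
        j_rel = int(np.argmin(costs))  # first minimum -> smallest second medoid
        key = (float(costs[j_rel]), float(candidates[i]),
               float(candidates[i + 1 + j_rel]))
        if best is None or key < best:
            best = key
    assert best is not None
    _, m_lo, m_hi = best
    # ties in point-to-medoid distance assign to the lower-valued medoid
    to_high = np.abs(x - m_hi) < np.abs(x - m_lo)
    labels = np.where(to_high, HIGH, LOW)
    return pd.Series(labels, index=values.index)


def bootstrap_association(
    group_labels: pd.Series,
    endpoint_events: pd.Series,
    n_iter: int = N_ITER,
    seed: int | None = None,
) -> tuple[int, float]:
    """Permutation p-value for enrichment of events in the high group.

    The observed statistic is the number of event-positive patients in the
    high group.  Each iteration permutes the event labels and reassigns
    them to groups of the original sizes; ``p`` is the fraction of
    iterations with a statistic >= the observed one (so p > 0 always).
    Returns ``(observed, p)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels = pd.Series(group_labels)
    events = pd.Series(endpoint_events).loc[labels.index].to_numpy(dtype=int)
    if not set(np.unique(events)).issubset({0, 1}):
        raise ValueError("events must be 0/1 indicators")
    is_high = (labels == HIGH).to_numpy()
    n_high = int(is_high.sum())
    observed = int(events[is_high].sum())
    rng = np.random.default_rng(seed)
    n = len(events)
    keys = rng.random((n_iter, n))
    idx = np.argsort(keys, axis=1)[:, :n_high]
    stat = events[idx].sum(axis=1)
    p = float((stat >= observed).sum()) / n_iter
    return observed, p


def km_logrank(
    times: pd.Series,
    events: pd.Series,
    groups: pd.Series,
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per group and the two-group log-rank p-value.

    With zero events in both groups the log-rank statistic is undefined;
    the convention here is p = 1 with a warning.  Curves are returned as
    tables of (time, at_risk, survival).
    """
    times = pd.Series(times, dtype=float)
    events = pd.Series(events).loc[times.index].astype(int)
    groups = pd.Series(groups).loc[times.index]
    if (times <= 0).any():
        raise ValueError("times must be positive")
    curves: dict[str, pd.DataFrame] = {}
    for name in sorted(groups.unique()):
        mask = groups == name
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} has zero members")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        table = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            }
        )
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError("km_logrank expects exactly two groups")
    if int(events.sum()) == 0:
        warnings.warn("no events in either group: log-rank undefined, p = 1",
                      stacklevel=2)
        return curves, 1.0
    mask = groups == names[0]
    res = logrank_test(
        times[mask], times[~mask], events[mask], events[~mask]
    )
    p = float(res.p_value)
    if not np.isfinite(p):
        warnings.warn("degenerate log-rank statistic, reporting p = 1",
                      stacklevel=2)
        p = 1.0
    return curves, p
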