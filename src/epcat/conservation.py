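"""Windowed conservation scoring of locus exons and control comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

WINDOW_BP = 50
MIN_TAIL_BP = 10


@dataclass
class ConservationTrack:
    """Per-base scores stored as sorted half-open scored intervals per
    chromosome; bases not covered by any interval are missing (NaN)."""

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, score: float) -> None:
        if start >= end:
            raise ValueError(f"track interval start >= end at {chrom}:{start}")
        self.intervals.setdefault(chrom, []).append((start, end, score))

    def sort(self) -> None:
        for chrom in self.intervals:
            self.intervals[chrom].sort()

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered bases are NaN."""
        if start >= end:
            raise ValueError("query start must be < end")
        out = np.full(end - start, np.nan)
        for iv_start, iv_end, score in self.intervals.get(chrom, ()):
            lo = max(iv_start, start)
            hi = min(iv_end, end)
            if lo < hi:
                out[lo - start : hi - start] = score
        return out


def tile_windows(
    n_bases: int, window_bp: int = WINDOW_BP, min_tail_bp: int = MIN_TAIL_BP
) -> list[tuple[int, int]]:
    """Non-overlapping window offsets over ``n_bases`` concatenated bases.

    The final short window stands alone when it has at least
    ``min_tail_bp`` bases, otherwise it merges into the previous window; a
    sequence shorter than one window is a single window regardless.
    """
    if n_bases <= 0:
        raise ValueError("n_bases must be positive")
    edges = list(range(0, n_bases, window_bp))
    windows = [(lo, min(lo + window_bp, n_bases)) for lo in edges]
    if len(windows) > 1:
        last_lo, last_hi = windows[-1]
        if last_hi - last_lo < min_tail_bp:
            prev_lo, _ = windows[-2]
            windows = windows[:-2] + [(prev_lo, last_hi)]
    return windows


def locus_conservation_score(
    exons: Sequence[tuple[str, int, int]],
    track: ConservationTrack,
    window_bp: int = WINDOW_BP,
    min_tail_bp: int = MIN_TAIL_BP,
) -> float:
    """Representative conservation score of a locus.

    Exon bases are concatenated in genomic order, tiled into
    non-overlapping ``window_bp`` windows, and the maximum window mean is
    returned.  Missing bases are excluded from window means; windows with
    no covered base are skipped.
    """
    if not exons:
        raise ValueError("empty exon set")
    ordered = sorted(exons, key=lambda e: (e[0], e[1], e[2]))
    for (c1, s1, e1), (c2, s2, e2) in zip(ordered, ordered[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError("exons must be non-overlapping")
    per_base = np.concatenate(
        [track.scores(chrom, start, end) for chrom, start, end in ordered]
    )
    best = -np.inf
    for lo, hi in tile_windows(len(per_base), window_bp, min_tail_bp):
        window = per_base[lo:hi]
        if np.all(np.isnan(window)):
            continue
        best = max(best, float(np.nanmean(window)))
    if best == -np.inf:
        raise ValueError("no covered bases in any window")
    return best


def compare_to_controls(
    locus_scores: Sequence[float],
    coding_scores: Sequence[float],
    repeat_scores: Sequence[float],
) -> dict[str, float]:
    """Directional rank-sum comparisons of locus scores against controls.

    Returns group medians plus one-sided Wilcoxon rank-sum p-values in
    both directions for locus-vs-coding and locus-vs-repeat.
    """
    groups = {
        "locus": np.asarray(locus_scores, dtype=float),
        "coding": np.asarray(coding_scores, dtype=float),
        "repeat": np.asarray(repeat_scores, dtype=float),
    }
    for name, values in groups.items():
        if values.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    locus = groups["locus"]
    out = {f"median_{name}": float(np.median(v)) for name, v in groups.items()}
    for other in ("coding", "repeat"):
        for direction, alt in (("lt", "less"), ("gt", "greater")):
            p = stats.mannwhitneyu(
                locus, groups[other], alternative=alt
            ).pvalue
            out[f"p_locus_{direction}_{other}"] = float(p)
    return out
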