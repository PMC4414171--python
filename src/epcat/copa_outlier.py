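"""COPA transformation, per-row outlier calling and transcript-cluster filters.

The transform median-centers each feature row and scales it by the unscaled
median absolute deviation (MAD).  Outliers are samples whose transformed
score strictly exceeds ``2 * MAD(scores) / 0.6745``, a one-sided
(overexpression-only) rule.  Rows with zero raw MAD are flagged degenerate
and yield no outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: normal-consistency constant; enters the threshold only, never the transform
MAD_CONSISTENCY = 0.6745

CONTROL = "control"
CANCER = "cancer"


@dataclass(frozen=True)
class TranscriptCluster:
    """A probe-level feature with a genomic interval (0-based half-open)."""

    tc_id: str
    chrom: str
    start: int
    end: int
    strand: str
    probe_count: int
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.tc_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.probe_count < 1:
            raise ValueError(f"{self.tc_id}: probe_count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.tc_id}: strand must be '+' or '-'")


@dataclass
class ExpressionDataset:
    """One cohort: a log2 feature-by-sample matrix plus sample group labels.

    ``sample_groups`` maps sample id -> group label; ``group_classes`` maps
    group label -> ``"control"`` or ``"cancer"``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    sample_groups: Mapping[str, str]
    group_classes: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.matrix.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(
                f"dataset {self.dataset_id}: samples missing from metadata: "
                f"{missing[0]}"
            )
        for group in set(self.sample_groups.values()):
            cls = self.group_classes.get(group)
            if cls not in (CONTROL, CANCER):
                raise ValueError(
                    f"dataset {self.dataset_id}: group {group!r} has invalid "
                    f"class {cls!r}"
                )
        if not self.control_samples or not self.cancer_samples:
            raise ValueError(
                f"dataset {self.dataset_id}: need at least one control and one "
                "cancer sample"
            )

    def _samples_of_class(self, cls: str) -> list[str]:
        return [
            s
            for s in self.matrix.columns
            if self.group_classes[self.sample_groups[s]] == cls
        ]

    @property
    def control_samples(self) -> list[str]:
        return self._samples_of_class(CONTROL)

    @property
    def cancer_samples(self) -> list[str]:
        return self._samples_of_class(CANCER)


@dataclass
class OutlierCall:
    """Per-feature COPA scores, threshold and boolean outlier mask."""

    tc_id: str
    copa_scores: pd.Series
    threshold: float
    outlier_mask: pd.Series
    degenerate: bool = False

    @property
    def outlier_samples(self) -> list[str]:
        return list(self.outlier_mask.index[self.outlier_mask])


def median_absolute_deviation(values: np.ndarray) -> float:
    """Unscaled MAD: median of absolute deviations from the median."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


def copa_transform(row: Sequence[float] | pd.Series) -> np.ndarray:
    """Median-center and MAD-scale one row of log2 values.

    Returns all-zero scores when the row MAD is zero (degenerate rows);
    use :func:`is_degenerate` or :func:`detect_outliers` to flag them.
    """
    values = np.asarray(row, dtype=float)
    if values.size < 3:
        raise ValueError(f"copa_transform needs >= 3 samples, got {values.size}")
    med = np.median(values)
    mad = float(np.median(np.abs(values - med)))
    if mad == 0.0:
        return np.zeros_like(values)
    return (values - med) / mad


def is_degenerate(row: Sequence[float] | pd.Series) -> bool:
    """True when the raw row has zero MAD (flat beyond its median half)."""
    return median_absolute_deviation(np.asarray(row, dtype=float)) == 0.0


def detect_outliers(
    copa_scores: Sequence[float] | pd.Series,
    *,
    tc_id: str = "",
    degenerate: bool = False,
) -> OutlierCall:
    """Call outlier samples from COPA scores.

    Threshold ``t = 2 * MAD(scores) / 0.6745`` over all samples of the
    dataset; a sample is an outlier iff its score is strictly above ``t``.
    Degenerate rows get an empty outlier set and threshold 0.
    """
    scores = pd.Series(copa_scores, dtype=float)
    if degenerate:
        mask = pd.Series(False, index=scores.index)
        return OutlierCall(tc_id, scores, 0.0, mask, degenerate=True)
    threshold = 2.0 * median_absolute_deviation(scores.to_numpy()) / MAD_CONSISTENCY
    mask = scores > threshold
    return OutlierCall(tc_id, scores, threshold, mask, degenerate=False)


def call_dataset(dataset: ExpressionDataset) -> dict[str, OutlierCall]:
    """Transform every row of a dataset and call outliers per feature."""
    calls: dict[str, OutlierCall] = {}
    for tc_id, row in dataset.matrix.iterrows():
        degenerate = is_degenerate(row.to_numpy())
        scores = pd.Series(copa_transform(row.to_numpy()), index=row.index)
        calls[tc_id] = detect_outliers(scores, tc_id=tc_id, degenerate=degenerate)
    return calls


def filter_transcript_clusters(
    dataset: ExpressionDataset,
    tcs: Sequence[TranscriptCluster],
    calls: Mapping[str, OutlierCall],
    min_cancer_outlier_fraction: float = 0.05,
) -> list[str]:
    """Apply the three feature-level filters; return retained tc ids.

    Retained features are (a) unannotated, (b) without any outlier among
    control-class samples and (c) with an outlier fraction of at least
    ``min_cancer_outlier_fraction`` among cancer-class samples.  Boundary
    cases at exactly the threshold are retained.
    """
    controls = dataset.control_samples
    cancers = dataset.cancer_samples
    retained: list[str] = []
    for tc in tcs:
        call = calls.get(tc.tc_id)
        if call is None:
            raise KeyError(f"no outlier call for transcript cluster {tc.tc_id}")
        if tc.annotated:
            continue
        mask = call.outlier_mask
        if mask.loc[controls].any():
            continue
        cancer_fraction = float(mask.loc[cancers].mean())
        if cancer_fraction >= min_cancer_outlier_fraction:
            retained.append(tc.tc_id)
    return retained
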