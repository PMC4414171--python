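"""Ground-truth simulators for every pipeline stage.

Generates multi-cohort expression matrices with implanted outlier loci,
known-gene annotation placed to realize requested positional classes,
clinical follow-up tables, peak interval sets and conservation tracks.
All randomness flows from a single root seed through a fixed
``numpy.random.SeedSequence`` spawning order: child 0 drives the shared
genomic layout, children 1..n_datasets drive per-dataset expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .copa_outlier import CANCER, CONTROL, ExpressionDataset, TranscriptCluster
from .epcat_grouping import (
    ANTISENSE,
    INTERGENIC,
    INTRONIC,
    OVERLAP_3PRIME,
    OVERLAP_5PRIME,
    Epcat,
    Gene,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-cohort simulation (all log2-scale shifts)."""

    n_datasets: int = 3
    control_groups: Mapping[str, int] = field(
        default_factory=lambda: {"NAP": 15}
    )
    cancer_groups: Mapping[str, int] = field(
        default_factory=lambda: {"PCa": 40}
    )
    n_background_tcs: int = 200
    n_true_loci: int = 5
    tcs_per_locus: tuple[int, int] = (3, 4)
    probes_per_tc: tuple[int, int] = (5, 8)
    outlier_fraction: float = 0.3
    effect_size: float = 4.0
    noise_sd: float = 0.3
    annotated_decoy_fraction: float = 0.2
    baseline_range: tuple[float, float] = (4.0, 8.0)
    locus_span_bp: int = 40_000
    inter_locus_spacing_bp: int = 2_000_000
    background_spacing_bp: int = 300_000
    tc_length_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "n_background_tcs": self.n_background_tcs,
            "n_true_loci": self.n_true_loci,
            "locus_span_bp": self.locus_span_bp,
            "inter_locus_spacing_bp": self.inter_locus_spacing_bp,
            "background_spacing_bp": self.background_spacing_bp,
            "tc_length_bp": self.tc_length_bp,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"invalid config field {name}: must be >= 1")
        if not 0 < self.outlier_fraction <= 1:
            raise ValueError("invalid config field outlier_fraction: not in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("invalid config field effect_size: must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("invalid config field noise_sd: must be > 0")
        if not 0 <= self.annotated_decoy_fraction <= 1:
            raise ValueError(
                "invalid config field annotated_decoy_fraction: not in [0, 1]"
            )
        for name in ("tcs_per_locus", "probes_per_tc"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid config field {name}: bad range")
        for name in ("control_groups", "cancer_groups"):
            groups = getattr(self, name)
            if not groups or any(n < 1 for n in groups.values()):
                raise ValueError(f"invalid config field {name}: counts must be >= 1")


@dataclass(frozen=True)
class TrueLocus:
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tc_ids: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything the simulator knows: loci, members, outliers, baselines."""

    loci: list[TrueLocus]
    transcript_clusters: dict[str, TranscriptCluster]
    outlier_samples: dict[tuple[str, str], tuple[str, ...]]
    baselines: dict[tuple[str, str], float]

    def locus(self, locus_id: str) -> TrueLocus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


_LOCUS_CHROMS = [f"chr{i}" for i in range(1, 9)]
_BACKGROUND_CHROMS = [f"chr{i}" for i in range(9, 21)]


def _build_layout(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[TrueLocus], dict[str, TranscriptCluster]]:
    tcs: dict[str, TranscriptCluster] = {}
    loci: list[TrueLocus] = []
    for i in range(config.n_true_loci):
        chrom = _LOCUS_CHROMS[i % len(_LOCUS_CHROMS)]
        block = i // len(_LOCUS_CHROMS)
        start = 1_000_000 + block * config.inter_locus_spacing_bp
        end = start + config.locus_span_bp
        strand = "+" if i % 2 == 0 else "-"
        n_tc = int(rng.integers(config.tcs_per_locus[0], config.tcs_per_locus[1] + 1))
        step = config.locus_span_bp // n_tc
        member_ids = []
        for j in range(n_tc):
            tc_id = f"LOC{i:02d}_TC{j}"
            tc_start = start + j * step
            tc_end = min(tc_start + config.tc_length_bp, end)
            probes = int(
                rng.integers(config.probes_per_tc[0], config.probes_per_tc[1] + 1)
            )
            tcs[tc_id] = TranscriptCluster(
                tc_id, chrom, tc_start, tc_end, strand, probes, annotated=False
            )
            member_ids.append(tc_id)
        loci.append(TrueLocus(f"L{i:02d}", chrom, strand, start, end, tuple(member_ids)))
    decoys = rng.random(config.n_background_tcs) < config.annotated_decoy_fraction
    for i in range(config.n_background_tcs):
        chrom = _BACKGROUND_CHROMS[i % len(_BACKGROUND_CHROMS)]
        block = i // len(_BACKGROUND_CHROMS)
        start = 100_000 + block * config.background_spacing_bp
        strand = "+" if i % 2 == 0 else "-"
        probes = int(
            rng.integers(config.probes_per_tc[0], config.probes_per_tc[1] + 1)
        )
        tc_id = f"BG{i:04d}"
        tcs[tc_id] = TranscriptCluster(
            tc_id, chrom, start, start + config.tc_length_bp, strand, probes,
            annotated=bool(decoys[i]),
        )
    return loci, tcs


def _sample_layout(config: SimulationConfig, dataset_id: str) -> tuple[
    list[str], dict[str, str], dict[str, str]
]:
    sample_ids: list[str] = []
    sample_groups: dict[str, str] = {}
    group_classes: dict[str, str] = {}
    for groups, cls in ((config.control_groups, CONTROL), (config.cancer_groups, CANCER)):
        for group in sorted(groups):
            group_classes[group] = cls
            for k in range(groups[group]):
                sid = f"{dataset_id}_{group}_{k:02d}"
                sample_ids.append(sid)
                sample_groups[sid] = group
    return sample_ids, sample_groups, group_classes


def generate_expression_datasets(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate ``n_datasets`` cohorts sharing one transcript-cluster layout.

    Background rows are baseline plus Gaussian noise in every sample;
    rows of implanted loci additionally gain ``effect_size`` in a random
    per-locus subset (``outlier_fraction``) of cancer samples, shared by
    all member features of the locus.  Deterministic under ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + config.n_datasets)
    layout_rng = np.random.default_rng(children[0])
    loci, tcs = _build_layout(config, layout_rng)
    tc_ids = sorted(tcs)

    datasets: list[ExpressionDataset] = []
    outliers: dict[tuple[str, str], tuple[str, ...]] = {}
    baselines: dict[tuple[str, str], float] = {}
    for d in range(config.n_datasets):
        dataset_id = f"D{d + 1}"
        rng = np.random.default_rng(children[1 + d])
        sample_ids, sample_groups, group_classes = _sample_layout(config, dataset_id)
        cancer_samples = [
            s for s in sample_ids if group_classes[sample_groups[s]] == CANCER
        ]
        base = rng.uniform(
            config.baseline_range[0], config.baseline_range[1], size=len(tc_ids)
        )
        values = base[:, None] + rng.normal(
            0.0, config.noise_sd, size=(len(tc_ids), len(sample_ids))
        )
        matrix = pd.DataFrame(values, index=tc_ids, columns=sample_ids)
        for tc_id, b in zip(tc_ids, base):
            baselines[(dataset_id, tc_id)] = float(b)
        for locus in loci:
            n_out = max(1, round(config.outlier_fraction * len(cancer_samples)))
            chosen = sorted(
                rng.choice(cancer_samples, size=n_out, replace=False).tolist()
            )
            outliers[(dataset_id, locus.locus_id)] = tuple(chosen)
            if config.effect_size > 0:
                matrix.loc[list(locus.tc_ids), chosen] += config.effect_size
        datasets.append(
            ExpressionDataset(dataset_id, matrix, sample_groups, group_classes)
        )
    truth = GroundTruth(loci, tcs, outliers, baselines)
    return datasets, truth


def generate_annotation(
    truth: GroundTruth,
    class_requests: Mapping[str, str],
) -> list[Gene]:
    """Place genes realizing a requested positional class per locus.

    ``class_requests`` maps locus id to one of the positional classes;
    loci requested ``intergenic`` (or omitted) get no gene.  Placement is
    relative to the member-feature span so classification of a fully
    recovered locus yields the requested class by construction.
    """
    genes: list[Gene] = []
    for locus_id, cls in sorted(class_requests.items()):
        locus = truth.locus(locus_id)
        members = [truth.transcript_clusters[t] for t in locus.tc_ids]
        mstart = min(t.start for t in members)
        mend = max(t.end for t in members)
        mid = (mstart + mend) // 2
        name = f"GENE_{locus_id}_{cls}"
        if cls == INTERGENIC:
            continue
        if cls == ANTISENSE:
            strand = "-" if locus.strand == "+" else "+"
            start, end = mstart - 1_000, mend + 1_000
            exons = ((start, start + 500), (end - 500, end))
        elif cls == OVERLAP_5PRIME:
            strand = locus.strand
            if strand == "+":
                start, end = mid, mend + 20_000
            else:
                start, end = mstart - 20_000, mid
            exons = ((start, start + 500), (end - 500, end))
        elif cls == OVERLAP_3PRIME:
            strand = locus.strand
            if strand == "+":
                start, end = mstart - 20_000, mid
            else:
                start, end = mid, mend + 20_000
            exons = ((start, start + 500), (end - 500, end))
        elif cls == INTRONIC:
            strand = locus.strand
            start, end = mstart - 10_000, mend + 10_000
            exons = ((start, start + 500), (end - 500, end))
        else:
            raise ValueError(f"unknown positional class request: {cls!r}")
        genes.append(Gene(name, locus.chrom, strand, start, end, exons))
    return genes


def generate_clinical(
    samples: Sequence[str],
    high_group_ids: Sequence[str],
    event_rate_high: float,
    event_rate_low: float,
    seed: int | None = None,
    *,
    event_time_scale: float = 24.0,
    censor_time_scale: float = 60.0,
) -> pd.DataFrame:
    """Bernoulli endpoint events at group-specific rates with exponential
    event/censoring times (months).  Returns (sample_id, event, time)."""
    for rate, name in ((event_rate_high, "event_rate_high"),
                       (event_rate_low, "event_rate_low")):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    unknown = set(high_group_ids) - set(samples)
    if unknown:
        raise KeyError(f"unknown sample id(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    high = set(high_group_ids)
    records = []
    for sid in samples:
        rate = event_rate_high if sid in high else event_rate_low
        event = int(rng.random() < rate)
        scale = event_time_scale if event else censor_time_scale
        time = float(rng.exponential(scale))
        records.append((sid, event, max(time, 1e-3)))
    return pd.DataFrame(records, columns=["sample_id", "event", "time"])


def generate_peaks(
    loci: Sequence[TrueLocus],
    hit_ids: Sequence[str],
    flank_bp: int = 50_000,
    seed: int | None = None,
    *,
    peak_width: int = 600,
) -> list[tuple[str, int, int, str]]:
    """Peaks inside (locus +/- flank) for hits and beyond it for non-hits."""
    known = {l.locus_id for l in loci}
    missing = set(hit_ids) - known
    if missing:
        raise ValueError(f"hit_ids not among loci: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    hits = set(hit_ids)
    peaks = []
    for locus in loci:
        if locus.locus_id in hits:
            center = int(rng.integers(locus.start, locus.end))
        else:
            offset = int(rng.integers(50_000, 150_000))
            center = locus.end + flank_bp + peak_width + offset
        peaks.append(
            (
                locus.chrom,
                max(center - peak_width // 2, 0),
                center + peak_width // 2,
                f"peak_{locus.locus_id}",
            )
        )
    return peaks


def generate_conservation(
    loci: Sequence[TrueLocus],
    elevated_windows: Mapping[str, Sequence[tuple[int, int, float]]] | None = None,
    *,
    baseline_score: float = 0.0,
    noise_sd: float = 0.0,
    bin_bp: int = 25,
    seed: int | None = None,
) -> ConservationTrack:
    """Per-base score track over each locus span.

    ``elevated_windows`` maps locus id to (relative start, relative end,
    score) windows overriding the baseline.  With ``noise_sd`` = 0 the
    track is fully deterministic.
    """
    rng = np.random.default_rng(seed)
    track = ConservationTrack()
    elevated_windows = elevated_windows or {}
    for locus in loci:
        length = locus.end - locus.start
        per_base = np.full(length, baseline_score)
        if noise_sd > 0:
            n_bins = (length + bin_bp - 1) // bin_bp
            bin_scores = baseline_score + rng.normal(0.0, noise_sd, size=n_bins)
            per_base = np.repeat(bin_scores, bin_bp)[:length]
        for rel_start, rel_end, score in elevated_windows.get(locus.locus_id, ()):
            per_base[max(rel_start, 0) : min(rel_end, length)] = score
        # run-length encode so stored intervals never overlap
        change = np.flatnonzero(np.diff(per_base)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [length]))
        for lo, hi in zip(starts, ends):
            track.add(
                locus.chrom, locus.start + int(lo), locus.start + int(hi),
                float(per_base[lo]),
            )
    track.sort()
    return track


def match_epcats_to_truth(
    epcats: Sequence[Epcat], truth: GroundTruth
) -> tuple[set[str], list[Epcat]]:
    """Match recovered EPCATs to implanted loci by same-strand span overlap.

    Returns the set of recovered locus ids and the list of false EPCATs
    (those overlapping no implanted locus).
    """
    recovered: set[str] = set()
    false_epcats: list[Epcat] = []
    for epcat in epcats:
        matched = False
        for locus in truth.loci:
            if (
                epcat.chrom == locus.chrom
                and epcat.strand == locus.strand
                and epcat.start < locus.end
                and locus.start < epcat.end
            ):
                recovered.add(locus.locus_id)
                matched = True
        if not matched:
            false_epcats.append(epcat)
    return recovered, false_epcats
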