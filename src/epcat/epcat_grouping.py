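"""Group retained transcript clusters into candidate loci, reconcile loci
across datasets into named EPCATs, and classify them against annotation.

Grouping builds a graph over same-chromosome, same-strand features whose
interval gap is below 250 kb and whose COPA score vectors have Spearman
correlation >= 0.5; loci are the connected components.  Loci from different
datasets merge into one EPCAT when their spans overlap on the same strand;
EPCATs detected in fewer than two datasets or summing fewer than 12 probes
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .copa_outlier import TranscriptCluster

MAX_GAP_BP = 250_000
MIN_RHO = 0.5
MIN_DATASETS = 2
MIN_PROBES = 12

INTERGENIC = "intergenic"
ANTISENSE = "antisense"
OVERLAP_5PRIME = "overlap_5prime"
OVERLAP_3PRIME = "overlap_3prime"
INTRONIC = "intronic"


@dataclass(frozen=True)
class Gene:
    """Annotated gene with exon structure (0-based half-open coordinates)."""

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start >= end")

    @property
    def five_prime(self) -> int:
        """Base position of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exons = sorted(self.exons)
        return tuple(
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i][1] < exons[i + 1][0]
        )


@dataclass(frozen=True)
class CandidateLocus:
    """A per-dataset group of transcript clusters sharing one outlier profile."""

    dataset_id: str
    tc_ids: tuple[str, ...]
    chrom: str
    strand: str
    start: int
    end: int
    probe_total: int


@dataclass
class Epcat:
    """A cross-dataset candidate locus."""

    chrom: str
    strand: str
    start: int
    end: int
    members_by_dataset: dict[str, tuple[str, ...]]
    datasets_detected: frozenset[str]
    probe_total: int
    name: str | None = None
    positional_class: str | None = None

    @property
    def tc_ids(self) -> tuple[str, ...]:
        """Union of member tc ids over datasets (sorted, de-duplicated)."""
        union: set[str] = set()
        for ids in self.members_by_dataset.values():
            union.update(ids)
        return tuple(sorted(union))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Separation between two half-open intervals; 0 when they touch/overlap."""
    return max(a_start - b_end, b_start - a_end, 0)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else np.nan


def group_tcs(
    tcs: Sequence[TranscriptCluster],
    copa_scores: Mapping[str, np.ndarray],
    *,
    dataset_id: str = "",
    max_gap_bp: int = MAX_GAP_BP,
    min_rho: float = MIN_RHO,
) -> list[CandidateLocus]:
    """Partition features of one dataset into candidate loci.

    An edge joins two features iff they share chromosome and strand, their
    interval gap is strictly below ``max_gap_bp`` and the Spearman
    correlation of their COPA score vectors is >= ``min_rho``.  Loci are
    connected components; singletons are allowed.
    """
    for tc in tcs:
        if tc.tc_id not in copa_scores:
            raise KeyError(f"no COPA scores for transcript cluster {tc.tc_id}")
    order = sorted(range(len(tcs)), key=lambda i: (tcs[i].chrom, tcs[i].strand, tcs[i].start, tcs[i].end, tcs[i].tc_id))
    uf = _UnionFind(len(tcs))
    for pos_a in range(len(order)):
        i = order[pos_a]
        a = tcs[i]
        for pos_b in range(pos_a + 1, len(order)):
            j = order[pos_b]
            b = tcs[j]
            if (a.chrom, a.strand) != (b.chrom, b.strand):
                break
            if interval_gap(a.start, a.end, b.start, b.end) >= max_gap_bp:
                continue
            rho = _spearman(
                np.asarray(copa_scores[a.tc_id], dtype=float),
                np.asarray(copa_scores[b.tc_id], dtype=float),
            )
            if np.isfinite(rho) and rho >= min_rho:
                uf.union(i, j)
    components: dict[int, list[TranscriptCluster]] = {}
    for i, tc in enumerate(tcs):
        components.setdefault(uf.find(i), []).append(tc)
    loci = []
    for members in components.values():
        members.sort(key=lambda t: (t.start, t.end, t.tc_id))
        loci.append(
            CandidateLocus(
                dataset_id=dataset_id,
                tc_ids=tuple(t.tc_id for t in members),
                chrom=members[0].chrom,
                strand=members[0].strand,
                start=min(t.start for t in members),
                end=max(t.end for t in members),
                probe_total=sum(t.probe_count for t in members),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.strand, l.start, l.end))
    return loci


def reconcile_datasets(
    loci_by_dataset: Mapping[str, Sequence[CandidateLocus]],
    tcs: Mapping[str, TranscriptCluster],
    *,
    min_datasets: int = MIN_DATASETS,
    min_probes: int = MIN_PROBES,
) -> list[Epcat]:
    """Merge per-dataset loci into cross-dataset EPCATs.

    Loci link when they overlap (>= 1 bp) on the same chromosome and strand;
    each connected component seen in at least ``min_datasets`` datasets
    becomes one EPCAT with the union of member features and the union span.
    The probe total is summed over the de-duplicated member set; EPCATs
    below ``min_probes`` are removed.
    """
    if len(loci_by_dataset) < 2:
        raise ValueError("reconcile_datasets needs loci from >= 2 datasets")
    for dataset_id, loci in loci_by_dataset.items():
        seen: set[str] = set()
        for locus in loci:
            for tc_id in locus.tc_ids:
                if tc_id in seen:
                    raise ValueError(
                        f"dataset {dataset_id}: duplicate tc id {tc_id}"
                    )
                seen.add(tc_id)
    flat: list[CandidateLocus] = [
        locus
        for dataset_id in sorted(loci_by_dataset)
        for locus in loci_by_dataset[dataset_id]
    ]
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            a, b = flat[i], flat[j]
            if (a.chrom, a.strand) != (b.chrom, b.strand):
                continue
            if a.start < b.end and b.start < a.end:
                uf.union(i, j)
    components: dict[int, list[CandidateLocus]] = {}
    for i, locus in enumerate(flat):
        components.setdefault(uf.find(i), []).append(locus)

    epcats: list[Epcat] = []
    for members in components.values():
        datasets = frozenset(l.dataset_id for l in members)
        if len(datasets) < min_datasets:
            continue
        members_by_dataset: dict[str, set[str]] = {}
        for locus in members:
            members_by_dataset.setdefault(locus.dataset_id, set()).update(
                locus.tc_ids
            )
        union_ids = sorted(set().union(*members_by_dataset.values()))
        probe_total = sum(tcs[tc_id].probe_count for tc_id in union_ids)
        if probe_total < min_probes:
            continue
        epcats.append(
            Epcat(
                chrom=members[0].chrom,
                strand=members[0].strand,
                start=min(l.start for l in members),
                end=max(l.end for l in members),
                members_by_dataset={
                    d: tuple(sorted(ids)) for d, ids in members_by_dataset.items()
                },
                datasets_detected=datasets,
                probe_total=probe_total,
            )
        )
    epcats.sort(key=lambda e: (_chrom_key(e.chrom), e.strand, e.start, e.end))
    return epcats


def _chrom_key(chrom: str) -> tuple[int, str]:
    label = chrom.removeprefix("chr")
    return (0, f"{int(label):03d}") if label.isdigit() else (1, label)


def name_epcats(epcats: Iterable[Epcat], *, pad: int = 3) -> list[Epcat]:
    """Assign names ``EPCAT{chrom}{F|R}{ordinal}`` by genomic position.

    Ordinals are zero-padded and count within each (chromosome, strand)
    group in order of start coordinate; renaming is deterministic.
    """
    ordered = sorted(
        epcats, key=lambda e: (_chrom_key(e.chrom), e.strand, e.start, e.end)
    )
    counters: dict[tuple[str, str], int] = {}
    named = []
    for epcat in ordered:
        key = (epcat.chrom, epcat.strand)
        counters[key] = counters.get(key, 0) + 1
        label = epcat.chrom.removeprefix("chr")
        strand_code = "F" if epcat.strand == "+" else "R"
        named.append(
            replace_name(epcat, f"EPCAT{label}{strand_code}{counters[key]:0{pad}d}")
        )
    return named


def replace_name(epcat: Epcat, name: str) -> Epcat:
    return Epcat(
        chrom=epcat.chrom,
        strand=epcat.strand,
        start=epcat.start,
        end=epcat.end,
        members_by_dataset=dict(epcat.members_by_dataset),
        datasets_detected=epcat.datasets_detected,
        probe_total=epcat.probe_total,
        name=name,
        positional_class=epcat.positional_class,
    )


def classify_epcat(epcat: Epcat, genes: Sequence[Gene]) -> str:
    """Positional class of an EPCAT relative to annotated genes.

    Precedence: same-strand overlap containing a gene's 5' end ->
    ``overlap_5prime``; containing a 3' end -> ``overlap_3prime``; fully
    inside a same-strand gene (typically an intron) -> ``intronic``;
    overlapping only opposite-strand genes -> ``antisense``; otherwise
    ``intergenic``.
    """
    span = (epcat.start, epcat.end)
    same, opposite = [], []
    for gene in genes:
        if gene.chrom != epcat.chrom:
            continue
        if gene.start < span[1] and span[0] < gene.end:
            (same if gene.strand == epcat.strand else opposite).append(gene)
    if any(span[0] <= g.five_prime < span[1] for g in same):
        return OVERLAP_5PRIME
    if any(span[0] <= g.three_prime < span[1] for g in same):
        return OVERLAP_3PRIME
    for gene in same:
        if gene.start <= span[0] and span[1] <= gene.end:
            return INTRONIC
    if opposite:
        return ANTISENSE
    return INTERGENIC


def classify_all(epcats: Sequence[Epcat], genes: Sequence[Gene]) -> list[Epcat]:
    out = []
    for epcat in epcats:
        clone = replace_name(epcat, epcat.name or "")
        clone.name = epcat.name
        clone.positional_class = classify_epcat(epcat, genes)
        out.append(clone)
    return out
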