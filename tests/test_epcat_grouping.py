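"""Tests for locus grouping, cross-dataset reconciliation, naming and
positional classification."""

import numpy as np
import pytest
from scipy import stats

from epcat.copa_outlier import TranscriptCluster
from epcat.epcat_grouping import (
    ANTISENSE,
    INTERGENIC,
    INTRONIC,
    OVERLAP_3PRIME,
    OVERLAP_5PRIME,
    CandidateLocus,
    Epcat,
    Gene,
    classify_epcat,
    group_tcs,
    interval_gap,
    name_epcats,
    reconcile_datasets,
)


def tc(tc_id, start, end, chrom="chr1", strand="+", probes=5, annotated=False):
    return TranscriptCluster(tc_id, chrom, start, end, strand, probes, annotated)


def locus(dataset, start, end, tc_ids, chrom="chr2", strand="+", probes=20):
    return CandidateLocus(dataset, tuple(tc_ids), chrom, strand, start, end, probes)


def make_epcat(chrom="chr1", strand="+", start=100, end=200):
    return Epcat(chrom, strand, start, end, {"D1": ("a",)}, frozenset({"D1", "D2"}), 20)


# --- independent oracle: all-pairs edges + graph traversal --------------------

def oracle_components(tcs, scores, max_gap, min_rho):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(t.tc_id for t in tcs)
    for i in range(len(tcs)):
        for j in range(i + 1, len(tcs)):
            a, b = tcs[i], tcs[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            gap = max(a.start - b.end, b.start - a.end, 0)
            if gap >= max_gap:
                continue
            rho = stats.spearmanr(scores[a.tc_id], scores[b.tc_id]).statistic
            if np.isfinite(rho) and rho >= min_rho:
                g.add_edge(a.tc_id, b.tc_id)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestGroupTcs:
    def test_hand_example(self):
        tcs = [
            tc("a", 1000, 2000, chrom="chr2"),
            tc("b", 100_000, 101_000, chrom="chr2"),
            tc("c", 400_000, 401_000, chrom="chr2"),
        ]
        v = np.arange(10.0)
        scores = {t.tc_id: v for t in tcs}
        loci = group_tcs(tcs, scores)
        parts = {frozenset(l.tc_ids) for l in loci}
        assert parts == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_opposite_strands_never_group(self):
        tcs = [tc("a", 0, 100, strand="+"), tc("b", 200, 300, strand="-")]
        v = np.arange(8.0)
        loci = group_tcs(tcs, {"a": v, "b": v})
        assert len(loci) == 2

    def test_gap_is_separation_not_midpoint(self):
        # gap exactly at the limit is excluded (strict <)
        tcs = [tc("a", 0, 1000), tc("b", 251_000, 252_000)]
        v = np.arange(8.0)
        assert len(group_tcs(tcs, {"a": v, "b": v})) == 2
        tcs = [tc("a", 0, 1000), tc("b", 250_999, 252_000)]
        assert len(group_tcs(tcs, {"a": v, "b": v})) == 1

    def test_missing_scores_error(self):
        with pytest.raises(KeyError, match="a"):
            group_tcs([tc("a", 0, 100)], {})

    def test_matches_oracle_on_random_instances(self, rng):
        patterns = [rng.normal(0, 1, 12) for _ in range(6)]
        for _ in range(30):
            n = 20
            tcs = []
            scores = {}
            for i in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                strand = "+" if rng.random() < 0.5 else "-"
                start = int(rng.integers(0, 1_000_000))
                tcs.append(tc(f"t{i}", start, start + 500, chrom, strand))
                base = patterns[rng.integers(0, len(patterns))]
                scores[f"t{i}"] = base + rng.normal(0, 0.3, 12)
            got = {frozenset(l.tc_ids) for l in group_tcs(tcs, scores)}
            assert got == oracle_components(tcs, scores, 250_000, 0.5)

    def test_partition_and_order_invariance(self, rng):
        tcs = [tc(f"t{i}", i * 100_000, i * 100_000 + 500) for i in range(12)]
        scores = {t.tc_id: rng.normal(0, 1, 10) for t in tcs}
        loci = group_tcs(tcs, scores)
        all_ids = sorted(i for l in loci for i in l.tc_ids)
        assert all_ids == sorted(t.tc_id for t in tcs)
        shuffled = list(tcs)
        rng.shuffle(shuffled)
        loci2 = group_tcs(shuffled, scores)
        assert {frozenset(l.tc_ids) for l in loci} == {
            frozenset(l.tc_ids) for l in loci2
        }

    def test_loosening_parameters_is_monotone(self, rng):
        tcs = [tc(f"t{i}", i * 150_000, i * 150_000 + 500) for i in range(10)]
        scores = {t.tc_id: rng.normal(0, 1, 10) for t in tcs}
        strict = group_tcs(tcs, scores, max_gap_bp=100_000, min_rho=0.7)
        loose = group_tcs(tcs, scores, max_gap_bp=250_000, min_rho=0.3)
        loose_parts = [set(l.tc_ids) for l in loose]
        for l in strict:
            assert any(set(l.tc_ids) <= part for part in loose_parts)


class TestReconcile:
    TCS = {
        "a": tc("a", 1_000_000, 1_200_000, chrom="chr2", probes=8),
        "b": tc("b", 1_100_000, 1_300_000, chrom="chr2", probes=7),
        "c": tc("c", 5_000_000, 5_010_000, chrom="chr2", probes=30),
    }

    def test_overlapping_loci_merge(self):
        loci = {
            "A": [locus("A", 1_000_000, 1_200_000, ["a"])],
            "B": [locus("B", 1_100_000, 1_300_000, ["b"])],
        }
        epcats = reconcile_datasets(loci, self.TCS)
        assert len(epcats) == 1
        e = epcats[0]
        assert (e.start, e.end) == (1_000_000, 1_300_000)
        assert e.tc_ids == ("a", "b")
        assert e.probe_total == 15

    def test_single_dataset_locus_removed(self):
        loci = {
            "A": [locus("A", 5_000_000, 5_010_000, ["c"])],
            "B": [],
        }
        assert reconcile_datasets(loci, self.TCS) == []

    def test_probe_threshold_boundary(self):
        for probes, kept in [(11, 0), (12, 1)]:
            tcs = {"x": tc("x", 0, 100, probes=probes)}
            loci = {
                "A": [CandidateLocus("A", ("x",), "chr1", "+", 0, 100, probes)],
                "B": [CandidateLocus("B", ("x",), "chr1", "+", 0, 100, probes)],
            }
            assert len(reconcile_datasets(loci, tcs)) == kept

    def test_duplicate_tc_in_dataset_errors(self):
        loci = {
            "A": [
                locus("A", 0, 100, ["a"], chrom="chr2"),
                locus("A", 1_000_000, 1_000_100, ["a"], chrom="chr2"),
            ],
            "B": [],
        }
        with pytest.raises(ValueError, match="duplicate tc id"):
            reconcile_datasets(loci, self.TCS)

    def test_needs_two_datasets(self):
        with pytest.raises(ValueError, match=">= 2 datasets"):
            reconcile_datasets({"A": []}, {})

    def test_min_datasets_one_is_superset(self):
        loci = {
            "A": [locus("A", 1_000_000, 1_200_000, ["a"]),
                  locus("A", 5_000_000, 5_010_000, ["c"])],
            "B": [locus("B", 1_100_000, 1_300_000, ["b"])],
        }
        strict = reconcile_datasets(loci, self.TCS, min_datasets=2, min_probes=1)
        relaxed = reconcile_datasets(loci, self.TCS, min_datasets=1, min_probes=1)
        strict_spans = {(e.chrom, e.strand, e.start, e.end) for e in strict}
        relaxed_spans = {(e.chrom, e.strand, e.start, e.end) for e in relaxed}
        assert strict_spans <= relaxed_spans
        assert len(relaxed) > len(strict)


class TestNaming:
    def test_forward_chr2(self):
        named = name_epcats([make_epcat(chrom="chr2", strand="+")])
        assert named[0].name == "EPCAT2F001"

    def test_reverse_chrx(self):
        named = name_epcats([make_epcat(chrom="chrX", strand="-")])
        assert named[0].name == "EPCATXR001"

    def test_ordinal_by_start_within_group(self):
        epcats = [
            make_epcat(start=5000, end=6000),
            make_epcat(start=100, end=200),
            make_epcat(chrom="chr2", start=50, end=80),
        ]
        names = [e.name for e in name_epcats(epcats)]
        assert names == ["EPCAT1F001", "EPCAT1F002", "EPCAT2F001"]

    def test_renaming_deterministic(self):
        epcats = [make_epcat(start=s, end=s + 10) for s in (300, 100, 200)]
        first = [e.name for e in name_epcats(epcats)]
        second = [e.name for e in name_epcats(epcats)]
        assert first == second


# --- classification ----------------------------------------------------------

def oracle_classify(span_chrom, span_start, span_end, span_strand, genes):
    """Brute-force interval logic written independently from the precedence."""
    same = [
        g for g in genes
        if g.chrom == span_chrom and g.strand == span_strand
        and g.start < span_end and span_start < g.end
    ]
    anti = [
        g for g in genes
        if g.chrom == span_chrom and g.strand != span_strand
        and g.start < span_end and span_start < g.end
    ]
    for g in same:
        fp = g.start if g.strand == "+" else g.end - 1
        if span_start <= fp < span_end:
            return OVERLAP_5PRIME
    for g in same:
        tp = g.end - 1 if g.strand == "+" else g.start
        if span_start <= tp < span_end:
            return OVERLAP_3PRIME
    for g in same:
        if g.start <= span_start and span_end <= g.end:
            return INTRONIC
    if anti:
        return ANTISENSE
    return INTERGENIC


class TestClassify:
    def test_intronic(self):
        gene = Gene("g", "chr1", "+", 0, 10_000,
                    exons=((0, 100), (9_900, 10_000)))
        assert classify_epcat(make_epcat(start=500, end=600), [gene]) == INTRONIC

    def test_antisense_only(self):
        gene = Gene("g", "chr1", "-", 50, 5_000)
        assert classify_epcat(make_epcat(start=100, end=200), [gene]) == ANTISENSE

    def test_no_overlap_intergenic(self):
        gene = Gene("g", "chr1", "+", 10_000, 20_000)
        assert classify_epcat(make_epcat(start=100, end=200), [gene]) == INTERGENIC

    def test_five_prime_precedence(self):
        gene = Gene("g", "chr1", "+", 150, 5_000)
        assert classify_epcat(make_epcat(start=100, end=200), [gene]) == OVERLAP_5PRIME

    def test_three_prime(self):
        gene = Gene("g", "chr1", "+", 0, 150)
        assert classify_epcat(make_epcat(start=100, end=200), [gene]) == OVERLAP_3PRIME

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200)[:200]:
            span_start = int(rng.integers(0, 5_000))
            span_end = span_start + int(rng.integers(100, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes = []
            for k in range(int(rng.integers(0, 4))):
                g_start = int(rng.integers(0, 6_000))
                g_end = g_start + int(rng.integers(200, 4_000))
                g_strand = "+" if rng.random() < 0.5 else "-"
                genes.append(Gene(f"g{k}", "chr1", g_strand, g_start, g_end))
            epcat = make_epcat(start=span_start, end=span_end, strand=strand)
            assert classify_epcat(epcat, genes) == oracle_classify(
                "chr1", span_start, span_end, strand, genes
            )


class TestGroundTruthRecovery:
    def test_spans_contain_implanted_members(self, sim):
        from epcat.cli_io import discover_epcats
        from epcat.synthetic_data import match_epcats_to_truth

        _, datasets, truth = sim
        epcats = discover_epcats(datasets, truth.transcript_clusters)
        recovered, false_epcats = match_epcats_to_truth(epcats, truth)
        assert recovered == {l.locus_id for l in truth.loci}
        assert false_epcats == []
        by_key = {(e.chrom, e.strand): e for e in epcats}
        for locus in truth.loci:
            e = by_key[(locus.chrom, locus.strand)]
            members = [truth.transcript_clusters[t] for t in locus.tc_ids]
            assert e.start <= min(t.start for t in members)
            assert e.end >= max(t.end for t in members)
            assert set(e.tc_ids) == set(locus.tc_ids)

    def test_interval_gap(self):
        assert interval_gap(0, 10, 20, 30) == 10
        assert interval_gap(20, 30, 0, 10) == 10
        assert interval_gap(0, 10, 5, 30) == 0
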