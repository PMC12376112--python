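"""Haplotig pairing evidence and the greedy purge classifier."""
import random

import pytest

from diphap import io as dio
from diphap.purge import (
    build_pair_evidence,
    classify_haplotigs,
    collinear_genes_map,
    compute_pair_coverage,
    detect_collinear_blocks,
    purge_assembly,
    shared_single_copy_markers,
)
from diphap.types import (
    AlignmentRecord,
    Contig,
    GeneAnchor,
    MarkerHit,
    PairEvidence,
    PurgeConfig,
)


def aln(q, qlen, qs, qe, t, tlen, ts, te, mapq=60):
    return AlignmentRecord(q, qlen, qs, qe, "+", t, tlen, ts, te, mapq=mapq)


def anchors_for(contig, gene_ids):
    """Equally spaced anchors in the given gene order."""
    out = [GeneAnchor(g, contig, 1000 * i, 1000 * i + 500)
           for i, g in enumerate(gene_ids)]
    return dio.assign_ranks(out)


# ---------------------------------------------------------------------------
# coverage


class TestPairCoverage:
    lengths = {"B": 1_000, "A": 5_000}

    def test_single_alignment_fraction(self):
        cov = compute_pair_coverage(
            [aln("B", 1_000, 0, 710, "A", 5_000, 100, 810)], self.lengths)
        assert cov[("B", "A")] == pytest.approx(0.71)

    def test_no_alignments_means_no_pair(self):
        assert compute_pair_coverage([], self.lengths) == {}

    def test_overlapping_segments_counted_once(self):
        cov = compute_pair_coverage(
            [aln("B", 1_000, 0, 400, "A", 5_000, 0, 400),
             aln("B", 1_000, 300, 800, "A", 5_000, 300, 800)], self.lengths)
        assert cov[("B", "A")] == pytest.approx(0.80)

    def test_measured_on_shorter_side_regardless_of_paf_role(self):
        # same pair, but the long contig is the PAF query
        cov = compute_pair_coverage(
            [aln("A", 5_000, 100, 810, "B", 1_000, 0, 710)], self.lengths)
        assert cov[("B", "A")] == pytest.approx(0.71)

    def test_self_alignments_ignored(self):
        cov = compute_pair_coverage(
            [aln("A", 5_000, 0, 5_000, "A", 5_000, 0, 5_000)], self.lengths)
        assert cov == {}

    def test_unknown_contig_is_integrity_error(self):
        with pytest.raises(dio.IntegrityError, match="unknown contig"):
            compute_pair_coverage(
                [aln("B", 1_000, 0, 710, "Z", 5_000, 100, 810)],
                self.lengths)

    def test_random_instances_match_per_base_oracle(self):
        rnd = random.Random(7)
        for _ in range(100):
            short_len = rnd.randint(200, 2_000)
            lengths = {"S": short_len, "L": short_len + rnd.randint(1, 500)}
            alns = []
            ivs = []
            for _ in range(rnd.randint(0, 8)):
                s = rnd.randrange(0, short_len - 1)
                e = rnd.randrange(s + 1, short_len + 1)
                ivs.append((s, e))
                alns.append(aln("S", short_len, s, e, "L", lengths["L"],
                                0, e - s))
            cov = compute_pair_coverage(alns, lengths)
            per_base = sum(
                1 for p in range(short_len)
                if any(s <= p < e for s, e in ivs))
            if alns:
                assert cov[("S", "L")] == pytest.approx(
                    per_base / short_len)
            else:
                assert cov == {}


# ---------------------------------------------------------------------------
# micro-synteny


def brute_force_monotone_chain(perm_b):
    """Independent oracle: longest strictly monotone (either direction)
    subsequence of the b-rank sequence, textbook O(n^2) DP."""
    def longest(seq):
        n = len(seq)
        dp = [1] * n
        for i in range(n):
            for j in range(i):
                if seq[j] < seq[i]:
                    dp[i] = max(dp[i], dp[j] + 1)
        return max(dp) if dp else 0

    return max(longest(perm_b), longest([-x for x in perm_b]))


class TestCollinearBlocks:
    def run(self, order_b, config=None):
        genes = [f"g{i}" for i in range(len(order_b))]
        a = anchors_for("A", genes)
        b = anchors_for("B", [genes[i - 1] for i in order_b])
        matches = [(g, g) for g in genes]
        return detect_collinear_blocks(a, b, matches,
                                       config or PurgeConfig())

    def test_identical_order_single_block(self):
        blocks = self.run([1, 2, 3, 4, 5, 6])
        assert blocks[0].size == 6
        assert blocks[0].orientation == "same"

    def test_four_genes_do_not_reach_the_criterion(self):
        blocks = self.run([1, 2, 3, 4])
        assert blocks[0].size == 4
        assert blocks[0].size < PurgeConfig().min_collinear_genes

    def test_permuted_order_chains_the_lis(self):
        # b-rank sequence (2,1,3,5,4): best monotone chain is 3
        blocks = self.run([2, 1, 3, 5, 4])
        assert blocks[0].size == 3

    def test_inverted_order_detected_as_inverted(self):
        blocks = self.run([6, 5, 4, 3, 2, 1])
        assert blocks[0].size == 6
        assert blocks[0].orientation == "inverted"

    def test_chain_is_monotone_in_both_rank_orders(self):
        blocks = self.run([3, 1, 4, 2, 6, 5, 7])
        ra = [p[0] for p in blocks[0].anchor_pairs]
        rb = [p[1] for p in blocks[0].anchor_pairs]
        assert ra == sorted(ra)
        assert rb == sorted(rb) or rb == sorted(rb, reverse=True)

    def test_anchor_gap_cap_limits_chains(self):
        # matched genes 15 ranks apart on b cannot chain under gap 10
        genes = ["g0", "g1"]
        a = anchors_for("A", genes)
        b = anchors_for("B", ["g0"] + [f"f{i}" for i in range(14)] + ["g1"])
        blocks = detect_collinear_blocks(
            a, b, [("g0", "g0"), ("g1", "g1")],
            PurgeConfig(max_anchor_gap=10))
        assert blocks[0].size == 1
        blocks = detect_collinear_blocks(
            a, b, [("g0", "g0"), ("g1", "g1")],
            PurgeConfig(max_anchor_gap=20))
        assert blocks[0].size == 2

    def test_200_random_permutations_match_brute_force(self):
        rnd = random.Random(123)
        for _ in range(200):
            n = rnd.randint(1, 15)
            perm = list(range(1, n + 1))
            rnd.shuffle(perm)
            blocks = self.run(perm, PurgeConfig(max_anchor_gap=n))
            assert blocks[0].size == brute_force_monotone_chain(perm)

    def test_duplicate_rank_is_integrity_error(self):
        a = anchors_for("A", ["g0", "g1"])
        a[1].rank = 1
        with pytest.raises(dio.IntegrityError, match="rank"):
            detect_collinear_blocks(a, anchors_for("B", ["g0", "g1"]),
                                    [("g0", "g0")])


# ---------------------------------------------------------------------------
# shared markers


class TestSharedMarkers:
    def test_single_copy_on_both_links_the_pair(self):
        hits = [MarkerHit("m1", "A", "complete", 1),
                MarkerHit("m1", "B", "complete", 1)]
        assert shared_single_copy_markers(hits) == {("A", "B"): 1}

    def test_fragmented_copy_does_not_count(self):
        hits = [MarkerHit("m1", "A", "complete", 1),
                MarkerHit("m1", "B", "fragmented", 1)]
        assert shared_single_copy_markers(hits) == {}

    def test_multi_copy_on_one_contig_does_not_count(self):
        hits = [MarkerHit("m1", "A", "complete", 2),
                MarkerHit("m1", "B", "complete", 1)]
        assert shared_single_copy_markers(hits) == {}


# ---------------------------------------------------------------------------
# classification


class TestClassifyHaplotigs:
    lengths = {"A": 3_000, "B": 2_000, "C": 1_000}

    def test_coverage_criterion(self):
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", coverage=0.80)], self.lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["B"].label == "haplotig"
        assert by_id["B"].partner_id == "A"
        assert by_id["B"].triggered_criteria == ("coverage",)

    def test_coverage_threshold_is_strict(self):
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", coverage=0.70)], self.lengths)
        assert all(d.label == "primary" for d in decisions)

    def test_synteny_criterion_at_five_genes(self):
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", coverage=0.50, collinear_genes=5)],
            self.lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["B"].triggered_criteria == ("synteny",)

    def test_marker_criterion_at_one_marker(self):
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", shared_markers=1)], self.lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["B"].triggered_criteria == ("marker",)

    def test_chain_of_haplotigs_all_purged(self):
        # C pairs with B, B pairs with A: B haplotig of A; C haplotig of
        # B (a purged partner is still a valid recorded partner).
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", coverage=0.9),
             PairEvidence("C", "B", coverage=0.9)], self.lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["A"].label == "primary"
        assert by_id["B"].partner_id == "A"
        assert by_id["C"].partner_id == "B"
        assert by_id["C"].label == "haplotig"

    def test_best_partner_prefers_more_criteria_then_coverage(self):
        decisions = classify_haplotigs(
            [PairEvidence("C", "A", coverage=0.95),
             PairEvidence("C", "B", coverage=0.80, shared_markers=2)],
            self.lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["C"].partner_id == "B"  # two criteria beat coverage

    def test_equal_length_tie_purges_lexicographically_larger(self):
        lengths = {"A": 1_000, "B": 1_000}
        decisions = classify_haplotigs(
            [PairEvidence("B", "A", coverage=0.9)], lengths)
        by_id = {d.contig_id: d for d in decisions}
        assert by_id["A"].label == "primary"
        assert by_id["B"].label == "haplotig"

    def test_decisions_do_not_depend_on_evidence_order(self):
        evidence = [PairEvidence("B", "A", coverage=0.9),
                    PairEvidence("C", "B", coverage=0.9),
                    PairEvidence("C", "A", coverage=0.9)]
        base = classify_haplotigs(evidence, self.lengths)
        flipped = classify_haplotigs(evidence[::-1], self.lengths)
        assert base == flipped

    def test_raising_min_coverage_never_enlarges_purged_set(self):
        evidence = [PairEvidence("B", "A", coverage=0.75),
                    PairEvidence("C", "A", coverage=0.95)]
        purged = {}
        for thr in (0.5, 0.7, 0.9):
            decisions = classify_haplotigs(
                evidence, self.lengths, PurgeConfig(min_coverage=thr))
            purged[thr] = {d.contig_id for d in decisions
                           if d.label == "haplotig"}
        assert purged[0.9] <= purged[0.7] <= purged[0.5]


# ---------------------------------------------------------------------------
# output partition


def test_purge_assembly_conserves_every_base():
    contigs = {"A": Contig("A", "ACGT" * 250), "B": Contig("B", "ACGT" * 100)}
    decisions = classify_haplotigs(
        [PairEvidence("B", "A", coverage=0.9)],
        {cid: c.length for cid, c in contigs.items()})
    primary, haplotigs, report = purge_assembly(contigs, decisions)
    assert sum(c.length for c in primary + haplotigs) == 1_400
    assert {c.id for c in primary} | {c.id for c in haplotigs} == {"A", "B"}
    assert len(report) == len(contigs)


def test_purge_assembly_all_primary_keeps_everything():
    contigs = {"A": Contig("A", "ACGTACGT"), "B": Contig("B", "ACGT")}
    primary, haplotigs, report = purge_assembly(
        contigs, classify_haplotigs([], {"A": 8, "B": 4}))
    assert haplotigs == []
    assert {c.id for c in primary} == {"A", "B"}


def test_purge_assembly_missing_decision_is_integrity_error():
    contigs = {"A": Contig("A", "ACGT")}
    with pytest.raises(dio.IntegrityError, match="no decision"):
        purge_assembly(contigs, [])


# ---------------------------------------------------------------------------
# end-to-end on the simulated scene


def test_simulated_scene_purges_exactly_the_true_haplotigs(small_scene):
    ds = small_scene
    lengths = {cid: c.length for cid, c in ds.contigs.items()}
    evidence = build_pair_evidence(
        compute_pair_coverage(ds.contig_alignments, lengths),
        collinear_genes_map(ds.truth.gene_anchors, ds.truth.gene_matches),
        shared_single_copy_markers(ds.truth.marker_hits),
        lengths)
    decisions = classify_haplotigs(evidence, lengths)
    predicted = {d.contig_id: d.label for d in decisions}
    assert predicted == ds.truth.labels
    partners = {d.contig_id: d.partner_id for d in decisions
                if d.label == "haplotig"}
    assert partners == {h.contig_id: h.partner_id
                        for h in ds.truth.haplotigs}
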