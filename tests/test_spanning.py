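"""Anchor finding, span classification, and tract extraction."""

import collections

import numpy as np
import pytest

from repeatspan import (FULL_CLASSES, FULL_FWD, FULL_REV, NON_SPANNING,
                        PARTIAL_3P, PARTIAL_5P, RC_SWAP, classify_read,
                        classify_sequences, extract_tract, find_anchors,
                        generate_allele, generate_locus, simulate_reads)
from repeatspan.oracles import infix_edit_distance
from repeatspan.sequence import revcomp
from repeatspan.simulate import inject_errors
from repeatspan.spanning import AnchorHit, flank_anchors

CORE = "GGCCTG"


@pytest.fixture(scope="module")
def anchors(flanks):
    return flank_anchors(*flanks, anchor_len=30)


class TestFindAnchors:
    def test_exact_embedding(self, anchors):
        la, ra = anchors
        read = la + CORE * 10 + ra
        hits = find_anchors(read, la, ra, max_edit_fraction=0.0)
        plus = {h.which: h for h in hits if h.strand == "+"}
        assert plus["left"].read_start == 0
        assert plus["left"].read_end == 30
        assert plus["right"].read_start == 30 + 60
        assert plus["right"].read_end == 30 + 60 + 30
        assert all(h.edit_distance == 0 for h in plus.values())

    def test_reverse_complement_mirrored_hits(self, anchors):
        la, ra = anchors
        read = revcomp(la + CORE * 10 + ra)
        hits = find_anchors(read, la, ra, max_edit_fraction=0.0)
        minus = {h.which: h for h in hits if h.strand == "-"}
        # minus hits are reported on the rc'd read, i.e. original layout
        assert minus["left"].read_start == 0
        assert minus["right"].read_end == len(read)

    def test_anchor_longer_than_read_yields_no_hit(self, anchors):
        la, ra = anchors
        assert find_anchors("ACGTACGT", la, ra) == []

    def test_noisy_hits_match_bruteforce_infix_oracle(self, anchors):
        la, ra = anchors
        rng = np.random.default_rng(99)
        construct = la + CORE * 40 + ra
        for _ in range(10):
            read, _ = inject_errors(construct, 0.12, None, rng)
            hits = find_anchors(read, la, ra, max_edit_fraction=0.25)
            for h in hits:
                target = read if h.strand == "+" else revcomp(read)
                anchor = la if h.which == "left" else ra
                assert h.edit_distance == infix_edit_distance(anchor, target)


class TestClassifyRead:
    def mk(self, which, start, end, strand="+", ed=0):
        return AnchorHit(which=which, read_start=start, read_end=end,
                         edit_distance=ed, strand=strand)

    def test_both_plus_anchors_full_forward(self):
        hits = [self.mk("left", 0, 30), self.mk("right", 90, 120)]
        assert classify_read(hits, 120) == FULL_FWD

    def test_both_minus_anchors_full_reverse(self):
        hits = [self.mk("left", 0, 30, "-"), self.mk("right", 90, 120, "-")]
        assert classify_read(hits, 120) == FULL_REV

    def test_left_only_with_trailing_bases_is_5p(self):
        hits = [self.mk("left", 0, 30)]
        assert classify_read(hits, 330) == PARTIAL_5P

    def test_left_only_on_minus_is_3p(self):
        hits = [self.mk("left", 0, 30, "-")]
        assert classify_read(hits, 330) == PARTIAL_3P

    def test_right_only_is_3p_plus_5p_minus(self):
        assert classify_read([self.mk("right", 300, 330)], 330) == PARTIAL_3P
        assert classify_read([self.mk("right", 300, 330, "-")],
                             330) == PARTIAL_5P

    def test_no_bases_beyond_anchor_is_non_spanning(self):
        assert classify_read([self.mk("left", 0, 30)], 30) == NON_SPANNING
        assert classify_read([self.mk("right", 0, 30)], 30) == NON_SPANNING

    def test_contradictory_hits_non_spanning(self, caplog):
        hits = [self.mk("left", 90, 120), self.mk("right", 0, 30)]
        with caplog.at_level("WARNING"):
            assert classify_read(hits, 120) == NON_SPANNING
        assert "contradictory" in caplog.text


class TestExtractTract:
    def test_exact_construct(self, anchors):
        la, ra = anchors
        read = la + CORE * 10 + ra
        hits = find_anchors(read, la, ra, 0.0)
        assert extract_tract(read, hits, FULL_FWD) == CORE * 10

    def test_reverse_complement_normalization(self, anchors):
        la, ra = anchors
        fwd = la + CORE * 10 + ra
        rev = revcomp(fwd)
        hits = find_anchors(rev, la, ra, 0.0)
        assert extract_tract(rev, hits, FULL_REV) == CORE * 10

    def test_partial_extraction(self, anchors):
        la, ra = anchors
        read = la + CORE * 7  # runs off into the tract
        hits = find_anchors(read, la, ra, 0.0)
        assert extract_tract(read, hits, PARTIAL_5P) == CORE * 7


class TestAgainstSimulatorTruth:
    def test_error_free_classification_and_tracts(self, flanks):
        left, right = flanks
        allele = generate_allele(120, 0.05, seed=21)
        locus, iv = generate_locus(allele, left, right)
        reads = simulate_reads(locus, iv, coverage=15, error_rate=0.0,
                               seed=21, allele=allele)
        classified = classify_sequences(
            [(r.read_id, r.sequence) for r in reads], left, right)
        for got, want in zip(classified, reads):
            assert got.span_class == want.truth.span_class
            if got.span_class in FULL_CLASSES:
                assert got.tract == allele.tract

    def test_partition_and_involution(self, flanks, noisy_sample):
        left, right = flanks
        seqs = [(r.read_id, r.sequence) for r in noisy_sample.reads]
        fwd = classify_sequences(seqs, left, right)
        rev = classify_sequences([(i, revcomp(s)) for i, s in seqs],
                                 left, right)
        cf = collections.Counter(c.span_class for c in fwd)
        cr = collections.Counter(c.span_class for c in rev)
        assert sum(cf.values()) == len(seqs)  # partition: one class per read
        for cls, n in cf.items():
            assert cr[RC_SWAP[cls]] == n
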