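"""Tract tokenization, de-novo motif promotion, and nucleotide-ratio tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatspan import (DEFAULT_CATALOG, OTHER_LABEL, MotifRatioTable,
                        motif_ratios, rare_motif_labels, tokenize,
                        tokenize_sample, top_motifs)
from repeatspan.errors import DataError
from repeatspan.oracles import brute_tokenize_cost, enumerate_optimal_parses

CORE = DEFAULT_CATALOG.core
MOTIFS = DEFAULT_CATALOG.motifs


def _mutate(seq, n_subs, rng):
    seq = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1 + rng.integers(3)) % 4]
    return "".join(seq)


class TestTokenize:
    def test_pure_core_zero_cost(self):
        tk = tokenize(CORE * 3)
        assert tk.labels == (CORE,) * 3
        assert tk.total_cost == 0

    def test_exact_catalog_concatenation(self):
        tk = tokenize(CORE + "GGCTG" + CORE)  # 17 bp
        assert tk.labels == (CORE, "GGCTG", CORE)
        assert tk.total_cost == 0

    def test_empty_tract(self):
        tk = tokenize("")
        assert tk.tokens == ()

    def test_non_dna_rejected(self):
        with pytest.raises(DataError):
            tokenize("GGCXTG")

    def test_substituted_concatenation_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            gen = tuple(MOTIFS[i] for i in rng.integers(0, len(MOTIFS), 9))
            clean = "".join(gen)
            noisy = _mutate(clean, 1, rng)
            tk = tokenize(noisy)
            assert tk.total_cost == brute_tokenize_cost(noisy, MOTIFS)
            parses = enumerate_optimal_parses(noisy, MOTIFS)
            if len(parses) == 1:
                assert tk.labels == parses[0]
            else:
                assert tk.labels in parses

    def test_token_lengths_near_motif_lengths(self):
        rng = np.random.default_rng(23)
        gen = tuple(MOTIFS[i] for i in rng.integers(0, len(MOTIFS), 30))
        noisy = _mutate("".join(gen), 3, rng)
        for t in tokenize(noisy).tokens:
            if t.label != OTHER_LABEL:
                assert abs(t.length - len(t.label)) <= 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(MOTIFS), min_size=1, max_size=12),
           st.integers(0, 10**6))
    def test_tiling_conservation_property(self, gen, seed):
        rng = np.random.default_rng(seed)
        noisy = _mutate("".join(gen), min(2, len(gen)), rng)
        tk = tokenize(noisy)
        assert sum(t.length for t in tk.tokens) == len(noisy)
        assert tk.tokens[0].start == 0 and tk.tokens[-1].end == len(noisy)
        for a, b in zip(tk.tokens, tk.tokens[1:]):
            assert a.end == b.start

    def test_clean_parse_recovers_generating_tokens(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            gen = tuple(MOTIFS[i] for i in rng.integers(0, len(MOTIFS), 15))
            tk = tokenize("".join(gen))
            assert tk.total_cost == 0
            assert tk.labels == gen


class TestDeNovoPromotion:
    # Bases at the edges of an unassigned run can be tie-absorbed into
    # cost-capped near-core tokens, so the promotable segment is the
    # residual interior of the inserted run, not the full insert.

    def test_recurring_unassigned_segment_is_promoted(self):
        novel = "ATTATTAT"
        tracts = [CORE * 5 + novel + CORE * 5 for _ in range(3)]
        baseline, _ = tokenize_sample(tracts, DEFAULT_CATALOG, promote=False)
        tokenized, promoted = tokenize_sample(tracts, DEFAULT_CATALOG)
        assert promoted  # a recurring unassigned segment was promoted
        for label in promoted:
            assert 4 <= len(label) <= 8
            assert label in novel
        for before, after in zip(baseline, tokenized):
            assert set(promoted) & set(after.labels)
            assert after.unassigned_bases < before.unassigned_bases
            assert after.total_cost < before.total_cost

    def test_rare_segment_stays_other(self):
        novel = "ATTATTAT"
        tracts = [CORE * 5 + novel + CORE * 5] + [CORE * 10] * 4
        tokenized, promoted = tokenize_sample(tracts, DEFAULT_CATALOG)
        assert promoted == ()  # a single occurrence does not recur
        assert tokenized[0].unassigned_bases > 0


class TestRatios:
    def test_single_motif_is_all(self):
        table = motif_ratios([tokenize(CORE * 10)])
        assert table.percentages() == {CORE: 100.0}

    def test_two_motif_percentages(self):
        table = motif_ratios([tokenize(CORE + "GGCTG")])
        pct = table.percentages()
        assert pct[CORE] == pytest.approx(100 * 6 / 11, abs=0.005)
        assert pct["GGCTG"] == pytest.approx(100 * 5 / 11, abs=0.005)

    def test_normalization_sums_to_100(self, noisy_sample):
        # pooled over noisy tracts of a simulated sample
        tracts = []
        for r in noisy_sample.reads[:20]:
            if r.truth.span_class != "non_spanning":
                tracts.append(r.sequence[:300])
        tokenized, _ = tokenize_sample(tracts, DEFAULT_CATALOG)
        table = motif_ratios(tokenized)
        assert sum(table.percentages().values()) == pytest.approx(100.0,
                                                                  abs=0.01)
        for sub in (table.group(5), table.group(6), table.group(7)):
            if sub.nucleotide_counts:
                assert sum(sub.percentages().values()) == pytest.approx(
                    100.0, abs=0.01)

    def test_per_tract_scope(self):
        tables = motif_ratios([tokenize(CORE * 2), tokenize("GGCTG" * 2)],
                              scope="per_tract")
        assert len(tables) == 2
        assert tables[0].percentages() == {CORE: 100.0}
        assert tables[1].percentages() == {"GGCTG": 100.0}


class TestTopAndRare:
    def test_top_k_ordering(self):
        table = MotifRatioTable({CORE: 80, "GGCTG": 15, "GGCCG": 5})
        assert top_motifs(table, k=2) == [CORE, "GGCTG"]

    def test_length_filter_excludes_everything(self):
        table = MotifRatioTable({CORE: 60, "GGCTG": 40})
        assert top_motifs(table, length_filter=7) == []

    def test_length_filter_restricts_before_ranking(self):
        table = MotifRatioTable({CORE: 60, "GGCTG": 30, "GGCCG": 10})
        assert top_motifs(table, length_filter=5) == ["GGCTG", "GGCCG"]

    def test_ties_break_lexicographically(self):
        table = MotifRatioTable({"GGCTG": 10, "GGCCG": 10, CORE: 80})
        assert top_motifs(table, k=3) == [CORE, "GGCCG", "GGCTG"]

    def test_rare_labels_strict_threshold(self):
        table = MotifRatioTable({CORE: 992, "GGCCG": 8})   # 0.8%
        assert rare_motif_labels(table) == {"GGCCG"}
        table = MotifRatioTable({CORE: 990, "GGCCG": 10})  # exactly 1.0%
        assert rare_motif_labels(table) == set()
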