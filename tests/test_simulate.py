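"""Synthetic locus and read generator: allele structure, locus assembly,
error injection, and truth bookkeeping."""

import collections
import io as _io

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatspan import (DEFAULT_CATALOG, NON_SPANNING, SPAN_CLASSES,
                        generate_allele, generate_locus, random_flanks,
                        simulate_reads, simulate_sample)
from repeatspan.errors import DataError, ParameterError
from repeatspan.io import write_fastq
from repeatspan.sequence import revcomp

CORE = DEFAULT_CATALOG.core


class TestGenerateAllele:
    def test_no_interruptions_forces_pure_core(self):
        allele = generate_allele(4, 0.0, seed=1)
        assert allele.tokens == (CORE,) * 4
        assert allele.tract == CORE * 4
        assert allele.core_count == 4

    def test_expanded_allele_length_arithmetic(self):
        allele = generate_allele(650, 0.0, seed=7)
        assert allele.tract_length_bp == 3900
        assert allele.core_count == 650

    def test_interrupted_allele_core_count_vs_token_tally(self):
        allele = generate_allele(700, 0.2, seed=42)
        # oracle: direct tally of emitted tokens
        tally = collections.Counter(allele.tokens)
        assert allele.core_count == tally[CORE]
        assert len(allele.tokens) == round(700 / 0.8)
        # binomial 99% interval around 0.8 * token count
        n = len(allele.tokens)
        sd = (n * 0.8 * 0.2) ** 0.5
        assert abs(allele.core_count - 0.8 * n) <= 2.58 * sd
        # tract is the concatenation of tokens
        assert allele.tract == "".join(allele.tokens)
        assert allele.tract_length_bp == sum(map(len, allele.tokens))

    @pytest.mark.parametrize("kwargs", [
        {"n_core_target": 0},
        {"n_core_target": 10, "interruption_fraction": 1.0},
        {"n_core_target": 10, "interruption_fraction": -0.1},
        {"n_core_target": 10, "interruption_fraction": 0.5,
         "variant_weights": (0.5, 0.5, 0.5, 0.5)},
        {"n_core_target": 10, "variant_weights": (1.0,)},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            generate_allele(seed=0, **kwargs)


class TestGenerateLocus:
    def test_interval_arithmetic(self):
        flank = "ACGTACGTAC" * 5
        locus, interval = generate_locus(generate_allele(3, 0.0, seed=0),
                                         flank, flank)
        assert interval == (50, 68)
        assert locus[50:68] == CORE * 3

    def test_empty_flank_rejected(self):
        with pytest.raises((ParameterError, DataError)):
            generate_locus(generate_allele(3, 0.0, seed=0),
                           "ACGT" * 20, "")

    def test_flank_with_core_run_rejected(self):
        bad = "A" * 80 + CORE * 2 + "C" * 80
        with pytest.raises(ParameterError):
            generate_locus(generate_allele(3, 0.0, seed=0), bad, "ACGT" * 20)

    def test_random_flank_locus_length(self):
        left, right = random_flanks(200, seed=5)
        allele = generate_allele(80, 0.1, seed=5)
        locus, interval = generate_locus(allele, left, right)
        assert len(locus) == 400 + allele.tract_length_bp
        assert interval == (200, 200 + allele.tract_length_bp)
        assert CORE * 2 not in left and CORE * 2 not in right


@pytest.fixture(scope="module")
def locus(flanks):
    allele = generate_allele(100, 0.05, seed=3)
    left, right = flanks
    seq, iv = generate_locus(allele, left, right)
    return allele, seq, iv


class TestSimulateReads:
    def test_error_free_full_length_reads_reconstruct_locus(self, locus):
        allele, seq, iv = locus
        reads = simulate_reads(seq, iv, coverage=5,
                               read_length_model={"kind": "fixed",
                                                  "length": None},
                               error_rate=0.0, seed=5, allele=allele)
        for r in reads:
            assert r.sequence in (seq, revcomp(seq))
            assert r.truth.span_class in ("full_dGGCCTGn", "full_dGGCCTGr")
            assert (r.truth.span_class == "full_dGGCCTGr") == (r.strand == "-")
            assert r.truth.core_count == allele.core_count

    def test_realized_error_rate_matches_requested(self, locus):
        allele, seq, iv = locus
        reads = simulate_reads(seq, iv, coverage=110,
                               read_length_model={"kind": "fixed",
                                                  "length": None},
                               error_rate=0.12, seed=9, allele=allele)
        assert len(reads) >= 100
        rates = []
        for r in reads:
            obs = r.sequence if r.strand == "+" else revcomp(r.sequence)
            d = edlib.align(obs, seq, mode="NW")["editDistance"]
            rates.append(d / len(seq))
        assert abs(np.mean(rates) - 0.12) <= 0.02

    def test_all_minus_strand(self, locus):
        allele, seq, iv = locus
        reads = simulate_reads(seq, iv, coverage=3, strand_fraction=1.0,
                               error_rate=0.0, seed=2, allele=allele)
        assert all(r.strand == "-" for r in reads)

    def test_truth_conservation(self, noisy_sample):
        counts = collections.Counter(r.truth.span_class
                                     for r in noisy_sample.reads)
        assert set(counts) <= set(SPAN_CLASSES)
        assert sum(counts.values()) == len(noisy_sample.reads)
        assert counts[NON_SPANNING] < len(noisy_sample.reads)

    def test_seed_determinism_byte_identical_fastq(self, locus, tmp_path):
        allele, seq, iv = locus
        payloads = []
        for _ in range(2):
            reads = simulate_reads(seq, iv, coverage=3, error_rate=0.12,
                                   seed=77, allele=allele)
            out = tmp_path / f"run{len(payloads)}.fastq"
            write_fastq(out, reads)
            payloads.append(out.read_bytes())
        assert payloads[0] == payloads[1]

    def test_parameter_validation(self, locus):
        _, seq, iv = locus
        with pytest.raises(ParameterError):
            simulate_reads(seq, iv, coverage=0, seed=1)
        with pytest.raises(ParameterError):
            simulate_reads(seq, iv, error_rate=0.6, seed=1)
        with pytest.raises(ParameterError):
            simulate_reads(seq, iv, error_mix={"sub": 1.0, "ins": 0.5},
                           seed=1)


class TestCompositionRecovery:
    def test_variant_frequencies_within_multinomial_bounds(self):
        weights = (0.4, 0.3, 0.2, 0.1)
        allele = generate_allele(1200, 0.5, variant_weights=weights, seed=13)
        variants = [t for t in allele.tokens if t != CORE]
        assert len(variants) >= 1000 * 0.5  # enough draws
        counts = collections.Counter(variants)
        n = len(variants)
        for w, motif in zip(weights, DEFAULT_CATALOG.variants):
            sd = (n * w * (1 - w)) ** 0.5
            assert abs(counts[motif] - n * w) <= 3 * sd


class TestSimulateSample:
    def test_per_molecule_jitter_and_truth(self, flanks):
        left, right = flanks
        sample = simulate_sample("jit", left, right, mean_core=150,
                                 jitter_sd=25, coverage=12, error_rate=0.0,
                                 seed=3)
        cores = [a.core_count for a in sample.alleles.values()]
        assert len(set(cores)) > 1  # molecules genuinely differ
        # truth core count of a full-span read equals its molecule's count
        for r in sample.reads:
            if r.truth.span_class in ("full_dGGCCTGn", "full_dGGCCTGr"):
                assert r.truth.core_count == \
                    sample.alleles[r.truth.allele_id].core_count


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(1, 60), f=st.floats(0, 0.6), seed=st.integers(0, 10**6))
def test_allele_invariants_property(n, f, seed):
    allele = generate_allele(n, f, seed=seed)
    assert allele.tract == "".join(allele.tokens)
    assert allele.tract_length_bp == len(allele.tract)
    assert 0 <= allele.core_count <= len(allele.tokens)
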