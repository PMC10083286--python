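"""Ground-truthed simulation of an expanded, interrupted repeat locus read by
noisy CLR-like long reads.

The generator emulates the structure of an expanded SCA36-type allele: a long
tract of core GGCCTG units with occasional variant interruption units, framed
by unique flanking sequence.  Reads are fragments sampled uniformly from the
locus, optionally reverse complemented, and corrupted by i.i.d. per-base
substitution/insertion/deletion errors at a configurable total rate (CLR
single-pass reads run at roughly 11-15%).  Every read carries its ground
truth — source allele, span class, and true core-unit count — recorded
*before* error injection, so downstream classification and counting can be
scored exactly.

Somatic heterogeneity is emulated at the sample level: each sequenced
molecule draws its own core-unit count from a normal jitter around the
sample mean, so read-to-read repeat-number spread has both a biological
(jitter) and a technical (error) knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import DEFAULT_CATALOG, MotifCatalog
from .errors import ParameterError
from .sequence import require_dna, require_fraction, revcomp
from .spanclasses import (FULL_FWD, NON_SPANNING, PARTIAL_3P, PARTIAL_5P,
                          RC_SWAP)

#: Default split of the total error rate into substitution/insertion/deletion,
#: indel-dominant to match CLR error character.
DEFAULT_ERROR_MIX: Mapping[str, float] = {"sub": 0.25, "ins": 0.45, "del": 0.30}

#: Shortest read the length model will emit (bp), unless the locus is shorter.
MIN_READ_LENGTH = 500

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Alleles and loci


@dataclass(frozen=True)
class RepeatAllele:
    """One haplotype's repeat tract as an ordered list of motif tokens."""

    tokens: tuple[str, ...]
    core: str = DEFAULT_CATALOG.core
    allele_id: str = "allele"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def tract(self) -> str:
        return "".join(self.tokens)

    @property
    def tract_length_bp(self) -> int:
        return sum(len(t) for t in self.tokens)

    @property
    def core_count(self) -> int:
        return sum(1 for t in self.tokens if t == self.core)

    def token_intervals(self) -> list[tuple[str, int, int]]:
        """(motif, start, end) for each token, 0-based half-open on the tract."""
        out, pos = [], 0
        for t in self.tokens:
            out.append((t, pos, pos + len(t)))
            pos += len(t)
        return out


def generate_allele(n_core_target: int,
                    interruption_fraction: float = 0.0,
                    variant_weights: Sequence[float] | None = None,
                    seed: int | None = None,
                    catalog: MotifCatalog = DEFAULT_CATALOG,
                    allele_id: str = "allele") -> RepeatAllele:
    """Draw a repeat allele with ~``n_core_target`` core units.

    Tokens are i.i.d.: core with probability ``1 - interruption_fraction``,
    otherwise a variant drawn by ``variant_weights`` (uniform when omitted).
    The token count is ``round(n_core_target / (1 - interruption_fraction))``
    so the *expected* core count matches the target; the realized count is
    binomial.  Deterministic for a fixed seed.
    """
    if n_core_target < 1:
        raise ParameterError(f"n_core_target={n_core_target} must be >= 1")
    f = require_fraction(interruption_fraction, "interruption_fraction")
    if variant_weights is None:
        weights = np.full(len(catalog.variants), 1.0 / len(catalog.variants))
    else:
        weights = np.asarray(variant_weights, dtype=float)
        if weights.shape != (len(catalog.variants),):
            raise ParameterError(
                f"variant_weights needs {len(catalog.variants)} entries, "
                f"got {weights.shape}")
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0,
                                                   abs_tol=1e-9):
            raise ParameterError("variant_weights must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    n_tokens = max(1, round(n_core_target / (1.0 - f)))
    is_variant = rng.random(n_tokens) < f
    variant_idx = rng.choice(len(catalog.variants), size=n_tokens, p=weights)
    tokens = tuple(catalog.variants[variant_idx[i]] if is_variant[i]
                   else catalog.core for i in range(n_tokens))
    return RepeatAllele(tokens=tokens, core=catalog.core, allele_id=allele_id)


def validate_flank(flank: str, core: str, min_len: int = 30,
                   what: str = "flank") -> str:
    """Flanks must be long enough to anchor and free of core-motif runs."""
    require_dna(flank, what)
    if len(flank) < min_len:
        raise ParameterError(
            f"{what} length {len(flank)} < minimum anchor length {min_len}")
    if core * 2 in flank:
        raise ParameterError(
            f"{what} contains a run of >=2 core motifs; it cannot anchor "
            "the repeat boundary unambiguously")
    return flank


def generate_locus(allele: RepeatAllele, left_flank: str, right_flank: str,
                   min_flank: int = 30) -> tuple[str, tuple[int, int]]:
    """Embed the allele tract between flanks.

    Returns ``(locus, (start, end))`` with the repeat interval 0-based
    half-open: ``locus[start:end] == allele.tract``.
    """
    validate_flank(left_flank, allele.core, min_flank, "left_flank")
    validate_flank(right_flank, allele.core, min_flank, "right_flank")
    locus = left_flank + allele.tract + right_flank
    interval = (len(left_flank), len(left_flank) + allele.tract_length_bp)
    return locus, interval


def random_flanks(length: int = 200, seed: int = 0,
                  core: str = DEFAULT_CATALOG.core) -> tuple[str, str]:
    """Seed-fixed synthetic flank pair, guaranteed free of core-motif runs.

    These are synthetic stand-ins for the genomic context of a real locus
    (e.g. NOP56 intron 1); uniform random sequence is unique enough for
    anchoring at the default 30 bp anchor length.
    """
    rng = np.random.default_rng(seed)
    flanks = []
    while len(flanks) < 2:
        cand = "".join(rng.choice(list(_BASES), size=length))
        # a single core occurrence is tolerable; a run of two would break
        # boundary anchoring, and we also avoid lone occurrences for margin
        if core not in cand:
            flanks.append(cand)
    return flanks[0], flanks[1]


# ---------------------------------------------------------------------------
# Truth classes

def true_span_class(frag_start: int, frag_end: int, interval: tuple[int, int],
                    anchor_len: int = 30, max_edit_fraction: float = 0.25,
                    min_tract_bp: int = 1) -> str:
    """Ground-truth span class of an error-free fragment, + orientation.

    An anchor counts as present when the fragment covers it up to the edit
    allowance ``E = ceil(max_edit_fraction * anchor_len)``: a fragment whose
    end falls <= E bases inside an anchor still yields a legitimate anchor
    hit at edit distance <= E, so truth is defined at the same resolution as
    the classifier contract.
    """
    a, b = interval
    k = anchor_len
    e = math.ceil(max_edit_fraction * k)
    left_ok = frag_end >= a and frag_start <= a - k + e
    right_ok = frag_start <= b and frag_end >= b + k - e
    if left_ok and right_ok:
        return FULL_FWD
    if left_ok and min(frag_end, b) - a >= min_tract_bp:
        return PARTIAL_5P
    if right_ok and b - max(frag_start, a) >= min_tract_bp:
        return PARTIAL_3P
    return NON_SPANNING


def _true_core_count(allele: RepeatAllele, interval: tuple[int, int],
                     frag_start: int, frag_end: int) -> int:
    """Core tokens lying entirely inside the fragment's overlap with the tract."""
    a, _ = interval
    lo = max(frag_start, a) - a
    hi = min(frag_end, a + allele.tract_length_bp) - a
    if hi <= lo:
        return 0
    if lo == 0 and hi == allele.tract_length_bp:
        return allele.core_count
    return sum(1 for m, s, t in allele.token_intervals()
               if m == allele.core and s >= lo and t <= hi)


# ---------------------------------------------------------------------------
# Errors


def _normalize_mix(error_mix: Mapping[str, float] | None) -> tuple[float, float, float]:
    mix = dict(DEFAULT_ERROR_MIX if error_mix is None else error_mix)
    extra = set(mix) - {"sub", "ins", "del"}
    if extra:
        raise ParameterError(f"unknown error_mix keys: {sorted(extra)}")
    sub, ins, dele = (float(mix.get(k, 0.0)) for k in ("sub", "ins", "del"))
    if min(sub, ins, dele) < 0 or not math.isclose(sub + ins + dele, 1.0,
                                                   abs_tol=1e-9):
        raise ParameterError("error_mix fractions must be >= 0 and sum to 1")
    return sub, ins, dele


def inject_errors(seq: str, error_rate: float,
                  error_mix: Mapping[str, float] | None,
                  rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. per-base errors; returns (noisy sequence, #error events).

    Substitutions always change the base; insertions add one uniform random
    base after the current one; deletions drop the base.
    """
    require_fraction(error_rate, "error_rate", 0.0, 0.5)
    if error_rate == 0.0 or not seq:
        return seq, 0
    sub, ins, _ = _normalize_mix(error_mix)
    r = rng.random(len(seq))
    hit = np.nonzero(r < error_rate)[0]
    if hit.size == 0:
        return seq, 0
    kind_draw = rng.random(hit.size)
    rand_bases = rng.integers(0, 4, size=hit.size)  # for subs: offset 1..3
    sub_offsets = rng.integers(1, 4, size=hit.size)
    parts: list[str] = []
    prev = 0
    for j, i in enumerate(hit):
        parts.append(seq[prev:i])
        x = kind_draw[j]
        if x < sub:
            parts.append(_BASES[(_BASES.index(seq[i]) + sub_offsets[j]) % 4])
        elif x < sub + ins:
            parts.append(seq[i])
            parts.append(_BASES[rand_bases[j]])
        # else deletion: emit nothing
        prev = i + 1
    parts.append(seq[prev:])
    return "".join(parts), int(hit.size)


# ---------------------------------------------------------------------------
# Reads


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth recorded before error injection."""
    allele_id: str
    span_class: str
    core_count: int | None  # None for non-spanning reads


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    strand: str  # '+' or '-'
    truth: ReadTruth
    applied_error_rate: float


def _draw_read_length(model: Mapping | None, locus_len: int,
                      rng: np.random.Generator) -> int:
    lo = min(MIN_READ_LENGTH, locus_len)
    if model is None:
        model = {"kind": "lognormal"}
    kind = model.get("kind", "lognormal")
    if kind == "fixed":
        length = int(model.get("length") or locus_len)
        return max(1, min(length, locus_len))
    if kind == "lognormal":
        mean_log = model.get("mean_log")
        if mean_log is None:
            mean_log = math.log(0.75 * locus_len)
        sigma = float(model.get("sigma", 0.55))
        length = int(round(rng.lognormal(mean_log, sigma)))
        return max(lo, min(length, locus_len))
    raise ParameterError(f"unknown read_length_model kind {kind!r}")


def _sample_read(locus: str, interval: tuple[int, int], allele: RepeatAllele,
                 read_id: str, read_length_model: Mapping | None,
                 error_rate: float, error_mix: Mapping[str, float] | None,
                 strand_fraction: float, rng: np.random.Generator,
                 anchor_len: int, max_edit_fraction: float,
                 min_tract_bp: int) -> tuple[SimulatedRead, int]:
    length = _draw_read_length(read_length_model, len(locus), rng)
    start = int(rng.integers(0, len(locus) - length + 1))
    end = start + length
    fragment = locus[start:end]
    cls = true_span_class(start, end, interval, anchor_len,
                          max_edit_fraction, min_tract_bp)
    strand = "-" if rng.random() < strand_fraction else "+"
    if strand == "-":
        cls = RC_SWAP[cls]
    core_count = (None if cls == NON_SPANNING
                  else _true_core_count(allele, interval, start, end))
    noisy, n_ops = inject_errors(fragment, error_rate, error_mix, rng)
    if strand == "-":
        noisy = revcomp(noisy)
    read = SimulatedRead(
        read_id=read_id, sequence=noisy, strand=strand,
        truth=ReadTruth(allele.allele_id, cls, core_count),
        applied_error_rate=n_ops / len(fragment) if fragment else 0.0)
    return read, length


def simulate_reads(locus: str, interval: tuple[int, int],
                   coverage: float = 100.0,
                   read_length_model: Mapping | None = None,
                   error_rate: float = 0.12,
                   error_mix: Mapping[str, float] | None = None,
                   strand_fraction: float = 0.5,
                   seed: int | None = None,
                   allele: RepeatAllele | None = None,
                   anchor_len: int = 30, max_edit_fraction: float = 0.25,
                   min_tract_bp: int = 1,
                   read_prefix: str = "read") -> list[SimulatedRead]:
    """Sample noisy reads from a single locus until ``coverage``-fold bases.

    Fragments are placed uniformly; truth span class is computed from the
    fragment's placement relative to ``interval`` before errors are applied;
    with probability ``strand_fraction`` the read is reverse complemented
    (and its truth class swapped accordingly).  Deterministic per seed.
    """
    if coverage <= 0:
        raise ParameterError(f"coverage={coverage} must be > 0")
    require_fraction(strand_fraction, "strand_fraction", 0.0, 1.0,
                     inclusive_hi=True)
    _normalize_mix(error_mix)
    require_dna(locus, "locus")
    a, b = interval
    if not (0 <= a <= b <= len(locus)):
        raise ParameterError(f"repeat interval {interval} outside locus")
    if allele is None:
        # reconstruct a core-only token view of the tract for truth counting
        allele = RepeatAllele(
            tokens=_tokens_from_exact_tract(locus[a:b], DEFAULT_CATALOG))
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    total = 0
    target = coverage * len(locus)
    while total < target:
        read, length = _sample_read(
            locus, interval, allele, f"{read_prefix}{len(reads):05d}",
            read_length_model, error_rate, error_mix, strand_fraction, rng,
            anchor_len, max_edit_fraction, min_tract_bp)
        reads.append(read)
        total += length
    return reads


def _tokens_from_exact_tract(tract: str, catalog: MotifCatalog) -> tuple[str, ...]:
    """Greedy exact parse of a clean tract into catalog units (longest first);
    used only to recover token truth when a locus is supplied without its
    generating allele."""
    motifs = sorted(catalog.motifs, key=len, reverse=True)
    tokens: list[str] = []
    i = 0
    while i < len(tract):
        for m in motifs:
            if tract.startswith(m, i):
                tokens.append(m)
                i += len(m)
                break
        else:
            tokens.append(tract[i])
            i += 1
    return tuple(tokens)


# ---------------------------------------------------------------------------
# Sample-level simulation (per-molecule jitter)


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    reads: tuple[SimulatedRead, ...]
    alleles: Mapping[str, RepeatAllele] = field(default_factory=dict)

    @property
    def true_mean_core(self) -> float:
        """Mean true core count over spanning reads with full-tract truth."""
        vals = [r.truth.core_count for r in self.reads
                if r.truth.core_count is not None]
        return float(np.mean(vals)) if vals else float("nan")


def simulate_sample(sample_id: str, left_flank: str, right_flank: str,
                    mean_core: float = 790.0, jitter_sd: float = 150.0,
                    interruption_fraction: float = 0.02,
                    variant_weights: Sequence[float] | None = None,
                    coverage: float = 60.0,
                    read_length_model: Mapping | None = None,
                    error_rate: float = 0.12,
                    error_mix: Mapping[str, float] | None = None,
                    strand_fraction: float = 0.5,
                    seed: int | None = None,
                    catalog: MotifCatalog = DEFAULT_CATALOG,
                    anchor_len: int = 30, max_edit_fraction: float = 0.25,
                    min_tract_bp: int = 1,
                    min_core: int = 20) -> SimulatedSample:
    """Simulate one 'sample': many molecules, each with its own jittered allele.

    Each sequenced molecule draws a core-unit count from
    ``Normal(mean_core, jitter_sd)`` (truncated at ``min_core``), builds its
    own allele and locus, and contributes one fragment.  Molecules are drawn
    until the total sampled bases reach ``coverage`` times the nominal locus
    length.  This emulates the read-to-read repeat-number spread (somatic
    heterogeneity) seen in expanded-repeat carriers.
    """
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    f = require_fraction(interruption_fraction, "interruption_fraction")
    unit = len(catalog.core)
    nominal_locus = (len(left_flank) + len(right_flank)
                     + round(mean_core / (1.0 - f)) * unit)
    target = coverage * nominal_locus
    reads: list[SimulatedRead] = []
    alleles: dict[str, RepeatAllele] = {}
    total = 0
    while total < target:
        core_i = max(min_core, int(round(rng.normal(mean_core, jitter_sd))))
        allele_id = f"{sample_id}_mol{len(reads):05d}"
        allele = generate_allele(core_i, f, variant_weights,
                                 seed=int(rng.integers(2 ** 31)),
                                 catalog=catalog, allele_id=allele_id)
        locus, interval = generate_locus(allele, left_flank, right_flank)
        read, length = _sample_read(
            locus, interval, allele, f"{sample_id}_read{len(reads):05d}",
            read_length_model, error_rate, error_mix, strand_fraction, rng,
            anchor_len, max_edit_fraction, min_tract_bp)
        alleles[allele_id] = allele
        reads.append(read)
        total += length
    return SimulatedSample(sample_id=sample_id, reads=tuple(reads),
                           alleles=alleles)
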