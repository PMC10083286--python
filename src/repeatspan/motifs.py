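"""Tokenization of repeat tracts into motif units and nucleotide-ratio tables.

The tokenizer is a minimum-cost dynamic program over tract positions: each
step either consumes ``u`` bases (``unit_min <= u <= unit_max``) at the edit
distance to the best catalog motif (capped at ``max_unit_cost``), or falls
back to a single base at cost 1 labeled ``other``.  On a clean concatenation
of catalog motifs this reduces to exact parsing (total cost 0); under random
sequencing errors the cost cap lets a damaged unit still be recognized.
Cost ties are broken by preferring the core label, then the longer step,
then the lexicographically smaller label, so tokenizations are stable.

Segments that match no catalog motif but recur as identical unassigned runs
of catalog-like length (4-8 bp) at least three times in a sample are
promoted to de-novo motifs and the sample re-tokenized, mirroring how
observed Top-10 motif lists extend past the named variant units.

Nucleotide ratios follow the convention: the percentage of a motif is
100 x (nucleotides labeled with that motif) / (total nucleotides in scope),
either per tract or pooled over all full-length tracts of a sample; 5/6/7-nt
group tables re-normalize within the group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .catalog import DEFAULT_CATALOG, MotifCatalog, OTHER_LABEL
from .errors import ParameterError
from .sequence import require_dna

UNIT_MIN = 4
UNIT_MAX = 8
MAX_UNIT_COST = 2

_INF = 10 ** 9


@dataclass(frozen=True)
class Token:
    label: str
    start: int
    end: int
    cost: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TokenizedTract:
    """A tract tiled exactly by motif tokens plus 'other' runs."""

    tract: str
    tokens: tuple[Token, ...]

    @property
    def total_cost(self) -> int:
        return sum(t.cost for t in self.tokens)

    @property
    def unassigned_bases(self) -> int:
        return sum(t.length for t in self.tokens if t.label == OTHER_LABEL)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)

    def core_token_count(self, core: str) -> int:
        return sum(1 for t in self.tokens if t.label == core)

    def nucleotide_counts(self) -> Counter:
        c: Counter = Counter()
        for t in self.tokens:
            c[t.label] += t.length
        return c


class _SegmentScorer:
    """Memoized best-motif lookup for short segments (segments recur heavily
    in repeat tracts, so the cache hit rate is high)."""

    def __init__(self, motifs: Sequence[str], core: str,
                 max_unit_cost: int) -> None:
        self.motifs = tuple(motifs)
        self.core = core
        self.max_unit_cost = max_unit_cost
        self._cache: dict[str, tuple[int, str] | None] = {}

    def best(self, seg: str) -> tuple[int, str] | None:
        try:
            return self._cache[seg]
        except KeyError:
            pass
        u = len(seg)
        best: tuple[int, int, str] | None = None
        for m in self.motifs:
            if abs(len(m) - u) > self.max_unit_cost:
                continue
            if seg == m:
                d = 0
            else:
                d = edlib.align(seg, m, mode="NW",
                                k=self.max_unit_cost)["editDistance"]
                if d < 0:
                    continue
            key = (d, 0 if m == self.core else 1, m)
            if best is None or key < best:
                best = key
        out = None if best is None else (best[0], best[2])
        self._cache[seg] = out
        return out


def tokenize(tract: str, catalog: MotifCatalog = DEFAULT_CATALOG,
             unit_min: int = UNIT_MIN, unit_max: int = UNIT_MAX,
             max_unit_cost: int = MAX_UNIT_COST,
             extra_motifs: Sequence[str] = (),
             _scorer: _SegmentScorer | None = None) -> TokenizedTract:
    """Minimum-cost tiling of *tract* into catalog (+extra) motif tokens."""
    require_dna(tract, "tract", allow_empty=True)
    if tract == "":
        return TokenizedTract(tract="", tokens=())
    if not 1 <= unit_min <= unit_max:
        raise ParameterError("need 1 <= unit_min <= unit_max")
    scorer = _scorer or _SegmentScorer((*catalog.motifs, *extra_motifs),
                                       catalog.core, max_unit_cost)
    n = len(tract)
    dp = [0] + [_INF] * n
    # per position: (tie_key, predecessor, label, step_cost)
    back: list[tuple[tuple, int, str, int] | None] = [None] * (n + 1)
    fallback_key = (2, -1, OTHER_LABEL)
    for i in range(n):
        base = dp[i]
        if base >= _INF:
            continue
        # fallback: one base of 'other'
        j, c = i + 1, base + 1
        if c < dp[j] or (c == dp[j] and fallback_key < back[j][0]):
            dp[j] = c
            back[j] = (fallback_key, i, OTHER_LABEL, 1)
        hi = min(unit_max, n - i)
        for u in range(unit_min, hi + 1):
            hit = scorer.best(tract[i:i + u])
            if hit is None:
                continue
            cost, label = hit
            j, c = i + u, base + cost
            if c > dp[j]:
                continue
            key = (0 if label == scorer.core else 1, -u, label)
            if c < dp[j] or key < back[j][0]:
                dp[j] = c
                back[j] = (key, i, label, cost)
    # backtrack and merge consecutive 'other' steps into runs
    raw: list[Token] = []
    j = n
    while j > 0:
        _, i, label, cost = back[j]
        raw.append(Token(label=label, start=i, end=j, cost=cost))
        j = i
    raw.reverse()
    tokens: list[Token] = []
    for t in raw:
        if (tokens and t.label == OTHER_LABEL
                and tokens[-1].label == OTHER_LABEL
                and tokens[-1].end == t.start):
            prev = tokens.pop()
            tokens.append(Token(OTHER_LABEL, prev.start, t.end,
                                prev.cost + t.cost))
        else:
            tokens.append(t)
    return TokenizedTract(tract=tract, tokens=tuple(tokens))


def promote_novel_motifs(tracts: Iterable[str],
                         catalog: MotifCatalog = DEFAULT_CATALOG,
                         min_recurrence: int = 3,
                         unit_min: int = UNIT_MIN, unit_max: int = UNIT_MAX,
                         max_unit_cost: int = MAX_UNIT_COST) -> tuple[str, ...]:
    """Identify recurring unassigned segments eligible as de-novo motifs.

    A candidate is the literal sequence of an 'other' run of length 4-8
    that appears at least ``min_recurrence`` times across the sample.
    """
    counts: Counter = Counter()
    scorer = _SegmentScorer(catalog.motifs, catalog.core, max_unit_cost)
    for tract in tracts:
        tk = tokenize(tract, catalog, unit_min, unit_max, max_unit_cost,
                      _scorer=scorer)
        for t in tk.tokens:
            if t.label == OTHER_LABEL and UNIT_MIN <= t.length <= UNIT_MAX:
                counts[tract[t.start:t.end]] += 1
    return tuple(sorted(seg for seg, c in counts.items()
                        if c >= min_recurrence and seg not in catalog.motifs))


def tokenize_sample(tracts: Sequence[str],
                    catalog: MotifCatalog = DEFAULT_CATALOG,
                    promote: bool = True,
                    min_recurrence: int = 3,
                    **kw) -> tuple[list[TokenizedTract], tuple[str, ...]]:
    """Tokenize a sample's tracts with optional de-novo motif promotion."""
    promoted: tuple[str, ...] = ()
    if promote:
        promoted = promote_novel_motifs(tracts, catalog,
                                        min_recurrence=min_recurrence, **kw)
    scorer = _SegmentScorer((*catalog.motifs, *promoted), catalog.core,
                            kw.get("max_unit_cost", MAX_UNIT_COST))
    out = [tokenize(t, catalog, extra_motifs=promoted, _scorer=scorer, **kw)
           for t in tracts]
    return out, promoted


# ---------------------------------------------------------------------------
# Ratio tables


@dataclass(frozen=True)
class MotifRatioTable:
    """Per-motif nucleotide counts and percentages over one scope."""

    nucleotide_counts: dict[str, int] = field(default_factory=dict)
    scope: str = "pooled"

    @property
    def total_nt(self) -> int:
        return sum(self.nucleotide_counts.values())

    def percentages(self) -> dict[str, float]:
        tot = self.total_nt
        if tot == 0:
            return {}
        return {label: 100.0 * n / tot
                for label, n in self.nucleotide_counts.items()}

    def group(self, length: int) -> "MotifRatioTable":
        """Restrict to motifs of one length (re-normalized within group)."""
        sub = {label: n for label, n in self.nucleotide_counts.items()
               if label != OTHER_LABEL and len(label) == length}
        return MotifRatioTable(nucleotide_counts=sub,
                               scope=f"{self.scope}/{length}nt")


def motif_ratios(tokenized: Sequence[TokenizedTract],
                 scope: str = "pooled"
                 ) -> MotifRatioTable | list[MotifRatioTable]:
    """Nucleotide-ratio table(s): one pooled table, or one per tract."""
    if scope == "pooled":
        counts: Counter = Counter()
        for tk in tokenized:
            counts.update(tk.nucleotide_counts())
        return MotifRatioTable(nucleotide_counts=dict(counts), scope="pooled")
    if scope == "per_tract":
        return [MotifRatioTable(nucleotide_counts=dict(tk.nucleotide_counts()),
                                scope=f"tract{i}")
                for i, tk in enumerate(tokenized)]
    raise ParameterError(f"unknown scope {scope!r}")


def top_motifs(table: MotifRatioTable, k: int = 10,
               length_filter: int | None = None) -> list[str]:
    """Motif labels ranked by percentage (desc), ties lexicographic.

    ``length_filter`` restricts to motifs of that length before ranking;
    the 'other' pseudo-label is never ranked.
    """
    pct = table.percentages()
    labels = [lab for lab in pct if lab != OTHER_LABEL]
    if length_filter is not None:
        labels = [lab for lab in labels if len(lab) == length_filter]
    labels.sort(key=lambda lab: (-pct[lab], lab))
    return labels[:k]


def rare_motif_labels(table: MotifRatioTable,
                      threshold_pct: float = 1.0) -> set[str]:
    """Labels strictly below ``threshold_pct`` percent of the scope."""
    return {label for label, p in table.percentages().items()
            if p < threshold_pct}


def ratio_frame(table: MotifRatioTable) -> pd.DataFrame:
    """TSV-shaped view: label, length_nt, nucleotides, percent, group."""
    pct = table.percentages()
    rows = []
    for label in sorted(table.nucleotide_counts,
                        key=lambda lab: (-pct[lab], lab)):
        length = 0 if label == OTHER_LABEL else len(label)
        group = f"{length}nt" if length else OTHER_LABEL
        rows.append({"label": label, "length_nt": length,
                     "nucleotides": table.nucleotide_counts[label],
                     "percent": round(pct[label], 4), "group": group})
    return pd.DataFrame(rows, columns=["label", "length_nt", "nucleotides",
                                       "percent", "group"])


def tokens_frame(tokenized: Sequence[TokenizedTract],
                 read_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-token TSV: read_id, label, start, end, cost (0-based half-open)."""
    rows = []
    for i, tk in enumerate(tokenized):
        rid = read_ids[i] if read_ids is not None else f"tract{i}"
        for t in tk.tokens:
            rows.append({"read_id": rid, "label": t.label, "start": t.start,
                         "end": t.end, "cost": t.cost})
    return pd.DataFrame(rows, columns=["read_id", "label", "start", "end",
                                       "cost"])
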