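"""Anchor-based spanning-read classification and tract extraction.

Instead of genome-scale alignment, each read is probed for the innermost K
bp of the left and right flanks (the "anchors") by semi-global (infix)
alignment, on the read and on its reverse complement.  The pattern of anchor
hits determines the span class:

* both anchors on '+'  -> full_dGGCCTGn (forward full span)
* both anchors on '-'  -> full_dGGCCTGr (reverse full span)
* left anchor only     -> 5p partial on '+', 3p partial on '-'
* right anchor only    -> 3p partial on '+', 5p partial on '-'
* otherwise            -> non_spanning

Minus-strand hits are reported in coordinates of the reverse-complemented
read, so for every hit the repeat tract lies to the right of the left anchor
and to the left of the right anchor.  Extracted tracts are therefore always
reported 5'->3' in the repeat's + orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import edlib

from .errors import ParameterError
from .sequence import require_dna, require_fraction, revcomp
from .spanclasses import (FULL_FWD, FULL_REV, NON_SPANNING, PARTIAL_3P,
                          PARTIAL_5P)

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_LEN = 30
DEFAULT_MAX_EDIT_FRACTION = 0.25


@dataclass(frozen=True)
class AnchorHit:
    """One flank-anchor match on a (possibly reverse-complemented) read.

    ``read_start``/``read_end`` are 0-based half-open on the read as given
    for '+' hits, and on the reverse-complemented read for '-' hits.
    """

    which: str          # 'left' or 'right'
    read_start: int
    read_end: int
    edit_distance: int
    strand: str         # '+' or '-'


@dataclass(frozen=True)
class SpanClassifiedRead:
    read_id: str
    span_class: str
    strand: str | None          # strand carrying the anchors; None if none
    tract: str | None           # present iff span_class != non_spanning
    anchors: tuple[AnchorHit, ...]


def max_edits(anchor_len: int, max_edit_fraction: float) -> int:
    require_fraction(max_edit_fraction, "max_edit_fraction", 0.0, 0.5)
    return math.ceil(max_edit_fraction * anchor_len)


def find_anchors(read: str, left_anchor: str, right_anchor: str,
                 max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION
                 ) -> list[AnchorHit]:
    """Best infix alignment of each anchor against the read and its reverse
    complement.

    A hit is reported iff its edit distance is within
    ``ceil(max_edit_fraction * anchor_len)``; at most one hit per
    (anchor, strand) — the minimum-distance one, ties broken by leftmost
    read start.  An anchor longer than the read yields no hit.
    """
    require_dna(read, "read")
    hits: list[AnchorHit] = []
    for strand, target in (("+", read), ("-", revcomp(read))):
        for which, anchor in (("left", left_anchor), ("right", right_anchor)):
            require_dna(anchor, f"{which} anchor")
            if len(anchor) > len(target):
                continue
            k = max_edits(len(anchor), max_edit_fraction)
            res = edlib.align(anchor, target, mode="HW", task="locations", k=k)
            dist = res["editDistance"]
            if dist < 0:
                continue
            start, end = min(
                ((s if s is not None else 0), e) for s, e in res["locations"])
            hits.append(AnchorHit(which=which, read_start=start,
                                  read_end=end + 1, edit_distance=dist,
                                  strand=strand))
    return hits


def _select_strand(hits: Sequence[AnchorHit]) -> tuple[str | None, dict]:
    """Pick the strand whose hits explain the read best: prefer two anchors,
    then lower total edit distance."""
    by_strand: dict[str, dict[str, AnchorHit]] = {}
    for h in hits:
        slot = by_strand.setdefault(h.strand, {})
        prev = slot.get(h.which)
        if prev is None or (h.edit_distance, h.read_start) < (
                prev.edit_distance, prev.read_start):
            slot[h.which] = h
    if not by_strand:
        return None, {}
    best = min(by_strand.items(),
               key=lambda kv: (-len(kv[1]),
                               sum(h.edit_distance for h in kv[1].values()),
                               kv[0]))
    return best[0], best[1]


def classify_read(hits: Sequence[AnchorHit], read_length: int,
                  min_tract_bp: int = 1) -> str:
    """Map anchor hits to a span class (see module docstring for the table).

    Partial classes additionally require at least ``min_tract_bp`` read
    bases beyond the anchor's inner end.  Contradictory double hits (left
    anchor landing right of the right anchor on one strand) are logged and
    classified non_spanning.
    """
    strand, slot = _select_strand(hits)
    if strand is None:
        return NON_SPANNING
    left, right = slot.get("left"), slot.get("right")
    if left is not None and right is not None:
        if left.read_end > right.read_start:
            logger.warning(
                "contradictory anchor hits (left at %d-%d, right at %d-%d); "
                "classifying non_spanning", left.read_start, left.read_end,
                right.read_start, right.read_end)
            return NON_SPANNING
        return FULL_FWD if strand == "+" else FULL_REV
    if left is not None:
        if read_length - left.read_end >= min_tract_bp:
            return PARTIAL_5P if strand == "+" else PARTIAL_3P
        return NON_SPANNING
    assert right is not None
    if right.read_start >= min_tract_bp:
        return PARTIAL_3P if strand == "+" else PARTIAL_5P
    return NON_SPANNING


def extract_tract(read: str, hits: Sequence[AnchorHit],
                  span_class: str) -> str:
    """Read segment between/beyond the anchor inner ends, normalized to the
    repeat's + orientation (reverse complemented first for '-' hits)."""
    if span_class == NON_SPANNING:
        raise ParameterError("cannot extract a tract from a non-spanning read")
    strand, slot = _select_strand(hits)
    if strand is None:
        raise ParameterError("no anchor hits to extract a tract from")
    seq = read if strand == "+" else revcomp(read)
    left, right = slot.get("left"), slot.get("right")
    if left is not None and right is not None:
        if right.read_start < left.read_end:
            logger.warning("negative-length tract segment; returning empty")
            return ""
        return seq[left.read_end:right.read_start]
    if left is not None:
        return seq[left.read_end:]
    assert right is not None
    return seq[:right.read_start]


def flank_anchors(left_flank: str, right_flank: str,
                  anchor_len: int = DEFAULT_ANCHOR_LEN) -> tuple[str, str]:
    """The innermost ``anchor_len`` bp of each flank."""
    if anchor_len < 1:
        raise ParameterError("anchor_len must be >= 1")
    if len(left_flank) < anchor_len or len(right_flank) < anchor_len:
        raise ParameterError(
            f"flanks shorter than anchor length {anchor_len}")
    return left_flank[-anchor_len:], right_flank[:anchor_len]


def classify_sequences(reads: Sequence[tuple[str, str]],
                       left_flank: str, right_flank: str,
                       anchor_len: int = DEFAULT_ANCHOR_LEN,
                       max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
                       min_tract_bp: int = 1) -> list[SpanClassifiedRead]:
    """Classify (read_id, sequence) pairs against a flank pair."""
    left_anchor, right_anchor = flank_anchors(left_flank, right_flank,
                                              anchor_len)
    out: list[SpanClassifiedRead] = []
    for read_id, seq in reads:
        hits = find_anchors(seq, left_anchor, right_anchor, max_edit_fraction)
        cls = classify_read(hits, len(seq), min_tract_bp)
        strand, _ = _select_strand(hits)
        tract = None
        if cls != NON_SPANNING:
            tract = extract_tract(seq, hits, cls)
        out.append(SpanClassifiedRead(read_id=read_id, span_class=cls,
                                      strand=strand, tract=tract,
                                      anchors=tuple(hits)))
    return out
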