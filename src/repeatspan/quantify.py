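"""Core-repeat counting, the pathogenic threshold, and per-sample summaries.

A read's repeat number is the count of tokens labeled with the core motif in
the tokenizer's minimum-cost tiling of its extracted tract, which reduces to
non-overlapping exact counting on clean tracts while degrading gracefully
when sequencing errors fall inside a unit.  An ``exact`` counting mode
(left-greedy non-overlapping exact matches) is kept for comparison.

The per-sample summary mirrors the standard spanning-read report: total
spanning subreads, how many exceed the pathogenic threshold (>650 core
units for SCA36), that count as a percentage of all spanning subreads, and
min/mean/max tract length and repeat number over full-length subreads.
Percentages are rounded half-up to 2 decimals and means to the nearest
integer, matching how such tables are conventionally printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .catalog import DEFAULT_CATALOG, MotifCatalog
from .motifs import tokenize
from .sequence import require_dna
from .spanclasses import FULL_CLASSES, FULL_FWD, FULL_REV, SPANNING_CLASSES

logger = logging.getLogger(__name__)

PATHOGENIC_THRESHOLD = 650


def count_core_repeats(tract: str, core: str = DEFAULT_CATALOG.core,
                       catalog: MotifCatalog | None = None,
                       mode: str = "dp") -> int:
    """Number of core units in *tract*.

    ``dp`` mode counts tokens labeled with the core in the catalog
    tokenization (interruption variants keep their own labels); ``exact``
    mode counts left-greedy non-overlapping exact occurrences.
    """
    require_dna(tract, "tract", allow_empty=True)
    if tract == "":
        return 0
    if mode == "exact":
        return tract.count(core)
    if mode != "dp":
        raise ValueError(f"unknown count mode {mode!r}")
    if catalog is None:
        catalog = (DEFAULT_CATALOG if core == DEFAULT_CATALOG.core
                   else MotifCatalog(core=core, variants=()))
    return tokenize(tract, catalog).core_token_count(core)


def is_pathogenic(core_count: int,
                  threshold: int = PATHOGENIC_THRESHOLD) -> bool:
    """Strictly more than *threshold* core units (the >650 rule)."""
    if core_count < 0:
        raise ValueError("core_count must be >= 0")
    return core_count > threshold


def round_half_up(x: float | Decimal, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pathogenic_ratio(n_over: int, subread_number: int) -> float:
    """100 x n_over / subread_number, half-up to 2 decimals."""
    if subread_number == 0:
        return 0.0
    ratio = Decimal(100) * Decimal(n_over) / Decimal(subread_number)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassifiedTract:
    """One spanning read's contribution to quantification."""
    read_id: str
    span_class: str
    tract_length_bp: int
    core_count: int


@dataclass(frozen=True)
class SampleRepeatSummary:
    """One row of the per-sample spanning-read report."""

    sample_id: str
    subread_number: int          # all spanning classes
    n_pathogenic: int            # spanning reads with core count > threshold
    ratio_pathogenic: float      # percent, 2 dp
    full_count: int              # forward + reverse full spans
    full_forward: int
    full_reverse: int
    max_length_bp: int
    mean_length_bp: int
    min_length_bp: int
    max_repeats: int
    mean_repeats: int
    min_repeats: int


def summarize_sample(records: Sequence[ClassifiedTract], sample_id: str,
                     threshold: int = PATHOGENIC_THRESHOLD
                     ) -> SampleRepeatSummary:
    """Fold per-read classifications into one summary row.

    The pathogenic numerator and the denominator both run over all spanning
    classes (full + partial, either strand); length and repeat-number
    min/mean/max are restricted to full-length tracts.
    """
    spanning = [r for r in records if r.span_class in SPANNING_CLASSES]
    full = [r for r in spanning if r.span_class in FULL_CLASSES]
    if not spanning:
        logger.warning("sample %s has no spanning reads; summary is zeros",
                       sample_id)
        return SampleRepeatSummary(sample_id, 0, 0, 0.0, 0, 0, 0,
                                   0, 0, 0, 0, 0, 0)
    n_path = sum(1 for r in spanning if is_pathogenic(r.core_count, threshold))
    lengths = [r.tract_length_bp for r in full]
    repeats = [r.core_count for r in full]
    def _mean(v):  # printed as integers
        return int(round_half_up(sum(v) / len(v))) if v else 0
    return SampleRepeatSummary(
        sample_id=sample_id,
        subread_number=len(spanning),
        n_pathogenic=n_path,
        ratio_pathogenic=pathogenic_ratio(n_path, len(spanning)),
        full_count=len(full),
        full_forward=sum(1 for r in full if r.span_class == FULL_FWD),
        full_reverse=sum(1 for r in full if r.span_class == FULL_REV),
        max_length_bp=max(lengths, default=0),
        mean_length_bp=_mean(lengths),
        min_length_bp=min(lengths, default=0),
        max_repeats=max(repeats, default=0),
        mean_repeats=_mean(repeats),
        min_repeats=min(repeats, default=0),
    )


#: Printed column order of the per-sample report.
SUMMARY_COLUMNS = [
    "Sample ID", "Subread number", "dGGCCTG 650+", "dGGCCTG 650+ ratio",
    "Full dGGCCTGn", "Max length (bp)", "Mean length (bp)", "Min length (bp)",
    "Max number of repeats", "Mean number of repeats", "Min number of repeats",
    "Full reverse (debug)",
]


def summaries_frame(summaries: Sequence[SampleRepeatSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "Sample ID": s.sample_id,
            "Subread number": s.subread_number,
            "dGGCCTG 650+": s.n_pathogenic,
            "dGGCCTG 650+ ratio": f"{s.ratio_pathogenic:.2f}",
            "Full dGGCCTGn": s.full_count,
            "Max length (bp)": s.max_length_bp,
            "Mean length (bp)": s.mean_length_bp,
            "Min length (bp)": s.min_length_bp,
            "Max number of repeats": s.max_repeats,
            "Mean number of repeats": s.mean_repeats,
            "Min number of repeats": s.min_repeats,
            "Full reverse (debug)": s.full_reverse,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
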