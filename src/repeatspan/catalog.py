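"""The repeat-unit catalog: one core motif plus variant interruption units.

The default catalog describes the SCA36 locus: a GGCCTG hexanucleotide core
interrupted by the variant units GGCTG, GGCCCTG, GGCCG and GGCCTTG that are
observed interspersed in expanded NOP56 intron-1 alleles.  The catalog also
carries the display colors used by the waterfall schematics; motifs outside
the catalog (de-novo promoted units) receive colors from a deterministic
palette keyed by a CRC of the label, so figures are stable across runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ParameterError
from .sequence import is_dna

CORE_MOTIF = "GGCCTG"
VARIANT_MOTIFS = ("GGCTG", "GGCCCTG", "GGCCG", "GGCCTTG")

#: Label used for bases the tokenizer cannot assign to any catalog motif.
OTHER_LABEL = "other"

DEFAULT_COLORS: Mapping[str, str] = {
    "GGCCTG": "#1f77b4",   # core: blue
    "GGCTG": "#ff7f0e",
    "GGCCCTG": "#2ca02c",
    "GGCCG": "#d62728",
    "GGCCTTG": "#9467bd",
    OTHER_LABEL: "#7f7f7f",
}

# Fallback cycle for labels without an explicit color (de-novo motifs).
_PALETTE = (
    "#8c564b", "#e377c2", "#bcbd22", "#17becf", "#aec7e8",
    "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5", "#c49c94",
)

MIN_MOTIF_LEN = 4
MAX_MOTIF_LEN = 8


@dataclass(frozen=True)
class MotifCatalog:
    """The core repeat unit and its variant interruption units.

    Invariants enforced at construction: the core is non-empty uppercase
    ACGT; variants are distinct, none equal to the core; every motif length
    lies in [4, 8].
    """

    core: str = CORE_MOTIF
    variants: tuple[str, ...] = VARIANT_MOTIFS
    colors: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        for m in (self.core, *self.variants):
            if not is_dna(m):
                raise ParameterError(f"motif {m!r} is not uppercase ACGT")
            if not MIN_MOTIF_LEN <= len(m) <= MAX_MOTIF_LEN:
                raise ParameterError(
                    f"motif {m!r} length {len(m)} outside "
                    f"[{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}]")
        if len(set(self.variants)) != len(self.variants):
            raise ParameterError("variant motifs are not distinct")
        if self.core in self.variants:
            raise ParameterError("core motif duplicated in variants")

    @property
    def motifs(self) -> tuple[str, ...]:
        """Core first, then variants, in declaration order."""
        return (self.core, *self.variants)

    def color_for(self, label: str) -> str:
        """Display color for *label*; deterministic palette fallback."""
        try:
            return self.colors[label]
        except KeyError:
            return _PALETTE[zlib.crc32(label.encode()) % len(_PALETTE)]


DEFAULT_CATALOG = MotifCatalog()
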