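"""Small DNA-string helpers used throughout the package.

All sequences are plain uppercase ACGT Python strings; all coordinates are
0-based half-open.
"""

from __future__ import annotations

from .errors import DataError, ParameterError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_DNA = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _DNA


def require_dna(seq: str, what: str = "sequence", allow_empty: bool = False) -> str:
    """Validate that *seq* is uppercase ACGT; raise :class:`DataError` otherwise."""
    if seq == "":
        if allow_empty:
            return seq
        raise DataError(f"{what} is empty")
    if not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise DataError(f"{what} contains non-ACGT characters: {bad}")
    return seq


def require_fraction(x: float, what: str, lo: float = 0.0, hi: float = 1.0,
                     inclusive_hi: bool = False) -> float:
    ok = lo <= x < hi or (inclusive_hi and x == hi)
    if not ok:
        bound = "]" if inclusive_hi else ")"
        raise ParameterError(f"{what}={x!r} outside [{lo}, {hi}{bound}")
    return float(x)
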