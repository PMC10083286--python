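"""Independent brute-force reference implementations used for validation.

These deliberately avoid the production code paths (edlib, the bottom-up
tokenizer DP): edit distances are computed with hand-rolled dynamic
programs, and tokenizations by top-down recursion over all tilings.  They
are quadratic/exponential and intended only for small validation instances.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance, full DP table."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def infix_edit_distance(query: str, target: str) -> int:
    """Minimum edit distance of *query* against any infix of *target*
    (semi-global: free gaps at both target ends), row-vectorized DP."""
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    n = len(t)
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)          # free start in target
    for ca in query.encode():
        cur = np.empty_like(prev)
        cur[0] = prev[0] + 1                        # deletion from query
        mismatch = (t != ca).astype(np.int64)
        cur[1:] = np.minimum(prev[:-1] + mismatch, prev[1:] + 1)
        # horizontal (insertion) relax: cur[j] = min_k<=j cur[k] + (j - k)
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx)
        prev = cur
    return int(prev.min())                          # free end in target


def brute_tokenize_cost(tract: str, motifs: tuple[str, ...],
                        unit_min: int = 4, unit_max: int = 8,
                        max_unit_cost: int = 2) -> int:
    """Minimum total cost over all tilings of *tract*, by memoized recursion.

    A step either consumes u in [unit_min, unit_max] bases at the cheapest
    motif's edit distance (if <= max_unit_cost), or consumes 1 base at cost
    1 (the 'other' fallback).  Mirrors the tokenizer's cost model through an
    independent implementation.
    """

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i == len(tract):
            return 0
        out = 1 + best(i + 1)
        for u in range(unit_min, unit_max + 1):
            if i + u > len(tract):
                break
            seg = tract[i:i + u]
            c = min((edit_distance(seg, m) for m in motifs
                     if abs(len(m) - u) <= max_unit_cost),
                    default=max_unit_cost + 1)
            if c <= max_unit_cost:
                out = min(out, c + best(i + u))
        return out

    return best(0)


def enumerate_optimal_parses(tract: str, motifs: tuple[str, ...],
                             unit_min: int = 4, unit_max: int = 8,
                             max_unit_cost: int = 2,
                             limit: int = 10000) -> list[tuple[str, ...]]:
    """All minimum-cost tilings as label tuples ('other' for fallback steps).

    Exponential; use only on short tracts.  Stops after *limit* parses.
    """
    target = brute_tokenize_cost(tract, motifs, unit_min, unit_max,
                                 max_unit_cost)

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i == len(tract):
            return 0
        out = 1 + best(i + 1)
        for u in range(unit_min, unit_max + 1):
            if i + u > len(tract):
                break
            seg = tract[i:i + u]
            c = min((edit_distance(seg, m) for m in motifs
                     if abs(len(m) - u) <= max_unit_cost),
                    default=max_unit_cost + 1)
            if c <= max_unit_cost:
                out = min(out, c + best(i + u))
        return out

    parses: list[tuple[str, ...]] = []

    def walk(i: int, cost: int, labels: tuple[str, ...]) -> None:
        if len(parses) >= limit:
            return
        if i == len(tract):
            if cost == target:
                parses.append(labels)
            return
        if cost + best(i) > target:
            return
        walk(i + 1, cost + 1, labels + ("other",))
        for u in range(unit_min, unit_max + 1):
            if i + u > len(tract):
                break
            seg = tract[i:i + u]
            for m in motifs:
                if abs(len(m) - u) > max_unit_cost:
                    continue
                c = edit_distance(seg, m)
                if c <= max_unit_cost:
                    walk(i + u, cost + c, labels + (m,))

    walk(0, 0, ())
    # collapse duplicate label tuples from distinct motif/segment pairings
    return sorted(set(parses))
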