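"""Two-pass geometric seed filter.

Each seed has a *surrounding area*: seeds of the same query, same reference
fragment and same strand, at most ``z`` bases away parallel to the diagonal
and at most ``w`` bases ahead along the reference.  After sorting the seeds,
pass 1 removes every seed whose successor is NOT in its surrounding area
(this deletes isolated seeds and the tail of every cluster); pass 2 rescans
the survivors and removes every seed whose new successor IS in its
surrounding area (collapsing each cluster onto one representative).  A seed
with no successor counts as "successor not in area" in both passes.

The net effect: a chain of n >= 2 seeds linked successor-to-successor yields
exactly one representative (the chain's second-to-last member) and isolated
seeds vanish, which is what keeps the number of banded extensions small.
The filter is purely geometric — no chaining scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .seeding import SEED_DTYPE, Seed


@dataclass(frozen=True)
class SurroundingArea:
    """z: tolerance across diagonals; w: look-ahead along the reference."""

    z: int = 16
    w: int = 64

    def __post_init__(self) -> None:
        if self.z < 0 or self.w < 1:
            raise ParameterError(f"need z >= 0 and w >= 1, got z={self.z}, w={self.w}")


_SORT_FIELDS = ("query_ordinal", "ref_ordinal", "strand", "ref_offset", "diagonal")


def sort_seeds(seeds: np.ndarray) -> np.ndarray:
    """Stable sort by (query, reference fragment, strand, ref position, diagonal)."""
    if len(seeds) == 0:
        return seeds.copy()
    order = np.lexsort(tuple(seeds[f] for f in reversed(_SORT_FIELDS)))
    return seeds[order]


def _is_sorted(seeds: np.ndarray) -> bool:
    if len(seeds) < 2:
        return True
    cols = [seeds[f].astype(np.int64) for f in _SORT_FIELDS]
    prev = np.zeros(len(seeds) - 1, dtype=bool)  # strictly-greater flag so far
    ok = np.ones(len(seeds) - 1, dtype=bool)
    for col in cols:
        ok &= prev | (col[:-1] <= col[1:])
        prev = prev | (col[:-1] < col[1:])
    return bool(ok.all())


def in_surrounding_area(a: Seed, b: Seed, area: SurroundingArea) -> bool:
    """True iff b lies in a's surrounding area (b strictly ahead on the reference)."""
    if (a.query_ordinal, a.ref_ordinal, a.strand) != (b.query_ordinal, b.ref_ordinal, b.strand):
        return False
    if abs(b.diagonal - a.diagonal) > area.z:
        return False
    return 0 < b.ref_offset - a.ref_offset <= area.w


def _successor_in_area(seeds: np.ndarray, area: SurroundingArea) -> np.ndarray:
    """Vectorised in_surrounding_area(seeds[i], seeds[i+1]); last element False."""
    n = len(seeds)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    a, b = seeds[:-1], seeds[1:]
    same_group = (
        (a["query_ordinal"] == b["query_ordinal"])
        & (a["ref_ordinal"] == b["ref_ordinal"])
        & (a["strand"] == b["strand"])
    )
    d_ref = b["ref_offset"] - a["ref_offset"]
    d_diag = np.abs(b["diagonal"] - a["diagonal"])
    flags[:-1] = same_group & (d_diag <= area.z) & (0 < d_ref) & (d_ref <= area.w)
    return flags


def reduce_seeds(seeds: np.ndarray, area: SurroundingArea) -> np.ndarray:
    """Apply the two passes to a sorted seed array; returns the representatives.

    Pass 2 operates on the re-linked list remaining after pass 1 (successor =
    next surviving seed), so a cluster's surviving members collapse onto one.
    Raises :class:`InputError` if the input is not in :func:`sort_seeds` order.
    """
    if len(seeds) == 0:
        return seeds.copy()
    if not _is_sorted(seeds):
        raise InputError("reduce_seeds requires sort_seeds order")
    keep1 = _successor_in_area(seeds, area)
    survivors = seeds[keep1]
    keep2 = ~_successor_in_area(survivors, area)
    return survivors[keep2]
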