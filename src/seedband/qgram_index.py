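"""Read-only q-gram index backed by sorted arrays.

The index maps 2-bit packed k-mer keys to the positions at which they occur
in a batch of reference fragments.  Unlike a hash table it stores the
key/value pairs in a pair of co-sorted arrays (the *data array*), plus an
*index array* made of the deduplicated keys, a per-key occurrence count
(``cell_size``) and the exclusive prefix sum of those counts (``gateway``).
Memory therefore scales with the number of stored k-mer occurrences, never
with the size of the key space, which is what allows k up to 31 with 64-bit
keys.

Lookups are binary searches on the deduplicated key array; a present key's
values occupy ``sorted_values[gateway : gateway + cell_size]``.  Keys that
occur more often than the repeat threshold have their ``cell_size`` zeroed
(the gateway keeps the pre-masking prefix sums), so over-represented
(repetitive) k-mers silently stop producing matches.

Construction and batched lookup are expressed as sorts, binary searches and
exclusive prefix sums only — all data-parallel primitives — and are realised
here with vectorised numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

#: Sentinel key for windows containing a non-ACGT letter.  Such windows have
#: no 2-bit encoding and are dropped before the index ever sees them.
AMBIGUOUS: int = -1

MAX_K = 31

# 256-entry byte -> 2-bit code table; 4 marks every non-ACGT byte.
_CODE_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i


def encode_kmer(window: str, k: int) -> int:
    """Pack a k-base window into an integer, 2 bits per base, A=0 C=1 G=2 T=3.

    The first base is most significant.  Returns :data:`AMBIGUOUS` if the
    window contains any non-ACGT character.
    """
    if not 1 <= k <= MAX_K:
        raise ParameterError(f"k must be in [1, {MAX_K}], got {k}")
    if len(window) != k:
        raise InputError(f"window length {len(window)} != k={k}")
    value = 0
    for ch in window.upper():
        code = _CODE_TABLE[ord(ch) & 0xFF]
        if code > 3:
            return AMBIGUOUS
        value = (value << 2) | int(code)
    return value


def encode_sequence_kmers(residues: str, k: int, step: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Encode every k-mer of ``residues`` at offsets 0, step, 2*step, ...

    Returns ``(keys, offsets)`` with ambiguous windows already removed.
    Vectorised: the packed code is built by k shifted accumulations over the
    whole byte array rather than per-window loops.
    """
    if not 1 <= k <= MAX_K:
        raise ParameterError(f"k must be in [1, {MAX_K}], got {k}")
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    n = len(residues)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = _CODE_TABLE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n_windows = n - k + 1
    keys = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for t in range(k):
        col = codes[t : t + n_windows]
        keys = (keys << 2) | np.where(col > 3, 0, col)
        valid &= col <= 3
    offsets = np.arange(0, n_windows, step, dtype=np.int64)
    keys = keys[offsets]
    valid = valid[offsets]
    return keys[valid], offsets[valid]


def exclusive_prefix_sum(counts: np.ndarray) -> np.ndarray:
    """out[0] = 0; out[i] = out[i-1] + counts[i-1]."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size and counts.min() < 0:
        raise InputError("counts must be non-negative")
    out = np.zeros_like(counts)
    if counts.size:
        np.cumsum(counts[:-1], out=out[1:])
    return out


@dataclass
class ReadOnlyQGramIndex:
    """Sorted-array k-mer index (data array + index array).

    ``sorted_values`` is an (n, 2) int64 array of position records
    ``(sequence_ordinal, offset)`` co-sorted with ``sorted_keys``;
    construction uses a stable sort so ties keep reference scan order.
    """

    sorted_keys: np.ndarray
    sorted_values: np.ndarray
    nonredundant_keys: np.ndarray
    cell_size: np.ndarray
    gateway: np.ndarray
    k: int
    p: int = 1
    repeat_threshold: int = field(default=np.iinfo(np.int64).max)

    @property
    def n_stored(self) -> int:
        return len(self.sorted_keys)

    @property
    def n_distinct(self) -> int:
        return len(self.nonredundant_keys)

    @property
    def n_masked(self) -> int:
        return int(np.count_nonzero(self.cell_size == 0))


def build_index(
    keys: np.ndarray,
    values: np.ndarray,
    k: int,
    p: int = 1,
    repeat_threshold: int | None = None,
) -> ReadOnlyQGramIndex:
    """Build the read-only index from parallel key/value arrays.

    The caller must already have dropped ambiguous keys.  ``values`` may be
    any array whose first axis parallels ``keys`` (the search pipeline passes
    (n, 2) position records).  ``gateway`` is the exclusive prefix sum of the
    pre-masking occurrence counts; masking afterwards zeroes ``cell_size``
    entries above the repeat threshold, which leaves the value slices of all
    unmasked keys valid.
    """
    keys = np.asarray(keys, dtype=np.int64)
    values = np.asarray(values)
    if len(keys) != len(values):
        raise InputError(f"{len(keys)} keys vs {len(values)} values")
    if repeat_threshold is None:
        repeat_threshold = np.iinfo(np.int64).max
    if repeat_threshold < 1:
        raise ParameterError(f"repeat_threshold must be >= 1, got {repeat_threshold}")
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    sorted_values = values[order]
    nonredundant_keys, counts = np.unique(sorted_keys, return_counts=True)
    gateway = exclusive_prefix_sum(counts)
    cell_size = np.where(counts > repeat_threshold, 0, counts)
    return ReadOnlyQGramIndex(
        sorted_keys=sorted_keys,
        sorted_values=sorted_values,
        nonredundant_keys=nonredundant_keys,
        cell_size=cell_size.astype(np.int64),
        gateway=gateway,
        k=k,
        p=p,
        repeat_threshold=repeat_threshold,
    )


def lookup(index: ReadOnlyQGramIndex, query_key: int) -> tuple[int, int]:
    """Binary-search one key; returns ``(gateway, cell_size)``.

    An absent key returns cell_size 0 (its gateway is meaningless and also 0).
    The matching values are ``index.sorted_values[gateway : gateway + cell_size]``.
    """
    pos = int(np.searchsorted(index.nonredundant_keys, query_key, side="left"))
    if pos == len(index.nonredundant_keys) or index.nonredundant_keys[pos] != query_key:
        return 0, 0
    return int(index.gateway[pos]), int(index.cell_size[pos])


def batch_lookup(
    index: ReadOnlyQGramIndex,
    query_keys: np.ndarray,
    query_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Look up many keys at once with prefix-sum result placement.

    Returns ``(query_value_out, matched_value_out)``: for query i, its block
    of matches occupies rows ``write_index[i] : write_index[i] + cell_size[i]``
    where ``write_index`` is the exclusive prefix sum of the per-query cell
    sizes; within a block, matches appear in ``sorted_values`` order.
    """
    query_keys = np.asarray(query_keys, dtype=np.int64)
    query_values = np.asarray(query_values)
    if len(query_keys) != len(query_values):
        raise InputError(f"{len(query_keys)} query keys vs {len(query_values)} query values")
    nq = len(query_keys)
    if nq == 0 or index.n_distinct == 0:
        empty_q = query_values[:0]
        empty_m = index.sorted_values[:0]
        return empty_q, empty_m
    pos = np.searchsorted(index.nonredundant_keys, query_keys, side="left")
    pos_clipped = np.minimum(pos, index.n_distinct - 1)
    present = index.nonredundant_keys[pos_clipped] == query_keys
    got_cell = np.where(present, index.cell_size[pos_clipped], 0)
    got_gateway = np.where(present, index.gateway[pos_clipped], 0)
    write_index = exclusive_prefix_sum(got_cell)
    total = int(write_index[-1] + got_cell[-1]) if nq else 0
    # Gather: row r of the result belongs to query q(r) and to the
    # (r - write_index[q])-th stored value of that query's key.
    query_row = np.repeat(np.arange(nq), got_cell)
    within = np.arange(total) - np.repeat(write_index, got_cell)
    value_row = np.repeat(got_gateway, got_cell) + within
    return query_values[query_row], index.sorted_values[value_row]
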