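"""Seed generation: k-mer extraction and index lookup on both strands.

A *seed* is an exact k-mer correspondence between a query position and a
reference position.  Reference k-mers are taken with a sliding window of k
and a stride of p; query k-mers always use stride 1.  Reverse-strand seeds
are found by reverse-complementing the query (cheaper than the reference);
their ``query_offset`` is expressed on the reverse-complemented sequence and
converted to forward-query coordinates only when hits are reported.

Internally seeds live in a numpy structured array (:data:`SEED_DTYPE`) so the
reduction stage can sort and scan them vectorised; :class:`Seed` is the
one-record view used in tests and at the extension boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .qgram_index import ReadOnlyQGramIndex, batch_lookup, encode_sequence_kmers
from .sequence_io import ReferenceFragment, SequenceRecord, reverse_complement

FORWARD = 0
REVERSE = 1

SEED_DTYPE = np.dtype(
    [
        ("query_ordinal", np.int64),
        ("query_offset", np.int64),
        ("ref_ordinal", np.int64),
        ("ref_offset", np.int64),
        ("strand", np.int64),
        ("diagonal", np.int64),
    ]
)


@dataclass(frozen=True)
class Seed:
    """One exact k-mer correspondence; ``diagonal = ref_offset - query_offset``."""

    query_ordinal: int
    query_offset: int
    ref_ordinal: int
    ref_offset: int
    strand: int = FORWARD

    @property
    def diagonal(self) -> int:
        return self.ref_offset - self.query_offset


def seeds_to_array(seeds: list[Seed]) -> np.ndarray:
    arr = np.empty(len(seeds), dtype=SEED_DTYPE)
    for i, s in enumerate(seeds):
        arr[i] = (s.query_ordinal, s.query_offset, s.ref_ordinal, s.ref_offset, s.strand, s.diagonal)
    return arr


def array_to_seeds(arr: np.ndarray) -> list[Seed]:
    return [
        Seed(int(r["query_ordinal"]), int(r["query_offset"]), int(r["ref_ordinal"]),
             int(r["ref_offset"]), int(r["strand"]))
        for r in arr
    ]


def extract_reference_kmers(
    fragments: list[ReferenceFragment], k: int, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """k-mers along each fragment at stride p.

    Returns ``(keys, values)`` where ``values`` is an (n, 2) array of
    ``(fragment_ordinal, offset)`` position records.  Windows containing a
    non-ACGT letter are omitted — the 2-bit packing has no code for them.
    Fragment ordinals follow load order, which is how seeds refer back to
    their fragment.
    """
    if p < 1:
        raise ParameterError(f"p must be >= 1, got {p}")
    all_keys = []
    all_values = []
    for ordinal, frag in enumerate(fragments):
        keys, offsets = encode_sequence_kmers(frag.residues, k, step=p)
        values = np.empty((len(keys), 2), dtype=np.int64)
        values[:, 0] = ordinal
        values[:, 1] = offsets
        all_keys.append(keys)
        all_values.append(values)
    if not all_keys:
        return np.empty(0, dtype=np.int64), np.empty((0, 2), dtype=np.int64)
    return np.concatenate(all_keys), np.concatenate(all_values)


def extract_query_kmers(record: SequenceRecord, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of the query at stride 1; a query shorter than k yields nothing."""
    return encode_sequence_kmers(record.residues, k, step=1)


def find_seeds(
    index: ReadOnlyQGramIndex,
    queries: list[SequenceRecord],
    strand_policy: str = "both",
    k: int | None = None,
) -> np.ndarray:
    """Search every query against the index and materialise seeds.

    Under ``strand_policy="both"`` each query is additionally searched as its
    reverse complement; those seeds carry ``strand=REVERSE`` with offsets on
    the reverse-complemented sequence.  Masked (repeat) k-mers yield no seeds
    because their cell_size is zero in the index.
    """
    if strand_policy not in ("both", "forward_only"):
        raise ParameterError(f"unknown strand_policy {strand_policy!r}")
    if k is not None and k != index.k:
        raise ParameterError(f"k mismatch: index built with k={index.k}, requested {k}")
    k = index.k

    strands = (FORWARD,) if strand_policy == "forward_only" else (FORWARD, REVERSE)
    qkeys_all = []
    qvals_all = []
    for ordinal, record in enumerate(queries):
        for strand in strands:
            residues = record.residues if strand == FORWARD else reverse_complement(record.residues)
            keys, offsets = encode_sequence_kmers(residues, k, step=1)
            vals = np.empty((len(keys), 3), dtype=np.int64)
            vals[:, 0] = ordinal
            vals[:, 1] = offsets
            vals[:, 2] = strand
            qkeys_all.append(keys)
            qvals_all.append(vals)
    if not qkeys_all:
        return np.empty(0, dtype=SEED_DTYPE)
    query_keys = np.concatenate(qkeys_all)
    query_values = np.concatenate(qvals_all)
    q_out, m_out = batch_lookup(index, query_keys, query_values)
    seeds = np.empty(len(q_out), dtype=SEED_DTYPE)
    seeds["query_ordinal"] = q_out[:, 0]
    seeds["query_offset"] = q_out[:, 1]
    seeds["strand"] = q_out[:, 2]
    seeds["ref_ordinal"] = m_out[:, 0]
    seeds["ref_offset"] = m_out[:, 1]
    seeds["diagonal"] = seeds["ref_offset"] - seeds["query_offset"]
    return seeds
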