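"""End-to-end search orchestration.

The run is organised as a nest of batches: references are split into
fragments no longer than ``L`` (overlapping so no alignment is lost at a
boundary), fragments are grouped into batches by total residue count, and an
index is built fresh for each reference batch — there is no preprocessed
on-disk database.  Queries are processed in batches against every reference
batch; seeds are found, reduced, extended and filtered, fragment coordinates
are lifted back to parent coordinates, and duplicates arising inside
fragment overlaps are collapsed.  The final hit set is invariant to the
batch structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .banded_alignment import BandSpec, Hit, ScoringScheme, banded_extend, filter_hits
from .errors import ParameterError
from .qgram_index import build_index
from .seed_reduction import SurroundingArea, reduce_seeds, sort_seeds
from .seeding import FORWARD, REVERSE, Seed, extract_reference_kmers, find_seeds
from .sequence_io import SequenceRecord, reverse_complement, split_reference

logger = logging.getLogger("seedband")


@dataclass
class SearchConfig:
    """Every user-adjustable knob of the search.

    k and p control seeding sensitivity/speed; z and w define the seed
    surrounding area; L and overlap control reference splitting; the repeat
    threshold masks over-represented k-mers; evalue/min_aln_length filter
    hits; mode chooses glocal vs local extension.  ``band_half_width=None``
    couples the extension band to the cluster tolerance as ``z + k``.
    ``overlap=None`` defaults to twice the longest query seen (fallback
    2,000), so a single read's alignment never spans two fragment boundaries.
    """

    k: int = 16
    p: int = 4
    z: int = 16
    w: int = 64
    L: int = 64_000_000
    overlap: int | None = None
    repeat_threshold: int = 1000
    evalue_threshold: float = 1e-3
    min_aln_length: int = 30
    mode: str = "global"
    strand_policy: str = "both"
    band_half_width: int | None = None
    reference_batch_residues: int = 64_000_000
    query_batch_count: int = 100_000
    rng_seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ParameterError(f"k must be in [1, 31], got {self.k}")
        if self.p < 1:
            raise ParameterError("p must be >= 1")
        if self.z < 0 or self.w < 1:
            raise ParameterError("need z >= 0 and w >= 1")
        if self.L < 1:
            raise ParameterError("L must be >= 1")
        if self.overlap is not None and self.L <= self.overlap:
            raise ParameterError("need L > overlap")
        if self.mode not in ("global", "local"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.strand_policy not in ("both", "forward_only"):
            raise ParameterError(f"unknown strand_policy {self.strand_policy!r}")
        if self.reference_batch_residues < 1 or self.query_batch_count < 1:
            raise ParameterError("batch sizes must be >= 1")

    @property
    def effective_band(self) -> BandSpec:
        hw = self.band_half_width if self.band_half_width is not None else self.z + self.k
        return BandSpec(half_width=hw)

    def effective_overlap(self, queries: list[SequenceRecord]) -> int:
        if self.overlap is not None:
            return self.overlap
        longest = max((q.length for q in queries), default=0)
        ov = max(2 * longest, 2000)
        return min(ov, self.L - 1)


def _batch(items: list, sizer, limit: int) -> Iterable[list]:
    batch: list = []
    total = 0
    for item in items:
        size = sizer(item)
        if batch and total + size > limit:
            yield batch
            batch, total = [], 0
        batch.append(item)
        total += size
    if batch:
        yield batch


def run_search(
    queries: list[SequenceRecord],
    references: list[SequenceRecord],
    config: SearchConfig,
) -> list[Hit]:
    """Run the full seed-reduce-extend-filter pipeline; returns filtered hits.

    Hits carry parent-reference coordinates and forward-query coordinates;
    E-values use the total residue count of all references as the database
    length.  Output order: query input order, then descending score (with a
    full deterministic tie-break).
    """
    if not queries or not references:
        return []
    overlap = config.effective_overlap(queries)
    fragments = []
    for rec in references:
        fragments.extend(split_reference(rec, config.L, overlap))
    parent_length = {rec.id: rec.length for rec in references}
    database_length = sum(r.length for r in references)
    band = config.effective_band
    area = SurroundingArea(z=config.z, w=config.w)
    qlen = {q.id: q.length for q in queries}
    rc_cache: dict[int, str] = {}

    dedup: dict[tuple, Hit] = {}
    for ref_batch in _batch(fragments, lambda f: f.length, config.reference_batch_residues):
        keys, values = extract_reference_kmers(ref_batch, config.k, config.p)
        index = build_index(keys, values, config.k, config.p, config.repeat_threshold)
        logger.info(
            "reference batch: %d fragments, %d k-mers indexed, %d distinct, %d masked",
            len(ref_batch), index.n_stored, index.n_distinct, index.n_masked,
        )
        for q_start in range(0, len(queries), config.query_batch_count):
            q_batch = queries[q_start : q_start + config.query_batch_count]
            seeds = find_seeds(index, q_batch, config.strand_policy)
            seeds = sort_seeds(seeds)
            reps = reduce_seeds(seeds, area)
            logger.info(
                "query batch at %d: %d seeds, %d representatives",
                q_start, len(seeds), len(reps),
            )
            n_raw = 0
            batch_hits: list[Hit] = []
            for rep in reps:
                q_ord = int(rep["query_ordinal"])
                record = q_batch[q_ord]
                strand = int(rep["strand"])
                if strand == FORWARD:
                    q_res = record.residues
                else:
                    key = q_start + q_ord
                    if key not in rc_cache:
                        rc_cache[key] = reverse_complement(record.residues)
                    q_res = rc_cache[key]
                frag = ref_batch[int(rep["ref_ordinal"])]
                seed = Seed(
                    query_ordinal=q_ord,
                    query_offset=int(rep["query_offset"]),
                    ref_ordinal=int(rep["ref_ordinal"]),
                    ref_offset=int(rep["ref_offset"]),
                    strand=strand,
                )
                hit = banded_extend(
                    q_res,
                    frag.residues,
                    seed,
                    config.k,
                    mode=config.mode,
                    band=band,
                    scoring=config.scoring,
                    query_id=record.id,
                    ref_id=frag.parent_id,
                    database_length=database_length,
                )
                if hit is None:
                    continue
                # Alignments truncated by an artificial fragment edge are
                # dropped: the overlap guarantees the intact alignment is
                # found untruncated in the neighbouring fragment (for
                # alignments shorter than the overlap).
                cut_left = frag.parent_offset > 0 and hit.r_start == 0
                cut_right = (
                    frag.parent_offset + frag.length < parent_length[frag.parent_id]
                    and hit.r_end == frag.length
                )
                if cut_left or cut_right:
                    continue
                n_raw += 1
                # lift fragment -> parent coordinates
                hit.r_start += frag.parent_offset
                hit.r_end += frag.parent_offset
                # lift searched-strand -> forward-query coordinates
                if strand == REVERSE:
                    n = record.length
                    hit.q_start, hit.q_end = n - hit.q_end, n - hit.q_start
                batch_hits.append(hit)
            kept = filter_hits(batch_hits, config.evalue_threshold, config.min_aln_length)
            logger.info("extended %d hits, %d pass filters", n_raw, len(kept))
            for hit in kept:
                key = (
                    hit.query_id, hit.ref_parent_id, hit.strand,
                    hit.r_start, hit.r_end, hit.q_start, hit.q_end,
                )
                old = dedup.get(key)
                if old is None or hit.score > old.score:
                    dedup[key] = hit

    order = {q.id: i for i, q in enumerate(queries)}
    hits = sorted(
        dedup.values(),
        key=lambda h: (
            order[h.query_id], -h.score, h.evalue, h.ref_parent_id,
            h.r_start, h.r_end, h.strand, h.q_start,
        ),
    )
    return hits


def select_best_nonself_hits(
    hits: list[Hit], origin: Mapping[str, str] | None = None
) -> dict[str, Hit]:
    """Best non-self hit per query.

    ``origin`` maps query id to its source reference id; hits to the source
    are discarded first (queries missing from the mapping keep everything).
    The best of the remainder is chosen by highest score, then lowest
    E-value, then lexicographically lowest reference id, then lowest
    reference start — the last two are pure tie-breaks for determinism.
    """
    origin = origin or {}
    best: dict[str, Hit] = {}
    for hit in hits:
        if origin.get(hit.query_id) == hit.ref_parent_id:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: Hit) -> tuple:
    return (-hit.score, hit.evalue, hit.ref_parent_id, hit.r_start)


def write_tabular(hits: Iterable[Hit], stream: IO) -> None:
    """12-column BLAST-style tabular output.

    Columns: query id, subject id, % identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, evalue, bit score.
    Coordinates are 1-based inclusive; reverse-strand hits report subject
    start > end.
    """
    for h in hits:
        if h.strand == REVERSE:
            s_start, s_end = h.r_end, h.r_start + 1
        else:
            s_start, s_end = h.r_start + 1, h.r_end
        stream.write(
            "\t".join(
                (
                    h.query_id,
                    h.ref_parent_id,
                    f"{100.0 * h.identity:.2f}",
                    str(h.aln_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start + 1),
                    str(h.q_end),
                    str(s_start),
                    str(s_end),
                    f"{h.evalue:.2e}",
                    f"{h.bitscore:.1f}",
                )
            )
            + "\n"
        )


def read_tabular(stream: IO) -> list[Hit]:
    """Parse hits written by :func:`write_tabular` (inverse, minus rounding)."""
    hits = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        q_start = int(f[6]) - 1
        q_end = int(f[7])
        s1, s2 = int(f[8]), int(f[9])
        if s1 > s2:
            strand, r_start, r_end = REVERSE, s2 - 1, s1
        else:
            strand, r_start, r_end = FORWARD, s1 - 1, s2
        hits.append(
            Hit(
                query_id=f[0],
                ref_parent_id=f[1],
                strand=strand,
                q_start=q_start,
                q_end=q_end,
                r_start=r_start,
                r_end=r_end,
                score=0,
                identity=float(f[2]) / 100.0,
                aln_length=int(f[3]),
                mismatches=int(f[4]),
                gap_opens=int(f[5]),
                evalue=float(f[10]),
                bitscore=float(f[11]),
            )
        )
    return hits
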