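"""Synthetic metagenomic communities and taxonomic-assignment evaluation.

The generator emulates the structure of a read-vs-reference-genome
benchmark: a set of labelled genomes grouped into genera, and query reads
sampled as fragments of those genomes.  Each genus descends from its own
random ancestral sequence; genomes within a genus are independent per-base
substitution mutants of that ancestor, so same-genus genomes share high
identity while different genera are unrelated.  Reads are drawn uniformly
over genomes, positions and strands, and may optionally carry i.i.d.
per-base substitution errors (fragments are error-free by default, matching
a benchmark that retrieves fragments verbatim).

Evaluation follows the best-non-self-hit protocol: hits of a read to its own
source genome are removed, the best remaining hit assigns a genus, and the
quality measure is the CGA ratio — correct genus assignments divided by
total reported hits.  A threshold sweep re-runs the evaluation after
discarding hits below an identity threshold and a query-coverage threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .banded_alignment import Hit
from .errors import ParameterError
from .pipeline import select_best_nonself_hits
from .sequence_io import SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunityParams:
    """Shape and divergence of the synthetic community.

    Rates are per-base substitution probabilities in [0, 0.5].  Genomes in a
    genus are each mutated from the genus ancestor at ``intra_rate`` (so two
    siblings differ at roughly twice that rate); genus ancestors are
    independent random sequences.  ``error_rate`` mutates the sampled reads
    and defaults to 0 — fragments retrieved verbatim.
    """

    n_genera: int = 5
    genomes_per_genus: int = 3
    genome_length: int = 100_000
    intra_rate: float = 0.05
    inter_rate: float = 0.5
    read_length: int = 100
    n_reads: int = 1000
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("intra_rate", "inter_rate", "error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.5:
                raise ParameterError(f"{name} must be in [0, 0.5], got {rate}")
        if self.genome_length < self.read_length:
            raise ParameterError("genome_length must be >= read_length")
        if self.n_genera < 1 or self.genomes_per_genus < 1 or self.n_reads < 0:
            raise ParameterError("community counts must be positive")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    residues: str
    true_genome_id: str
    true_genus: str
    true_offset: int
    true_strand: str  # "+" or "-"


@dataclass
class SyntheticCommunity:
    genomes: list[tuple[str, str, str]]  # (genome_id, genus_label, residues)
    reads: list[ReadTruth]
    params: CommunityParams
    rng_seed: int

    @property
    def genus_of(self) -> dict[str, str]:
        return {gid: genus for gid, genus, _ in self.genomes}

    @property
    def origin(self) -> dict[str, str]:
        return {r.read_id: r.true_genome_id for r in self.reads}

    def genome_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=gid, residues=res, description=genus)
                for gid, genus, res in self.genomes]

    def read_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=r.read_id, residues=r.residues) for r in self.reads]


@dataclass(frozen=True)
class EvaluationResult:
    """CGA-ratio summary: correct genus assignments / total reported hits."""

    total_reported_hits: int
    correct_genus_assignments: int

    @property
    def cga_ratio(self) -> float:
        if self.total_reported_hits == 0:
            return 0.0
        return self.correct_genus_assignments / self.total_reported_hits


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``.

    A substituted base always changes (drawn from the three other bases).
    """
    if rate <= 0.0:
        return seq.copy()
    out = seq.copy()
    sites = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(sites):
        # add 1..3 (mod 4) in code space so the base always changes
        codes = np.searchsorted(_BASES, out[sites])
        out[sites] = _BASES[(codes + rng.integers(1, 4, size=len(sites))) % 4]
    return out


def generate_community(params: CommunityParams, rng_seed: int = 0) -> SyntheticCommunity:
    """Build genomes and sample reads, fully reproducible from ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    genomes: list[tuple[str, str, str]] = []
    genome_arrays: list[np.ndarray] = []
    for g in range(params.n_genera):
        genus = f"genus{g:02d}"
        ancestor = _random_sequence(rng, params.genome_length)
        for s in range(params.genomes_per_genus):
            arr = _mutate(rng, ancestor, params.intra_rate)
            gid = f"{genus}_genome{s:02d}"
            genomes.append((gid, genus, arr.tobytes().decode("ascii")))
            genome_arrays.append(arr)

    n_genomes = len(genomes)
    reads: list[ReadTruth] = []
    pad = max(5, len(str(max(params.n_reads, 1))))
    for i in range(params.n_reads):
        gi = int(rng.integers(0, n_genomes))
        gid, genus, _ = genomes[gi]
        offset = int(rng.integers(0, params.genome_length - params.read_length + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        frag = genome_arrays[gi][offset : offset + params.read_length]
        frag = _mutate(rng, frag, params.error_rate)
        residues = frag.tobytes().decode("ascii")
        if strand == "-":
            residues = reverse_complement(residues)
        reads.append(
            ReadTruth(
                read_id=f"read{i:0{pad}d}",
                residues=residues,
                true_genome_id=gid,
                true_genus=genus,
                true_offset=offset,
                true_strand=strand,
            )
        )
    return SyntheticCommunity(genomes=genomes, reads=reads, params=params, rng_seed=rng_seed)


def evaluate_assignment(
    best: dict[str, Hit],
    community: SyntheticCommunity,
) -> EvaluationResult:
    """Score a best-non-self-hit table against the community's genus truth."""
    genus_of = community.genus_of
    true_genus = {r.read_id: r.true_genus for r in community.reads}
    total = 0
    correct = 0
    for read_id, hit in best.items():
        total += 1
        if genus_of.get(hit.ref_parent_id) == true_genus.get(read_id):
            correct += 1
    return EvaluationResult(total_reported_hits=total, correct_genus_assignments=correct)


def _coverage(hit: Hit, query_length: int) -> float:
    return (hit.q_end - hit.q_start) / query_length


def threshold_sweep(
    hits: list[Hit],
    community: SyntheticCommunity,
    identity_thresholds: Sequence[float] = (0.95, 0.90, 0.85, 0.80),
    coverage_threshold: float = 0.5,
) -> list[EvaluationResult]:
    """Evaluate unfiltered, then once per identity threshold (with coverage).

    Hits failing ``identity >= t`` or ``coverage >= coverage_threshold`` are
    dropped before best-non-self-hit selection.  Thresholds are fractions in
    [0, 1].  Returns ``[unfiltered, t_0, t_1, ...]`` in the given order.
    """
    for t in identity_thresholds:
        if not 0.0 <= t <= 1.0:
            raise ParameterError(f"identity threshold must be in [0, 1], got {t}")
    if not 0.0 <= coverage_threshold <= 1.0:
        raise ParameterError("coverage threshold must be in [0, 1]")
    read_len = {r.read_id: len(r.residues) for r in community.reads}
    origin = community.origin
    results = [evaluate_assignment(select_best_nonself_hits(hits, origin), community)]
    for t in identity_thresholds:
        kept = [
            h for h in hits
            if h.identity >= t and _coverage(h, read_len[h.query_id]) >= coverage_threshold
        ]
        results.append(evaluate_assignment(select_best_nonself_hits(kept, origin), community))
    return results


def write_truth(community: SyntheticCommunity, stream: IO) -> None:
    """TSV: read_id, genome_id, genus, offset, strand, length."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["read_id", "genome_id", "genus", "offset", "strand", "length"])
    for r in community.reads:
        writer.writerow(
            [r.read_id, r.true_genome_id, r.true_genus, r.true_offset,
             r.true_strand, len(r.residues)]
        )


def read_truth(stream: IO) -> list[ReadTruth]:
    reader = csv.DictReader(stream, delimiter="\t")
    out = []
    for row in reader:
        out.append(
            ReadTruth(
                read_id=row["read_id"],
                residues="N" * int(row["length"]),  # residues not stored in truth
                true_genome_id=row["genome_id"],
                true_genus=row["genus"],
                true_offset=int(row["offset"]),
                true_strand=row["strand"],
            )
        )
    return out
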