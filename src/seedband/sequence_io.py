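"""Sequence input, reference splitting and strand utilities.

FASTA/FASTQ parsing is delegated to Biopython's :mod:`Bio.SeqIO`; this module
adds the validation this tool requires (unique record ids, uppercase
residues), transparent gzip support by magic-byte sniffing, and the accessory
operation that splits reference sequences longer than the working limit ``L``
into overlapping fragments whose coordinates can be lifted back to the parent.

All coordinates in this package are 0-based, half-open.  Conversion to the
1-based inclusive convention of tabular output happens only in the writer.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_rc

from .errors import FormatError, InputError, ParameterError

# IUPAC nucleotide one-letter codes (U accepted and normalised to T on input
# validation level; the alignment alphabet itself is ACGT + ambiguity).
IUPAC_LETTERS = frozenset("ACGTUMRWSYKVHDBN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder of the header (may be empty).
    Residues are stored uppercased.
    """

    id: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceFragment:
    """A piece of a (possibly split) reference sequence.

    ``parent_offset`` is the 0-based position of the fragment start within the
    parent record, so parent coordinates are ``parent_offset + local``.
    """

    parent_id: str
    fragment_index: int
    parent_offset: int
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


StreamOrPath = Union[str, Path, IO]


def _open_text(source: StreamOrPath) -> IO:
    """Open ``source`` as a text stream, decompressing gzip input.

    Gzip is detected by the 1f-8b magic bytes, not the file name, so
    ``reads.fq.gz`` and a renamed compressed file behave the same.
    """
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return io.StringIO(data)
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        return io.StringIO(data.decode())
    path = Path(source)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _collect(handle: IO, fmt: str, what: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(handle, fmt):
            if rec.id in seen:
                raise FormatError(f"duplicate {what} id: {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc)
            )
    except ValueError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"malformed {what} input: {exc}") from exc
    return records


def read_fasta(source: StreamOrPath) -> list[SequenceRecord]:
    """Parse FASTA records (multi-line sequences allowed, gzip accepted).

    An empty stream yields an empty list.  Sequence data before the first
    header, or a duplicated id, raises :class:`FormatError`.
    """
    handle = _open_text(source)
    return _collect(handle, "fasta", "FASTA")


def read_fastq(source: StreamOrPath) -> list[SequenceRecord]:
    """Parse 4-line FASTQ records; qualities are validated for length, then dropped.

    Sequence/quality length mismatches and truncated records raise
    :class:`FormatError`.
    """
    handle = _open_text(source)
    return _collect(handle, "fastq", "FASTQ")


def read_sequences(source: StreamOrPath) -> list[SequenceRecord]:
    """Read FASTA or FASTQ, deciding by the first non-blank character."""
    handle = _open_text(source)
    text = handle.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    fmt = read_fastq if stripped[0] == "@" else read_fasta
    return fmt(io.StringIO(text))


def write_fasta(records: Iterable[SequenceRecord], stream: IO, width: int = 70) -> None:
    """Write records in wrapped FASTA."""
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        stream.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            stream.write(rec.residues[i : i + width] + "\n")


def split_reference(record: SequenceRecord, L: int, overlap: int) -> list[ReferenceFragment]:
    """Split a reference longer than ``L`` into overlapping fragments.

    Fragments start at offsets 0, L-overlap, 2(L-overlap), ...; every fragment
    has length ``L`` except possibly the last, and consecutive fragments share
    exactly ``overlap`` bases, so any alignment shorter than ``overlap`` is
    fully contained in at least one fragment.
    """
    if L < 1 or L <= overlap or overlap < 0:
        raise ParameterError(f"need L > overlap >= 0 and L >= 1, got L={L}, overlap={overlap}")
    n = record.length
    if n <= L:
        return [ReferenceFragment(record.id, 0, 0, record.residues)]
    step = L - overlap
    fragments = []
    offset = 0
    index = 0
    while True:
        chunk = record.residues[offset : offset + L]
        fragments.append(ReferenceFragment(record.id, index, offset, chunk))
        if offset + L >= n:
            break
        offset += step
        index += 1
    return fragments


_RC_ALLOWED = IUPAC_LETTERS


def reverse_complement(residues: str) -> str:
    """Reverse complement over the IUPAC alphabet (N -> N, M -> K, ...)."""
    upper = residues.upper()
    bad = set(upper) - _RC_ALLOWED
    if bad:
        raise InputError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return _bio_rc(upper)
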