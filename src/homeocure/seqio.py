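"""Sequence I/O: unigene references (FASTA) and short reads (FASTQ).

All sequences are handled uppercase over the alphabet {A, C, G, T, N}.
Base qualities are stored internally as integer Phred scores; on disk they
are ASCII-encoded with offset 33 (Sanger) or 64 (legacy Illumina 1.3+).
Quality encoding is always explicit — never auto-detected — and everything
downstream assumes Sanger-decoded Phred integers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
SANGER_OFFSET = 33
ILLUMINA13_OFFSET = 64
PHRED_MAX = 93

_ENCODING_FORMATS = {"sanger": "fastq", "illumina13": "fastq-illumina"}


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input or invalid sequence content."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class UnigeneReference:
    """Ordered collection of named nucleotide sequences.

    Serves both as the naive (uncured) unigene set and as cured variants of
    it. Identifiers are unique; sequences are non-empty, uppercase, and
    restricted to {A, C, G, T, N}.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self._entries: dict[str, str] = {}
        for name, seq in entries:
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._entries:
            raise SequenceFormatError(f"duplicate sequence identifier: {name!r}")
        seq = seq.upper()
        if not seq:
            raise SequenceFormatError(f"empty sequence for {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise SequenceFormatError(
                f"sequence {name!r} contains invalid characters {sorted(bad)}; "
                "only A, C, G, T, N are accepted"
            )
        self._entries[name] = seq

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._entries.items()}

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._entries.items())

    def __getitem__(self, name: str) -> str:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, UnigeneReference):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"UnigeneReference({len(self)} sequences)"

    def replace(self, name: str, seq: str) -> None:
        """Substitute the sequence for an existing entry (same length only)."""
        if name not in self._entries:
            raise KeyError(name)
        if len(seq) != len(self._entries[name]):
            raise ValueError("replacement sequence must preserve length")
        self._entries[name] = seq.upper()


@dataclass
class Read:
    """A single sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: np.ndarray  # int array, same length as bases

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise SequenceFormatError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > PHRED_MAX):
            raise SequenceFormatError(
                f"read {self.id!r}: Phred scores outside [0, {PHRED_MAX}]"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadSet:
    """A collection of reads from one sample.

    ``genome_tag`` records the declared genome of origin: "A" or "C" for
    diploid progenitor samples, "polyploid" for allopolyploid samples,
    "unknown" otherwise. Unless ``variable_length`` is set, all reads must
    share the nominal length.
    """

    reads: list[Read]
    sample: str = ""
    genome_tag: str = "unknown"
    variable_length: bool = False
    nominal_length: int | None = field(default=None)

    def __post_init__(self):
        if self.genome_tag not in {"A", "C", "polyploid", "unknown"}:
            raise ValueError(f"invalid genome_tag {self.genome_tag!r}")
        if self.nominal_length is None and self.reads:
            self.nominal_length = len(self.reads[0])
        if not self.variable_length:
            for r in self.reads:
                if len(r) != self.nominal_length:
                    raise SequenceFormatError(
                        f"read {r.id!r} has length {len(r)}, expected "
                        f"{self.nominal_length} (set variable_length=True to allow)"
                    )

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> UnigeneReference:
    """Load a FASTA file into a :class:`UnigeneReference`.

    Record order is preserved; sequences are uppercased. Identifiers are the
    header token up to the first whitespace. Duplicate identifiers and
    characters outside {A, C, G, T, N} are rejected.
    """
    ref = UnigeneReference()
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                ref.add(rec.id, str(rec.seq))
        except ValueError as exc:  # biopython parse failure
            raise SequenceFormatError(f"{path}: {exc}") from exc
    return ref


def write_fasta(ref: UnigeneReference, path, line_width: int = 60) -> None:
    """Write a reference as multi-line FASTA wrapped at ``line_width`` columns."""
    if not 1 <= line_width <= 80:
        raise ValueError("line_width must be in [1, 80]")
    with _open_text(path, "wt") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def decode_quals(qual_string: str, encoding: str = "sanger") -> np.ndarray:
    """Decode an ASCII quality string to Phred integers."""
    offset = _qual_offset(encoding)
    q = np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8).astype(np.int16)
    q -= offset
    if q.size and (q.min() < 0 or q.max() > PHRED_MAX):
        raise SequenceFormatError(
            f"quality string decodes outside [0, {PHRED_MAX}] with "
            f"{encoding} offset {offset}"
        )
    return q


def encode_quals(quals: np.ndarray, encoding: str = "sanger") -> str:
    """Encode Phred integers as an ASCII quality string."""
    offset = _qual_offset(encoding)
    q = np.asarray(quals, dtype=np.int16)
    if q.size and (q.min() < 0 or q.max() > PHRED_MAX):
        raise SequenceFormatError(f"Phred scores outside [0, {PHRED_MAX}]")
    return (q + offset).astype(np.uint8).tobytes().decode("ascii")


def _qual_offset(encoding: str) -> int:
    if encoding == "sanger":
        return SANGER_OFFSET
    if encoding == "illumina13":
        return ILLUMINA13_OFFSET
    raise ValueError(f"unknown quality encoding {encoding!r}")


def read_fastq(
    path,
    encoding: str = "sanger",
    sample: str = "",
    genome_tag: str = "unknown",
    variable_length: bool = False,
) -> ReadSet:
    """Load a 4-line-record FASTQ file into a :class:`ReadSet`.

    Qualities are decoded with the explicit ``encoding`` ("sanger" = ASCII
    offset 33, "illumina13" = offset 64) and stored as Phred integers.
    """
    fmt = _ENCODING_FORMATS.get(encoding)
    if fmt is None:
        raise ValueError(f"unknown quality encoding {encoding!r}")
    reads = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                quals = np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                )
                reads.append(Read(rec.id, str(rec.seq).upper(), quals))
        except ValueError as exc:
            raise SequenceFormatError(f"{path}: {exc}") from exc
    return ReadSet(
        reads, sample=sample, genome_tag=genome_tag, variable_length=variable_length
    )


def write_fastq(readset: ReadSet, path, encoding: str = "sanger") -> None:
    """Write reads as 4-line FASTQ records with the given quality encoding."""
    offset = _qual_offset(encoding)
    with _open_text(path, "wt") as fh:
        for r in readset:
            qual = (r.quals + offset).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def to_seqrecords(ref: UnigeneReference) -> list[SeqRecord]:
    """Expose a reference as Biopython SeqRecords (for interop)."""
    return [SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.items()]
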