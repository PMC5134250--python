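"""Streaming FASTQ input/output and mate pairing.

Reads are modelled as :class:`ReadRecord` (identifier, base string, integer
Phred vector).  Quality characters decode as ``Phred = ord(c) - offset`` with
the Sanger/modern-Illumina offset of 33 by default.  Mate files are assumed
order-synchronized (as written by the MiSeq basecaller); pairing is positional
with an identifier-stem check on every pair.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_OFFSET = 33
PHRED_MAX = 93

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
# mate designators: trailing "/1"-style suffix or a Casava 1.8+ comment field
_MATE_SUFFIX = re.compile(r"/[12]$")
_CASAVA_COMMENT = re.compile(r"^[12]:[YN]:\d+:\S*$")


class FastqFormatError(ValueError):
    """Raised for malformed records, bad quality encodings or unpaired mates."""


@dataclass
class ReadRecord:
    """A single sequencing read.

    Attributes
    ----------
    read_id:
        Full identifier line content (without the leading ``@``).
    sequence:
        Upper-case base string over ``{A, C, G, T, N}``.
    quals:
        Integer Phred scores, one per base, each in ``[0, 93]``.
    """

    read_id: str
    sequence: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.sequence):
            raise FastqFormatError(
                f"record {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.sequence == other.sequence
            and np.array_equal(self.quals, other.quals)
        )


@dataclass(frozen=True)
class ReadPair:
    """Synchronized forward/reverse mates sharing an identifier stem."""

    forward: ReadRecord
    reverse: ReadRecord

    def __post_init__(self) -> None:
        sf, sr = id_stem(self.forward.read_id), id_stem(self.reverse.read_id)
        if sf != sr:
            raise FastqFormatError(
                f"mate identifiers do not pair: {self.forward.read_id!r} vs "
                f"{self.reverse.read_id!r}"
            )


def id_stem(read_id: str) -> str:
    """Identifier with any mate designator stripped.

    Handles ``name/1`` / ``name/2`` suffixes and Casava 1.8+ ``name 1:N:0:...``
    comment fields; anything else is returned whole.
    """
    parts = read_id.split(None, 1)
    head = parts[0]
    if len(parts) == 2 and _CASAVA_COMMENT.match(parts[1]):
        return head
    return _MATE_SUFFIX.sub("", head)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def decode_quals(qual_str: str, offset: int = DEFAULT_OFFSET) -> np.ndarray:
    """Decode a FASTQ quality string to integer Phred scores."""
    q = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int64) - offset
    if q.size and (q.min() < 0 or q.max() > PHRED_MAX):
        raise FastqFormatError(
            f"Phred score outside [0, {PHRED_MAX}] after applying offset {offset}; "
            "is the encoding offset correct?"
        )
    return q


def encode_quals(quals: np.ndarray, offset: int = DEFAULT_OFFSET) -> str:
    quals = np.asarray(quals, dtype=np.int64)
    if quals.size and (quals.min() < 0 or quals.max() > PHRED_MAX):
        raise FastqFormatError(f"Phred score outside [0, {PHRED_MAX}]")
    return (quals + offset).astype(np.uint8).tobytes().decode("ascii")


def read_fastq(path: str | Path, offset: int = DEFAULT_OFFSET) -> Iterator[ReadRecord]:
    """Stream records from a (possibly gzipped) 4-line FASTQ file.

    Bases are upper-cased; quality characters decode with ``offset``.
    Malformed records or out-of-range Phred scores raise
    :class:`FastqFormatError` naming the offending record.
    """
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"record {title!r}: sequence and quality lengths differ"
                    )
                try:
                    quals = decode_quals(qual, offset)
                except FastqFormatError as exc:
                    raise FastqFormatError(f"record {title!r}: {exc}") from None
                yield ReadRecord(title, seq.upper(), quals)
        except ValueError as exc:  # Biopython's own malformed-record errors
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(
    records: Iterable[ReadRecord], path: str | Path, offset: int = DEFAULT_OFFSET
) -> int:
    """Write records as 4-line FASTQ; returns the number written.

    ``read_fastq(write_fastq(x))`` reproduces ``x`` exactly.
    """
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(
                f"@{rec.read_id}\n{rec.sequence}\n+\n{encode_quals(rec.quals, offset)}\n"
            )
            n += 1
    return n


def pair_streams(
    fwd: Iterable[ReadRecord], rev: Iterable[ReadRecord]
) -> Iterator[ReadPair]:
    """Pair two synchronized record streams positionally.

    Identifier stems must agree pair by pair; unequal stream lengths are a
    hard error reporting both counts.
    """
    fwd_it, rev_it = iter(fwd), iter(rev)
    n = 0
    sentinel = object()
    while True:
        f = next(fwd_it, sentinel)
        r = next(rev_it, sentinel)
        if f is sentinel and r is sentinel:
            return
        if f is sentinel or r is sentinel:
            extra = "forward" if r is sentinel else "reverse"
            raise FastqFormatError(
                f"unequal mate files: both had {n} records, then the "
                f"{extra} file ended early"
            )
        n += 1
        yield ReadPair(f, r)


def reverse_complement(r: ReadRecord) -> ReadRecord:
    """Reverse-complement a read; qualities are reversed alongside the bases."""
    bad = set(r.sequence) - _VALID_BASES
    if bad:
        raise FastqFormatError(
            f"record {r.read_id!r}: non-ACGTN character(s) {sorted(bad)}"
        )
    return ReadRecord(
        r.read_id, r.sequence.translate(_COMPLEMENT)[::-1], r.quals[::-1].copy()
    )
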