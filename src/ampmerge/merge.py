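"""Context-aware merging of overlapping paired-end mates.

The merger follows the CASPER scheme: scan every "inward" alignment of the
forward read against the reverse-complemented reverse read, keep the candidate
overlap with the lowest mismatch *rate* (ties broken toward the longer
overlap), and reject the pair if even the best candidate exceeds the allowed
mismatch fraction.  Within an accepted overlap, agreeing columns take the
higher of the two Phred scores; disagreeing columns are resolved by quality
difference when it is decisive, and otherwise by a vote over the dataset-wide
frequencies of the k-mers spanning the disputed position under each candidate
base.

The k-mer table is built in a first pass over the whole sample (forward reads
plus reverse-complemented reverse reads) before any pair is merged, so context
frequencies reflect the sample rather than a single pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastq_io import ReadPair, ReadRecord, reverse_complement

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MergeParams:
    """Tunables of the overlap search and mismatch resolution.

    min_overlap:
        Smallest acceptable overlap, in bases.
    max_mismatch_frac:
        Largest acceptable mismatch rate (mismatches / overlap length) for
        the best candidate; pairs above it are treated as non-overlapping.
    qdiff_threshold:
        Phred-difference at which quality alone decides a disputed column
        (inclusive).
    kmer_size:
        Context k-mer length; odd so a k-mer can be centred on a position.
    """

    min_overlap: int = 10
    max_mismatch_frac: float = 0.2
    qdiff_threshold: int = 19
    kmer_size: int = 17

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_frac <= 1.0):
            raise ValueError("max_mismatch_frac must lie in [0, 1]")
        if self.kmer_size < 3 or self.kmer_size % 2 == 0:
            raise ValueError("kmer_size must be odd and >= 3")


@dataclass(frozen=True)
class OverlapCandidate:
    """One scored suffix(fwd)/prefix(rc_rev) alignment."""

    overlap_len: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # offsets within the overlap


@dataclass
class MergedAmplicon:
    """A merged (overlapping) or stitched (non-overlapping) amplicon."""

    read_id: str
    sequence: str
    quals: np.ndarray
    spacer_mask: np.ndarray
    overlapped: bool
    overlap_len: int

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        self.spacer_mask = np.asarray(self.spacer_mask, dtype=bool)
        if not (len(self.sequence) == len(self.quals) == len(self.spacer_mask)):
            raise ValueError("sequence, quals and spacer_mask must have equal length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def unmasked_length(self) -> int:
        return int((~self.spacer_mask).sum())

    def quality_vector(self):
        from .quality import QualityVector

        return QualityVector(self.quals, self.spacer_mask)

    def to_read(self) -> ReadRecord:
        return ReadRecord(self.read_id, self.sequence, self.quals)


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


class KmerTable:
    """Dataset-wide canonical k-mer counts; k-mers containing N are skipped."""

    def __init__(self, k: int):
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        k = self.k
        counts = self.counts
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            kmer = canonical_kmer(kmer)
            counts[kmer] = counts.get(kmer, 0) + 1

    def count(self, kmer: str) -> int:
        if "N" in kmer:
            return 0
        return self.counts.get(canonical_kmer(kmer), 0)

    def __len__(self) -> int:
        return len(self.counts)


def build_kmer_table(pairs, k: int) -> KmerTable:
    """Count every k-mer of the forward reads and of the reverse-complemented
    reverse reads across a sample."""
    table = KmerTable(k)
    for pair in pairs:
        if k > min(len(pair.forward), len(pair.reverse)):
            raise ValueError(
                f"k={k} exceeds read length at pair {pair.forward.read_id!r}"
            )
        table.add_sequence(pair.forward.sequence)
        table.add_sequence(reverse_complement(pair.reverse).sequence)
    return table


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_best_overlap(
    fwd: ReadRecord, rc_rev: ReadRecord, params: MergeParams
) -> OverlapCandidate | None:
    """Best suffix(fwd)/prefix(rc_rev) overlap by mismatch rate.

    All overlap lengths in ``[min_overlap, min(len(fwd), len(rc_rev))]`` are
    scored; the candidate with the lowest mismatch rate wins, ties going to
    the longer overlap.  Returns None when even the best rate exceeds
    ``max_mismatch_frac`` — absence of overlap is a valid outcome.  Only
    inward layouts are considered: read-through of a fragment shorter than
    one read is reported as no overlap.
    """
    f = _as_bytes(fwd.sequence)
    r = _as_bytes(rc_rev.sequence)
    max_len = min(len(f), len(r))
    if max_len < params.min_overlap:
        return None
    best_len = best_mm = -1
    # exact rational comparison: rate(a) < rate(b)  <=>  mm_a*len_b < mm_b*len_a
    for olen in range(params.min_overlap, max_len + 1):
        mm = int(np.count_nonzero(f[len(f) - olen :] != r[:olen]))
        if best_len < 0 or mm * best_len <= best_mm * olen:
            best_len, best_mm = olen, mm
    if best_mm > params.max_mismatch_frac * best_len:
        return None
    positions = tuple(
        int(i)
        for i in np.nonzero(f[len(f) - best_len :] != r[:best_len])[0]
    )
    return OverlapCandidate(best_len, best_mm, positions)


def spanning_kmers(seq: list[str] | str, pos: int, base: str, k: int) -> list[str]:
    """All k-mers of ``seq`` covering ``pos`` with ``base`` substituted there.

    K-mers running past either end of the sequence, or containing an N, are
    dropped.
    """
    chars = list(seq)
    chars[pos] = base
    out = []
    for start in range(max(0, pos - k + 1), min(pos, len(chars) - k) + 1):
        kmer = "".join(chars[start : start + k])
        if "N" not in kmer:
            out.append(kmer)
    return out


def resolve_mismatch(
    base_f: str,
    q_f: int,
    base_r: str,
    q_r: int,
    context_f: list[str],
    context_r: list[str],
    table: KmerTable,
    params: MergeParams,
) -> tuple[str, int]:
    """Pick the base for a disagreeing overlap column.

    An N always loses to a called base.  A quality difference at or above
    ``qdiff_threshold`` is decisive; otherwise the base whose spanning k-mers
    are more frequent in the sample wins, with ties broken by the higher
    Phred and finally by the forward base.  The chosen base carries its own
    Phred score.
    """
    if base_f == "N" and base_r != "N":
        return base_r, q_r
    if base_r == "N" and base_f != "N":
        return base_f, q_f
    if abs(q_f - q_r) >= params.qdiff_threshold:
        return (base_f, q_f) if q_f > q_r else (base_r, q_r)
    votes_f = sum(table.count(km) for km in context_f)
    votes_r = sum(table.count(km) for km in context_r)
    if votes_f > votes_r:
        return base_f, q_f
    if votes_r > votes_f:
        return base_r, q_r
    if q_r > q_f:
        return base_r, q_r
    return base_f, q_f


def merge_pair(
    pair: ReadPair, table: KmerTable, params: MergeParams
) -> MergedAmplicon | None:
    """Merge one pair, or return None when no acceptable overlap exists.

    The merged amplicon is the forward-only prefix, the resolved overlap, and
    the reverse-only suffix; agreeing overlap columns take max(q_f, q_r).
    """
    from .fastq_io import id_stem

    fwd = pair.forward
    rc_rev = reverse_complement(pair.reverse)
    cand = find_best_overlap(fwd, rc_rev, params)
    if cand is None:
        return None
    olen = cand.overlap_len
    fseq, rseq = fwd.sequence, rc_rev.sequence
    fq, rq = fwd.quals, rc_rev.quals
    off = len(fseq) - olen

    merged = list(fseq[:off]) + list(fseq[off:]) + list(rseq[olen:])
    quals = np.concatenate([fq, rq[olen:]])
    # agreeing columns first: max quality; disputed columns provisionally
    # carry the forward base until resolved against the full context
    for i in range(olen):
        if i not in cand.mismatch_positions:
            quals[off + i] = max(fq[off + i], rq[i])
    for i in cand.mismatch_positions:
        pos = off + i
        bf, br = fseq[off + i], rseq[i]
        ctx_f = spanning_kmers(merged, pos, bf, params.kmer_size)
        ctx_r = spanning_kmers(merged, pos, br, params.kmer_size)
        base, q = resolve_mismatch(
            bf, int(fq[off + i]), br, int(rq[i]), ctx_f, ctx_r, table, params
        )
        merged[pos] = base
        quals[pos] = q

    seq = "".join(merged)
    return MergedAmplicon(
        read_id=id_stem(fwd.read_id),
        sequence=seq,
        quals=quals,
        spacer_mask=np.zeros(len(seq), dtype=bool),
        overlapped=True,
        overlap_len=olen,
    )
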