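"""N-patch stitching of non-overlapping mates.

Amplicons longer than the combined read span (e.g. 16S templates over 600 bp
under 2x300 sequencing) leave an unsequenced inner gap.  Rather than discard
such pairs, the reverse read is reverse-complemented and appended to the 3'
end of the forward read across a run of Ns (default 15) written at Phred 2.
The spacer positions are masked so that they are ignored by every quality
metric and statistic, while the Phred-2 Ns remain visible in the FASTQ output
for downstream consumers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fastq_io import PHRED_MAX, ReadPair, id_stem, reverse_complement
from .merge import MergedAmplicon

DEFAULT_SPACER_LEN = 15
DEFAULT_SPACER_PHRED = 2


@dataclass(frozen=True)
class StitchParams:
    """Spacer geometry and the retain/discard switch for unmerged pairs."""

    n_spacer: int = DEFAULT_SPACER_LEN
    spacer_phred: int = DEFAULT_SPACER_PHRED
    keep_nonoverlap: bool = False

    def __post_init__(self) -> None:
        if self.n_spacer < 0:
            raise ValueError("n_spacer must be >= 0")
        if not (0 <= self.spacer_phred <= PHRED_MAX):
            raise ValueError(f"spacer_phred must lie in [0, {PHRED_MAX}]")


def stitch_pair(pair: ReadPair, params: StitchParams) -> MergedAmplicon:
    """Join mates across the N spacer; the spacer is masked, everything else not.

    Lossless: dropping the spacer and reverse-complementing the suffix
    recovers both original mates exactly.
    """
    rc_rev = reverse_complement(pair.reverse)
    n = params.n_spacer
    seq = pair.forward.sequence + "N" * n + rc_rev.sequence
    quals = np.concatenate(
        [pair.forward.quals, np.full(n, params.spacer_phred, dtype=np.int64), rc_rev.quals]
    )
    mask = np.zeros(len(seq), dtype=bool)
    mask[len(pair.forward) : len(pair.forward) + n] = True
    return MergedAmplicon(
        read_id=id_stem(pair.forward.read_id),
        sequence=seq,
        quals=quals,
        spacer_mask=mask,
        overlapped=False,
        overlap_len=0,
    )


def spacer_mask_from_fastq(
    sequence: str,
    quals: np.ndarray,
    n_spacer: int = DEFAULT_SPACER_LEN,
    spacer_phred: int = DEFAULT_SPACER_PHRED,
) -> np.ndarray:
    """Re-derive a spacer mask from a stitched record read back from FASTQ.

    FASTQ cannot carry the mask, so on re-ingestion any run of at least
    ``n_spacer`` consecutive Ns at exactly ``spacer_phred`` is re-masked.
    The pipeline itself never needs this; it is a convenience for consumers
    of stitched output.
    """
    quals = np.asarray(quals)
    mask = np.zeros(len(sequence), dtype=bool)
    run_start = None
    for i in range(len(sequence) + 1):
        in_run = (
            i < len(sequence) and sequence[i] == "N" and quals[i] == spacer_phred
        )
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            if i - run_start >= n_spacer:
                mask[run_start:i] = True
            run_start = None
    return mask
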