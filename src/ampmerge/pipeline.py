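"""End-to-end pipeline: merge -> (optional) stitch -> filter -> report.

Pass 1 builds the sample-wide k-mer context table; pass 2 merges every pair,
stitching the unmergeable ones when ``keep_nonoverlap`` is set and discarding
them otherwise.  Every retained amplicon is then judged against the active
filter policy and written to ``<prefix>.hq.fastq`` or ``<prefix>.lq.fastq``;
the per-sample statistics land in ``<prefix>.report.tsv`` and ``.json``.
Record conservation holds on every run: HQ + LQ + discarded = total pairs.

The pair list is buffered in memory between the two passes; sample-scale
amplicon inputs fit comfortably.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .fastq_io import DEFAULT_OFFSET, pair_streams, read_fastq, write_fastq
from .merge import MergeParams, build_kmer_table, merge_pair
from .quality import FilterPolicy, passes_filter
from .report import QualityReport, build_report, write_report
from .stitch import StitchParams, stitch_pair

logger = logging.getLogger("ampmerge")

DEFAULT_FILTER = FilterPolicy(mode="meep", threshold=1.0)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    fwd_path: str | Path
    rev_path: str | Path
    out_prefix: str | Path
    merge: MergeParams = field(default_factory=MergeParams)
    stitch: StitchParams = field(default_factory=StitchParams)
    filter: FilterPolicy = DEFAULT_FILTER
    encoding_offset: int = DEFAULT_OFFSET
    log_level: str = "INFO"
    sample_id: str | None = None


def run_pipeline(cfg: PipelineConfig) -> QualityReport:
    """Run the full pipeline; returns the per-sample report."""
    for path in (cfg.fwd_path, cfg.rev_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    prefix = Path(cfg.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sample = cfg.sample_id or prefix.name

    pairs = list(
        pair_streams(
            read_fastq(cfg.fwd_path, cfg.encoding_offset),
            read_fastq(cfg.rev_path, cfg.encoding_offset),
        )
    )
    logger.info("%s: %d input pairs", sample, len(pairs))

    table = build_kmer_table(pairs, cfg.merge.kmer_size) if pairs else None
    if table is not None:
        logger.info("%s: k-mer table with %d distinct %d-mers", sample, len(table), table.k)

    amplicons = []
    discarded = 0
    for pair in pairs:
        amp = merge_pair(pair, table, cfg.merge)
        if amp is None:
            if cfg.stitch.keep_nonoverlap:
                amp = stitch_pair(pair, cfg.stitch)
            else:
                discarded += 1
                continue
        amplicons.append((amp, passes_filter(amp.quality_vector(), cfg.filter)))
    n_merged = sum(1 for a, _ in amplicons if a.overlapped)
    logger.info(
        "%s: merged %d, stitched %d, discarded %d",
        sample, n_merged, len(amplicons) - n_merged, discarded,
    )

    n_hq = write_fastq(
        (a.to_read() for a, ok in amplicons if ok),
        prefix.with_name(prefix.name + ".hq.fastq"),
        cfg.encoding_offset,
    )
    n_lq = write_fastq(
        (a.to_read() for a, ok in amplicons if not ok),
        prefix.with_name(prefix.name + ".lq.fastq"),
        cfg.encoding_offset,
    )
    logger.info("%s: %d high-quality, %d low-quality amplicons", sample, n_hq, n_lq)
    assert n_hq + n_lq + discarded == len(pairs), "record conservation violated"

    rep = build_report(amplicons, total_pairs=len(pairs), sample_id=sample)
    write_report(rep, prefix.with_name(prefix.name + ".report.tsv"), "tsv")
    write_report(rep, prefix.with_name(prefix.name + ".report.json"), "json")
    return rep
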