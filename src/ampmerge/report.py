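"""Per-sample quality-statistics report.

Eleven summary statistics per sample: total input pairs, overlapping and
non-overlapping amplicon counts, and average unmasked length, average Q and
average meep over all amplicons and over the high-quality (filter-passing)
subset, plus the high-quality count and the percentage of high-quality
amplicons that are overlapping.  "Average Q" and "average meep" are means over
amplicons of the per-amplicon values (not pooled per-base means), matching the
per-sample framing of the report.  Spacer positions are excluded throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

from .merge import MergedAmplicon
from .quality import avg_q, meep_score

REPORT_FIELDS = (
    "total_reads",
    "overlapping",
    "non_overlapping",
    "avg_amplicon_len",
    "avg_q_all",
    "avg_meep_all",
    "hq_count",
    "avg_len_hq",
    "avg_q_hq",
    "avg_meep_hq",
    "pct_overlap_hq",
)


@dataclass
class QualityReport:
    sample_id: str = "sample"
    total_reads: int = 0
    overlapping: int = 0
    non_overlapping: int = 0
    avg_amplicon_len: float = 0.0
    avg_q_all: float = 0.0
    avg_meep_all: float = 0.0
    hq_count: int = 0
    avg_len_hq: float = 0.0
    avg_q_hq: float = 0.0
    avg_meep_hq: float = 0.0
    pct_overlap_hq: float = 0.0
    hq_empty: bool = True  # True when no amplicon passed; HQ averages then read 0


def build_report(
    amplicons: Iterable[tuple[MergedAmplicon, bool]],
    total_pairs: int,
    sample_id: str = "sample",
) -> QualityReport:
    """Summarize a processed sample.

    ``amplicons`` yields ``(amplicon, passed_filter)`` for every retained
    amplicon; pairs that failed to merge and were discarded contribute only to
    ``total_pairs``.  An empty sample produces a report of zeros.
    """
    r = QualityReport(sample_id=sample_id, total_reads=total_pairs)
    n = 0
    sum_len = sum_q = sum_meep = 0.0
    hq_len = hq_q = hq_meep = 0.0
    hq_overlap = 0
    for amp, passed in amplicons:
        qv = amp.quality_vector()
        length = amp.unmasked_length
        q = avg_q(qv)
        meep = meep_score(qv)
        n += 1
        sum_len += length
        sum_q += q
        sum_meep += meep
        if amp.overlapped:
            r.overlapping += 1
        else:
            r.non_overlapping += 1
        if passed:
            r.hq_count += 1
            hq_len += length
            hq_q += q
            hq_meep += meep
            if amp.overlapped:
                hq_overlap += 1
    if n:
        r.avg_amplicon_len = sum_len / n
        r.avg_q_all = sum_q / n
        r.avg_meep_all = sum_meep / n
    if r.hq_count:
        r.hq_empty = False
        r.avg_len_hq = hq_len / r.hq_count
        r.avg_q_hq = hq_q / r.hq_count
        r.avg_meep_hq = hq_meep / r.hq_count
        r.pct_overlap_hq = 100.0 * hq_overlap / r.hq_count
    return r


def _rounded(r: QualityReport) -> dict:
    out = {"sample_id": r.sample_id}
    for name in REPORT_FIELDS:
        value = getattr(r, name)
        out[name] = round(value, 3) if isinstance(value, float) else value
    out["hq_empty"] = r.hq_empty
    return out


def write_report(r: QualityReport, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a report as TSV (header + one row) or JSON; floats at 3 dp."""
    data = _rounded(r)
    path = Path(path)
    if fmt == "tsv":
        cols = list(data)
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            fh.write("\t".join(str(data[c]) for c in cols) + "\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}; use 'tsv' or 'json'")
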