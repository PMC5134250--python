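"""Expected-error quality metrics and the two amplicon filter policies.

A Phred score Q maps to a per-base error probability P = 10^(-Q/10).  The
maximum expected error (MEE) of a read is the sum of P over its bases — the
expected number of miscalled bases.  The *meep* score expresses MEE as a
percentage of read length, so a meep cutoff of 1 permits at most one expected
error per 100 nt regardless of read length.  Average Q, by contrast, averages
the log-scale scores directly, which can hide a handful of terrible bases: a
100-nt read with 90 bases at Q40 and 10 at Q2 averages Q ~36 yet carries ~6
expected errors, while a uniform Q25 read averages only 25 with MEE 0.316.

Stitched amplicons carry an artificial N spacer whose positions are masked;
masked positions are excluded from every metric, including the meep
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastq_io import PHRED_MAX

FILTER_MODES = ("avgq", "meep")


@dataclass
class QualityVector:
    """Per-base Phred scores plus a mask of positions excluded from metrics.

    ``mask[i] is True`` means position ``i`` is ignored (used for the N
    spacer of stitched amplicons).  At least one unmasked position is
    required by every metric.
    """

    phreds: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phreds = np.asarray(self.phreds, dtype=np.int64)
        if self.mask is None:
            self.mask = np.zeros(len(self.phreds), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.phreds):
            raise ValueError("mask and phreds must have equal length")
        if self.phreds.size and (self.phreds.min() < 0 or self.phreds.max() > PHRED_MAX):
            raise ValueError(f"Phred scores must lie in [0, {PHRED_MAX}]")

    @property
    def unmasked(self) -> np.ndarray:
        return self.phreds[~self.mask]

    @property
    def unmasked_length(self) -> int:
        return int((~self.mask).sum())


@dataclass(frozen=True)
class FilterPolicy:
    """Amplicon filter: ``avgq`` (Phred units, pass at >= threshold) or
    ``meep`` (percent, pass at <= threshold)."""

    mode: str
    threshold: float

    def __post_init__(self) -> None:
        if self.mode not in FILTER_MODES:
            raise ValueError(f"unknown filter mode {self.mode!r}; use one of {FILTER_MODES}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def error_probability(q: int | np.ndarray) -> float | np.ndarray:
    """Per-base error probability P = 10^(-Q/10)."""
    q = np.asarray(q)
    if q.size and (q.min() < 0 or q.max() > PHRED_MAX):
        raise ValueError(f"Phred score outside [0, {PHRED_MAX}]")
    p = np.power(10.0, -q / 10.0)
    return float(p) if p.ndim == 0 else p


def _require_unmasked(qv: QualityVector) -> np.ndarray:
    u = qv.unmasked
    if u.size == 0:
        raise ValueError("quality metrics need at least one unmasked position")
    return u


def read_mee(qv: QualityVector) -> float:
    """Maximum expected error: sum of error probabilities over unmasked bases."""
    return float(np.sum(error_probability(_require_unmasked(qv))))


def meep_score(qv: QualityVector) -> float:
    """MEE as a percentage of the unmasked read length."""
    return read_mee(qv) * 100.0 / qv.unmasked_length


def avg_q(qv: QualityVector) -> float:
    """Arithmetic mean of the unmasked Phred scores."""
    return float(np.mean(_require_unmasked(qv)))


def passes_filter(qv: QualityVector, policy: FilterPolicy) -> bool:
    """Apply a filter policy; comparisons are inclusive at the threshold."""
    if policy.mode == "avgq":
        return avg_q(qv) >= policy.threshold
    if policy.mode == "meep":
        return meep_score(qv) <= policy.threshold
    raise ValueError(f"unknown filter mode {policy.mode!r}")
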