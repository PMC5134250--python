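"""Paired-end amplicon read simulator with a position-dependent error model.

Generates 2xL mate pairs from amplicon templates, injecting substitution
errors whose per-cycle probability follows a 4th-degree polynomial in the
cycle index, ``a + b * i^4`` with defaults a=3e-3, b=1.8e-9 — interpreted in
percent units, giving ~0.003% error at cycle 1 rising to ~14.6% at cycle 300,
a realistic Illumina MiSeq profile (the probability-unit reading would exceed
1 at cycle 300).  Quality strings are made consistent with the injected error
rates, Q_i = round(-10*log10(rate_i)) clipped to [2, 40], so expected-error
metrics of simulated reads can be reasoned about analytically.

Each pair carries ground truth: source template, template length, the exact
injected-error positions on each mate, and whether the pair is expected to
overlap (template length <= 2*read_len - min_overlap).  Everything is
deterministic given the seed.  Indels are not simulated; the merger is
ungapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fastq_io import ReadRecord, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MAX_SUB_RATE = 0.75  # a uniform random base differs 3 times out of 4


@dataclass(frozen=True)
class SimParams:
    """Simulator settings; defaults mirror a 2x300 MiSeq amplicon run."""

    read_len: int = 300
    n_pairs_per_template: int = 100
    error_coeff_a: float = 3e-3
    error_coeff_b: float = 1.8e-9
    error_exponent: int = 4
    rate_unit: str = "percent"  # or "probability"
    seed: int = 0
    min_overlap: int = 10  # used only for the expect_overlap ground truth

    def __post_init__(self) -> None:
        if self.rate_unit not in ("percent", "probability"):
            raise ValueError("rate_unit must be 'percent' or 'probability'")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated pair (error positions are 0-based)."""

    pair_id: str
    template_id: str
    template_len: int
    error_positions_f: tuple[int, ...]
    error_positions_r: tuple[int, ...]
    expect_overlap: bool


def error_rate(i: int | np.ndarray, p: SimParams) -> float | np.ndarray:
    """Substitution probability at 1-based cycle ``i``, clamped to [0, 0.75]."""
    raw = p.error_coeff_a + p.error_coeff_b * np.asarray(i, dtype=float) ** p.error_exponent
    prob = raw / 100.0 if p.rate_unit == "percent" else raw
    out = np.clip(prob, 0.0, MAX_SUB_RATE)
    return float(out) if out.ndim == 0 else out


def cycle_error_rates(p: SimParams) -> np.ndarray:
    return error_rate(np.arange(1, p.read_len + 1), p)


def cycle_qualities(p: SimParams) -> np.ndarray:
    """Phred per cycle consistent with the error model, clipped to [2, 40]."""
    rates = np.maximum(cycle_error_rates(p), 1e-9)
    return np.clip(np.rint(-10.0 * np.log10(rates)).astype(np.int64), 2, 40)


def make_templates(lengths: Sequence[int], seed: int) -> list[tuple[str, str]]:
    """Uniform-random ACGT templates of the requested lengths, as (id, seq)."""
    rng = np.random.default_rng(seed)
    out = []
    for idx, length in enumerate(lengths, start=1):
        seq = rng.integers(0, 4, size=length)
        out.append((f"template_{idx:02d}_len{length}", _BASES[seq].tobytes().decode()))
    return out


def write_templates_fasta(templates: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in templates:
            fh.write(f">{name}\n{seq}\n")


def read_templates_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


_RC = str.maketrans("ACGTN", "TGCAN")


def _mutate(true_read: str, rates: np.ndarray, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """Apply per-cycle substitutions; returns the read and 0-based error sites."""
    hits = np.nonzero(rng.random(len(true_read)) < rates)[0]
    if hits.size == 0:
        return true_read, ()
    chars = np.frombuffer(true_read.encode("ascii"), dtype=np.uint8).copy()
    # shift by 1..3 within {A,C,G,T} so the substituted base always differs
    shifts = rng.integers(1, 4, size=hits.size)
    base_idx = np.searchsorted(_BASES, chars[hits])
    chars[hits] = _BASES[(base_idx + shifts) % 4]
    return chars.tobytes().decode("ascii"), tuple(int(h) for h in hits)


def simulate_pairs(
    templates: Sequence[tuple[str, str]], p: SimParams
) -> tuple[list[ReadRecord], list[ReadRecord], list[SimTruth]]:
    """Simulate ``n_pairs_per_template`` mate pairs from every template.

    The forward read is the first ``read_len`` bases of the template and the
    reverse read is the reverse complement of the last ``read_len`` bases;
    both then receive position-dependent substitutions.
    """
    rates = cycle_error_rates(p)
    qual = cycle_qualities(p)
    rng = np.random.default_rng(p.seed)
    fwd_out: list[ReadRecord] = []
    rev_out: list[ReadRecord] = []
    truths: list[SimTruth] = []
    for t_id, t_seq in templates:
        if len(t_seq) < p.read_len:
            raise ValueError(
                f"template {t_id!r} ({len(t_seq)} bp) is shorter than read_len {p.read_len}"
            )
        fwd_true = t_seq[: p.read_len]
        rev_true = t_seq[-p.read_len :].translate(_RC)[::-1]
        expect = len(t_seq) <= 2 * p.read_len - p.min_overlap
        for j in range(p.n_pairs_per_template):
            stem = f"{t_id}_pair{j:06d}"
            fseq, ferr = _mutate(fwd_true, rates, rng)
            rseq, rerr = _mutate(rev_true, rates, rng)
            fwd_out.append(ReadRecord(f"{stem}/1", fseq, qual))
            rev_out.append(ReadRecord(f"{stem}/2", rseq, qual))
            truths.append(SimTruth(stem, t_id, len(t_seq), ferr, rerr, expect))
    return fwd_out, rev_out, truths


def write_truth_tsv(truths: Iterable[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pair_id\ttemplate_id\ttemplate_len\terror_positions_f\t"
            "error_positions_r\texpect_overlap\n"
        )
        for t in truths:
            fh.write(
                f"{t.pair_id}\t{t.template_id}\t{t.template_len}\t"
                f"{','.join(map(str, t.error_positions_f))}\t"
                f"{','.join(map(str, t.error_positions_r))}\t"
                f"{int(t.expect_overlap)}\n"
            )


def simulate_to_files(
    templates: Sequence[tuple[str, str]], p: SimParams, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Run the simulator and write ``<prefix>_R1.fastq``, ``<prefix>_R2.fastq``
    and ``<prefix>.truth.tsv``; returns the three paths."""
    prefix = Path(out_prefix)
    fwd, rev, truths = simulate_pairs(templates, p)
    p1 = prefix.parent / f"{prefix.name}_R1.fastq"
    p2 = prefix.parent / f"{prefix.name}_R2.fastq"
    pt = prefix.parent / f"{prefix.name}.truth.tsv"
    write_fastq(fwd, p1)
    write_fastq(rev, p2)
    write_truth_tsv(truths, pt)
    return p1, p2, pt
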