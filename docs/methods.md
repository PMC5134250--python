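# Methods

## Quality model

Phred scores map to error probabilities as P = 10^(−Q/10). The maximum
expected error (MEE) of a read is ΣPᵢ over its bases — by linearity of
expectation, the expected number of miscalled bases — and the meep score is
100·MEE/L, the expected-error percentage of read length L. All metrics are
computed in double precision; values are rounded (3 decimals) only at
display time, so worked boundary cases (e.g. MEE exactly 1.0 at Q20×100)
are reproduced exactly.

Filter comparisons are inclusive: an amplicon passes `avgq` at mean Phred ≥
threshold and `meep` at score ≤ threshold. Inclusivity at the boundary
matches the reading that a meep cutoff of 1 *permits* one expected error in
a 100-nt read.

Masked positions — the artificial N spacer of stitched amplicons — are
excluded from every metric, including the meep denominator, so a spacer
neither inflates nor dilutes a score. An `N` actually called by the
sequencer is *not* masked; its own (low) Phred contributes, because only the
artificial spacer carries no information by construction.

## Merging

The merger is an ungapped, context-aware scheme. For a pair, the reverse
mate is reverse-complemented and every inward alignment of a forward suffix
against a reverse-complement prefix is scored, for overlap lengths from
`min_overlap` (default 10) to the shorter read length. The objective is the
mismatch *rate* (count/length) rather than the raw count — a raw count
trivially favours the shortest overlaps — with ties broken toward the longer
overlap; rate comparisons are done exactly on integers (cross-multiplied),
not on floats. If even the best candidate exceeds `max_mismatch_frac`
(default 0.2) the pair is declared non-overlapping, which is an outcome, not
an error. Read-through layouts (amplicon shorter than one read) are not
searched: 16S amplicons targeted here always exceed one read length.

Within an accepted overlap, agreeing columns take the higher of the two
Phred scores. Disagreeing columns are resolved in order:

1. an `N` always loses to a called base, whatever the qualities;
2. a Phred difference of at least `qdiff_threshold` (default 19, inclusive)
   is decisive — the higher-quality base wins and keeps its own Phred;
3. otherwise a k-mer context vote: for each candidate base, every k-mer
   (default k = 17, odd so a k-mer can centre on the position) spanning the
   disputed position in the tentatively merged sequence is looked up in a
   sample-wide table, and the larger summed count wins. K-mers running past
   the sequence ends or containing an N are skipped. Remaining ties go to
   the higher Phred, then to the forward base, making the whole merge
   deterministic.

The k-mer table is built in a first pass over the entire sample (forward
reads plus reverse-complemented reverse reads, canonicalized to the
lexicographic minimum of each k-mer and its reverse complement) before any
pair is merged: context frequencies are only meaningful at dataset scope.
The pipeline buffers the pair list in memory between the two passes;
sample-scale amplicon inputs (10⁵–10⁶ pairs) fit easily, and the I/O layer
itself streams, so a re-reading variant would be a small change if ever
needed.

## Stitching

Non-overlapping pairs are retained (only when `keep_nonoverlap` is set;
default is to discard, mirroring common practice) by appending the
reverse-complemented reverse read to the 3′ end of the forward read across
`n_spacer` Ns (default 15) written at Phred `spacer_phred` (default 2). The
stitched amplicon keeps the forward read's identifier stem, since downstream
tools need one id per amplicon. The spacer mask lives in memory only — FASTQ
cannot encode it — so the Phred-2 Ns are what downstream consumers see on
disk; a helper (`spacer_mask_from_fastq`) re-masks any run of ≥ n_spacer
consecutive Ns at exactly the spacer Phred when stitched output is
re-ingested. Stitching is lossless: dropping the spacer and
reverse-complementing the suffix recovers both mates exactly.

## Per-sample report

Eleven statistics per sample: total input pairs; overlapping and
non-overlapping amplicon counts; average amplicon length, average Q and
average meep over all retained amplicons; and the high-quality count plus
the same three averages and the percentage of overlapping amplicons within
the high-quality subset. Averages are means over amplicons of per-amplicon
values (not pooled per-base means), lengths are unmasked lengths, and an
empty high-quality set reports zeros with an explicit `hq_empty` flag rather
than NaN, for robust TSV consumption. Record conservation holds by
construction and is asserted on every run: HQ + LQ + discarded = input
pairs.

## Read simulator

The simulator emulates a 2×300 MiSeq amplicon run. Templates are uniform
random ACGT sequences of user-chosen lengths — the pipeline's behaviour
depends on template *lengths* and error structure, not on taxonomy, so no
reference sequences need downloading; the default length set
(471/487/503/519 and 612/650) mirrors a realistic mix of mergeable V1–V3
amplicons and two species whose amplicons exceed the combined read span.
The forward read is the template's first 300 bases; the reverse read is the
reverse complement of its last 300.

Substitutions are injected per cycle i (1-based) with probability
(a + b·i⁴), a = 3e-3, b = 1.8e-9, interpreted in **percent** — ~0.003% at
cycle 1 rising to ~14.6% at cycle 300, a plausible late-cycle MiSeq decay.
A probability-unit mode exists but is not the default: read literally as a
probability the polynomial exceeds 1 before cycle 300, which is impossible,
so rates are clamped to [0, 0.75] (the substitution ceiling for a uniform
random base). Quality strings are made consistent with the injected rates,
Qᵢ = round(−10·log₁₀ rateᵢ) clipped to [2, 40], so expected-error metrics of
simulated reads can be reasoned about analytically. Indels are not
simulated; the merger is ungapped, and the two assumptions are made to
match. Every pair carries ground truth (template, exact error positions per
mate, expected overlap status with respect to `min_overlap`), and the whole
generator is deterministic given its seed.

What the simulator does not emulate: indels, chimeras, PCR bias, adapter
read-through, quality variation between reads at the same cycle, and real
16S sequence composition. Tests passing on simulated data therefore
demonstrate the pipeline's algebra and bookkeeping under a realistic error
*profile*, not its behaviour on every real-library artefact.

## Test problem sizes and statistical checks

The simulated end-to-end experiment runs at 600 pairs (6 templates × 100
pairs), a 1/200 scale of a full 120,000-pair run; counts at this scale are
large enough for the stochastic assertions (e.g. >95% of short-template
pairs merging) while keeping the whole suite fast. The per-cycle error-rate
check draws 10,000 reads and compares each cycle's injected-error count to
its binomial expectation: with 300 cycles a few ~3σ excursions are expected
by chance even under the correct model, so the test allows at most 3 cycles
beyond 3σ and none beyond 5σ — a family-wise bound on the same invariant
rather than a loosened per-cycle one.

## Numerical and design choices

- Quality encoding defaults to Phred+33 (modern Illumina); the offset is a
  config option, and decoding errors suggest checking it.
- Mate pairing is positional with an identifier-stem check per pair
  (`/1`/`/2` suffixes and Casava 1.8 comment fields are recognized), so
  files stream in constant memory; gzipped FASTQ is accepted by suffix.
- Lowercase bases are upper-cased on input to keep k-mer logic simple.
- Default filter: meep ≤ 1.0; `avgq` ≥ 20 selectable. Low-quality amplicons
  are written to `<prefix>.lq.fastq` rather than deleted, so every input
  pair is accounted for in the outputs.
- Merge defaults (min_overlap 10, max mismatch fraction 0.2, quality-difference
  threshold 19, k = 17) follow the upstream context-aware merger's
  conventions and are all exposed.

## Known limitations

- Ungapped overlap search: an indel between mates shifts the register and
  the pair will usually fail to merge rather than merge incorrectly.
- The k-mer vote uses raw counts; in very low-depth samples the table is
  sparse and the vote often falls through to the quality/forward tie-break.
- meep filtering of stitched amplicons judges the two sequenced segments
  only; the unsequenced gap contributes nothing, which slightly favours
  stitched amplicons over merged ones of equal sequenced quality.
- Interleaved FASTQ, BAM/SAM input, demultiplexing and adapter/primer
  trimming are out of scope.
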