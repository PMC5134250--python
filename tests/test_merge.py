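import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampmerge.fastq_io import ReadPair, reverse_complement
from ampmerge.merge import (
    KmerTable,
    MergeParams,
    build_kmer_table,
    canonical_kmer,
    find_best_overlap,
    merge_pair,
    resolve_mismatch,
    spanning_kmers,
)
from conftest import error_free_pair, make_read, rc_str

PARAMS = MergeParams()


def brute_force_best_overlap(fwd_seq: str, rc_rev_seq: str, params: MergeParams):
    """Independent exhaustive scorer: every overlap length, mismatch rate
    objective, ties to the longer overlap."""
    best = None
    for olen in range(params.min_overlap, min(len(fwd_seq), len(rc_rev_seq)) + 1):
        mm = sum(a != b for a, b in zip(fwd_seq[-olen:], rc_rev_seq[:olen]))
        rate = mm / olen
        if best is None or rate < best[0] or (rate == best[0] and olen > best[1]):
            best = (rate, olen, mm)
    if best is None or best[0] > params.max_mismatch_frac:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------- parameters


def test_merge_params_validation():
    with pytest.raises(ValueError):
        MergeParams(min_overlap=0)
    with pytest.raises(ValueError):
        MergeParams(kmer_size=4)
    with pytest.raises(ValueError):
        MergeParams(max_mismatch_frac=1.5)


# ---------------------------------------------------------------- k-mer table


def test_kmer_table_counts_and_canonicalizes():
    pair = ReadPair(make_read("p/1", "AAAA"), make_read("p/2", "CCCC"))
    # forward contributes AAA x2; rc(reverse) = GGGG contributes GGG x2 -> CCC
    table = build_kmer_table([pair], 3)
    assert table.counts == {"AAA": 2, "CCC": 2}
    assert table.count("TTT") == 2  # canonical lookup
    assert table.count("GGG") == 2


def test_kmer_table_skips_n_kmers():
    pair = ReadPair(make_read("p/1", "ANA"), make_read("p/2", "ANA"))
    assert build_kmer_table([pair], 3).counts == {}


def test_kmer_table_empty_stream():
    assert build_kmer_table([], 3).counts == {}


def test_kmer_table_rejects_k_beyond_read_length():
    pair = ReadPair(make_read("p/1", "ACGT"), make_read("p/2", "ACGT"))
    with pytest.raises(ValueError):
        build_kmer_table([pair], 5)


def test_canonical_kmer_is_min_of_strand_pair():
    assert canonical_kmer("TTT") == "AAA"
    assert canonical_kmer("ACG") == "ACG"  # rc = CGT > ACG


# ---------------------------------------------------------------- overlap search


def test_find_best_overlap_exact_suffix_prefix():
    fwd = make_read("f", "ACGTACGTAA")
    rc_rev = make_read("r", "ACGTAAGGGG")
    cand = find_best_overlap(fwd, rc_rev, MergeParams(min_overlap=4))
    assert (cand.overlap_len, cand.mismatch_count) == (6, 0)
    assert cand.mismatch_positions == ()


def test_find_best_overlap_simulated_constructed_overlap(sim_sample):
    template = next(seq for _, seq in sim_sample["templates"] if len(seq) == 471)
    pair = error_free_pair(template, 300)
    cand = find_best_overlap(
        pair.forward, reverse_complement(pair.reverse), PARAMS
    )
    assert (cand.overlap_len, cand.mismatch_count) == (2 * 300 - 471, 0)


def test_find_best_overlap_returns_none_without_overlap():
    rng = np.random.default_rng(5)
    bases = np.frombuffer(b"ACGT", np.uint8)
    a = bases[rng.integers(0, 4, 50)].tobytes().decode()
    b = bases[rng.integers(0, 4, 50)].tobytes().decode()
    assert find_best_overlap(make_read("f", a), make_read("r", b), PARAMS) is None


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_find_best_overlap_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", np.uint8)
    la, lb = rng.integers(10, 61, size=2)
    # half the time, plant a true overlap to exercise the accept path
    a = bases[rng.integers(0, 4, la)].tobytes().decode()
    if seed % 2:
        olen = int(rng.integers(10, min(la, lb) + 1))
        b = a[-olen:] + bases[rng.integers(0, 4, lb - olen)].tobytes().decode()
    else:
        b = bases[rng.integers(0, 4, lb)].tobytes().decode()
    expected = brute_force_best_overlap(a, b, PARAMS)
    got = find_best_overlap(make_read("f", a), make_read("r", b), PARAMS)
    if expected is None:
        assert got is None
    else:
        assert (got.overlap_len, got.mismatch_count) == expected


# ---------------------------------------------------------------- mismatch resolution


def test_quality_difference_is_decisive():
    base, q = resolve_mismatch("A", 40, "C", 10, [], [], KmerTable(3), PARAMS)
    assert (base, q) == ("A", 40)
    base, q = resolve_mismatch("A", 10, "C", 40, [], [], KmerTable(3), PARAMS)
    assert (base, q) == ("C", 40)


def test_qdiff_threshold_is_inclusive():
    # difference exactly at the threshold resolves on quality alone
    base, _ = resolve_mismatch("A", 30, "C", 11, [], [], KmerTable(3), PARAMS)
    assert base == "A"


def test_kmer_context_vote_breaks_quality_ties():
    table = KmerTable(3)
    for _ in range(12):
        table.add_sequence("GAG")
    for _ in range(3):
        table.add_sequence("GCG")
    ctx_a = spanning_kmers("GAG", 1, "A", 3)
    ctx_c = spanning_kmers("GCG", 1, "C", 3)
    base, _ = resolve_mismatch("A", 30, "C", 30, ctx_a, ctx_c, table, PARAMS)
    assert base == "A"
    base, _ = resolve_mismatch("C", 30, "A", 30, ctx_c, ctx_a, table, PARAMS)
    assert base == "A"  # vote wins regardless of which mate carries it


def test_empty_table_falls_back_to_forward_base():
    base, _ = resolve_mismatch("A", 30, "C", 30, ["AAA"], ["CCC"], KmerTable(3), PARAMS)
    assert base == "A"


def test_n_always_loses_to_called_base():
    base, q = resolve_mismatch("N", 40, "C", 2, [], [], KmerTable(3), PARAMS)
    assert (base, q) == ("C", 2)
    base, q = resolve_mismatch("A", 2, "N", 40, [], [], KmerTable(3), PARAMS)
    assert (base, q) == ("A", 2)


def test_spanning_kmers_respects_bounds_and_ns():
    # position 2 replaced by T -> "ACTTA"; the 3-mers covering position 2
    assert spanning_kmers("ACGTA", 2, "T", 3) == ["ACT", "CTT", "TTA"]
    assert spanning_kmers("ANGTA", 2, "T", 3) == ["TTA"]  # N k-mers dropped
    assert spanning_kmers("ACG", 1, "T", 3) == ["ATG"]  # clipped at both ends


# ---------------------------------------------------------------- merging


def test_error_free_pair_reconstructs_template(sim_sample):
    template = next(seq for _, seq in sim_sample["templates"] if len(seq) == 471)
    pair = error_free_pair(template, 300)
    amp = merge_pair(pair, KmerTable(17), PARAMS)
    assert amp is not None and amp.overlapped
    assert amp.sequence == template
    assert amp.overlap_len == 129
    assert len(amp) == 300 + 300 - amp.overlap_len
    assert not amp.spacer_mask.any()


def test_agreeing_overlap_base_takes_max_quality():
    rng = np.random.default_rng(3)
    bases = np.frombuffer(b"ACGT", np.uint8)
    template = bases[rng.integers(0, 4, 24)].tobytes().decode()  # reads 16 -> overlap 8
    pair = error_free_pair(template, 16, q=20)
    pair.forward.quals[-1] = 38  # last fwd base sits in the overlap
    amp = merge_pair(pair, KmerTable(17), MergeParams(min_overlap=5))
    assert amp.sequence == template
    assert amp.quals[15] == 38


def test_single_mismatch_resolved_toward_high_quality_mate():
    rng = np.random.default_rng(11)
    bases = np.frombuffer(b"ACGT", np.uint8)
    template = bases[rng.integers(0, 4, 45)].tobytes().decode()
    pair = error_free_pair(template, 30, q=35)
    # corrupt one forward base inside the overlap (positions 15..29) at low quality
    seq = list(pair.forward.sequence)
    pos = 20
    seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    pair.forward.sequence = "".join(seq)
    pair.forward.quals[pos] = 5  # qdiff 30 >= threshold
    amp = merge_pair(pair, KmerTable(17), PARAMS)
    assert amp.sequence == template  # reverse mate's base won
    assert amp.quals[pos] == 35


def test_non_overlapping_pair_returns_none(sim_sample):
    template = next(seq for _, seq in sim_sample["templates"] if len(seq) == 650)
    pair = error_free_pair(template, 300)
    assert merge_pair(pair, KmerTable(17), PARAMS) is None


def test_merge_is_deterministic(sim_sample):
    pairs = sim_sample["pairs"][:20]
    table = build_kmer_table(pairs, 17)
    first = [merge_pair(p, table, PARAMS) for p in pairs]
    second = [merge_pair(p, table, PARAMS) for p in pairs]
    for a, b in zip(first, second):
        if a is None:
            assert b is None
        else:
            assert a.sequence == b.sequence and np.array_equal(a.quals, b.quals)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(31, 50))
def test_zero_error_reconstruction_property(seed, template_len):
    """Error-free mates from any random template with L < T <= 2L - min_overlap
    merge back to exactly the template."""
    read_len = 30
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", np.uint8)
    template = bases[rng.integers(0, 4, template_len)].tobytes().decode()
    pair = error_free_pair(template, read_len)
    amp = merge_pair(pair, KmerTable(17), PARAMS)
    assert amp is not None
    assert amp.overlap_len >= 2 * read_len - template_len  # true or repeat-extended
    if amp.overlap_len == 2 * read_len - template_len:
        assert amp.sequence == template
        assert len(amp) == template_len
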