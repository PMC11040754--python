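"""Fragmentation, unmapped merging, k-mer masking, permutation distance test."""

import numpy as np
import pandas as pd
import pytest

from pantropon.core import Interval, decode, revcomp
from pantropon.kmers import SpecificKmerSet
from pantropon.origin import (classify_origin, distance_permutation_test,
                              fragment_genome, merge_unmapped,
                              subtract_pangenome_hits)
from pantropon.core import seq_canonical_codes


def rand_seq(rng, n):
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


# ---------------------------------------------------------------------------
# fragmentation

def test_fragment_2500bp_gives_1000_1000_500():
    rng = np.random.default_rng(0)
    frags = fragment_genome({"c": rand_seq(rng, 2500)})
    assert [(f.start, f.end) for f in frags] == [(0, 1000), (1000, 2000), (2000, 2500)]


def test_fragment_all_N_gives_nothing_and_999bp_gives_one():
    rng = np.random.default_rng(1)
    assert fragment_genome({"c": "N" * 5000}) == []
    frags = fragment_genome({"c": rand_seq(rng, 999)})
    assert [(f.start, f.end) for f in frags] == [(0, 999)]


def test_fragment_n_gap_splits_tiling_and_keeps_coordinates():
    rng = np.random.default_rng(2)
    seq = rand_seq(rng, 1500) + "N" * 100 + rand_seq(rng, 1200)
    frags = fragment_genome({"c": seq})
    assert [(f.start, f.end) for f in frags] == [
        (0, 1000), (1000, 1500), (1600, 2600), (2600, 2800)]


def test_fragments_partition_non_n_bases_exactly_once():
    rng = np.random.default_rng(3)
    seq = rand_seq(rng, 3333) + "N" * 7 + rand_seq(rng, 41)
    frags = fragment_genome({"c": seq})
    covered = sum(f.length for f in frags)
    assert covered == len(seq) - 7
    starts_ends = sorted((f.start, f.end) for f in frags)
    for (s1, e1), (s2, e2) in zip(starts_ends, starts_ends[1:]):
        assert e1 <= s2


# ---------------------------------------------------------------------------
# unmapped merging and subtraction

def test_merge_unmapped_rules():
    frags = [Interval("c", 0, 1000), Interval("c", 1000, 2000),
             Interval("c", 2000, 3000), Interval("c", 3000, 4000)]
    merged = merge_unmapped(frags, np.array([False, False, True, False]))
    assert [(m.start, m.end) for m in merged] == [(0, 2000), (3000, 4000)]
    assert merge_unmapped(frags, np.array([True] * 4)) == []
    # fragments separated by an N gap are not coordinate-contiguous
    gap = [Interval("c", 0, 1000), Interval("c", 1100, 2100)]
    merged2 = merge_unmapped(gap, np.array([False, False]))
    assert len(merged2) == 2


def test_merge_unmapped_flag_length_mismatch_errors():
    with pytest.raises(ValueError):
        merge_unmapped([Interval("c", 0, 10)], np.array([True, False]))


def test_subtract_pangenome_hits():
    ref = [Interval("c", 0, 2000)]
    pan = [Interval("c", 500, 800)]
    out = subtract_pangenome_hits(ref, pan)
    # [0,500) dropped (< 500 bp), [800,2000) kept
    assert [(o.start, o.end) for o in out] == [(800, 2000)]
    assert subtract_pangenome_hits(ref, []) == [Interval("c", 0, 2000)]
    assert subtract_pangenome_hits(ref, ref) == []


# ---------------------------------------------------------------------------
# masking / classification

def specset_from_seq(seq, k=15, genome="g"):
    codes = np.unique(seq_canonical_codes(seq, k))
    return SpecificKmerSet(k=k, assignments=pd.Series([genome] * len(codes),
                                                      index=codes))


def test_classify_origin_masked_fraction_thresholds():
    rng = np.random.default_rng(4)
    seq = rand_seq(rng, 1000)
    iv = Interval("c", 0, 1000)
    # mask ~150/1000 -> lost; the probe covers one 150 bp run
    spec = specset_from_seq(seq[200:336])  # 136-14 = 122 windows -> 150 bp run
    call = classify_origin(iv, seq, spec, "g")
    assert call.verdict == "lost" and call.masked_fraction < 0.2
    # mask >= 200/1000 -> nascent (boundary is strict: < 0.20 means lost)
    spec2 = specset_from_seq(seq[200:420])
    call2 = classify_origin(iv, seq, spec2, "g")
    assert call2.masked_fraction >= 0.2 and call2.verdict == "nascent"


def test_classify_origin_gap_join_hand_example():
    """Masked runs [100,140) and [180,220): 40 bp gap < 50 joins them into
    [100,220), masked_bp = 120."""
    rng = np.random.default_rng(5)
    seq = rand_seq(rng, 1000)
    k = 15
    probes = seq[100:140] + "ACGT" + seq[180:220]  # isolate the two runs
    codes = np.concatenate([seq_canonical_codes(seq[100:140], k),
                            seq_canonical_codes(seq[180:220], k)])
    spec = SpecificKmerSet(k=k, assignments=pd.Series(
        ["g"] * len(np.unique(codes)), index=np.unique(codes)))
    call = classify_origin(Interval("c", 0, 1000), seq, spec, "g")
    assert call.masked_bp == 120
    del probes


def test_classify_origin_empty_kmer_set_is_lost():
    rng = np.random.default_rng(6)
    seq = rand_seq(rng, 600)
    spec = SpecificKmerSet(k=15, assignments=pd.Series(dtype=object))
    assert classify_origin(Interval("c", 0, 600), seq, spec, "g").verdict == "lost"


def test_classify_origin_reverse_complement_invariant():
    rng = np.random.default_rng(7)
    seq = rand_seq(rng, 1000)
    spec = specset_from_seq(seq[300:700])
    a = classify_origin(Interval("c", 0, 1000), seq, spec, "g")
    b = classify_origin(Interval("c", 0, 1000), revcomp(seq), spec, "g")
    assert a.verdict == b.verdict
    assert a.masked_bp == b.masked_bp


# ---------------------------------------------------------------------------
# permutation distance test

def test_distance_permutation_queries_on_genes_give_minimal_p():
    genes = [Interval("c", i * 10_000, i * 10_000 + 2000) for i in range(10)]
    res = distance_permutation_test(genes[:5], genes, {"c": 200_000},
                                    n_perm=200, seed=0)
    assert res["observed_mean"] == 0
    assert res["p_closer"] == pytest.approx(1 / 201)


def test_distance_permutation_error_paths():
    with pytest.raises(ValueError, match="no genes"):
        distance_permutation_test([Interval("c", 0, 10)], [], {"c": 1000})
    # queries only on gene-free chromosomes -> excluded -> error
    with pytest.raises(ValueError, match="no query"):
        distance_permutation_test([Interval("c2", 0, 10)],
                                  [Interval("c1", 0, 100)], {"c1": 1000, "c2": 1000})


def test_distance_permutation_null_calibration():
    """Uniformly placed queries are not flagged: p >= 0.05 in >= 95%-ish of
    seeds (binomial slack at 30 seeds)."""
    rng = np.random.default_rng(8)
    genes = [Interval("c", int(s), int(s) + 1000)
             for s in rng.integers(0, 490_000, 40)]
    rejections = 0
    n_seeds = 30
    for seed in range(n_seeds):
        r2 = np.random.default_rng(1000 + seed)
        queries = [Interval("c", int(s), int(s) + 2000)
                   for s in r2.integers(0, 490_000, 25)]
        res = distance_permutation_test(queries, genes, {"c": 500_000},
                                        n_perm=200, seed=seed)
        if res["p_closer"] < 0.05:
            rejections += 1
    # binomial(30, 0.05): >= 6 rejections has probability < 0.002
    assert rejections <= 5


# ---------------------------------------------------------------------------
# end-to-end on the synthetic quartet

def test_end_to_end_origin_accuracy(small_origin_report):
    """>= 95% of planted nascent bases classified nascent and >= 95% of
    planted lost bases classified lost, in both genome pairs."""
    for pair, rep in small_origin_report.items():
        for key, val in rep.items():
            if "accuracy" in key:
                assert val >= 0.95, f"{pair}/{key} = {val}"
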