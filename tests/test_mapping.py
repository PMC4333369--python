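"""Semi-global read mapping, k-read-coherency and coverage profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bubblesnp as bs
from bubblesnp._seq import revcomp

from conftest import plant_snp, random_genome


def toy_bubble():
    return bs.Bubble(path_a="CTGACCT", path_b="CTGTCCT", k=4)


def brute_force_placements(read, path, max_mismatch, snp_index):
    """Oracle: try every offset on both strands, count mismatches directly."""
    hits = set()
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for off in range(-len(seq) + 1, len(path)):
            s, e = max(0, off), min(len(path), off + len(seq))
            if e - s < 1:
                continue
            mm = sum(seq[i - off] != path[i] for i in range(s, e))
            covers = s <= snp_index < e
            if covers and seq[snp_index - off] != path[snp_index]:
                continue
            if mm <= max_mismatch:
                hits.add((strand, off, mm))
    return hits


def test_index_covers_both_paths_and_strands():
    idx = bs.index_paths([toy_bubble()], 4)
    assert len(idx.path_seqs) == 2
    # shared flank k-mers hit both paths
    hits = bs.map_read("CTGA", idx, 0)
    assert {a.path_id for a in hits} == {0}
    hits = bs.map_read("TCCT", idx, 0)
    assert {a.path_id for a in hits} == {1}
    with pytest.raises(ValueError):
        bs.index_paths([])


def test_map_read_spec_examples():
    idx = bs.index_paths([toy_bubble()], 4)
    # full source sequence aligns to its own allele path, 0 mismatches
    alns = bs.map_read("ACTGACCTG", idx)
    own = [a for a in alns if a.path_id == 0]
    assert own and own[0].mismatches == 0 and own[0].covers_snp
    # the other allele is rejected at the SNP even with budget left
    assert not [a for a in alns if a.path_id == 1 and a.covers_snp]
    # two substitutions elsewhere: rejected at default, accepted at 2
    noisy = "AATGACCAG"  # subs at the first and last overlap columns
    alns = bs.map_read(noisy, idx, max_mismatch=1)
    assert not [a for a in alns if a.path_id == 0 and a.mismatches == 2]
    alns2 = bs.map_read(noisy, idx, max_mismatch=2)
    assert [a for a in alns2 if a.path_id == 0 and a.mismatches == 2]


def test_short_reads_are_skipped():
    idx = bs.index_paths([toy_bubble()], 4)
    assert bs.map_read("ACT", idx) == []


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_map_read_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = 5
    genome = random_genome(60, seed=seed + 1)
    site = 30
    alt = "ACGT"[("ACGT".index(genome[site]) + 1) % 4]
    mut = plant_snp(genome, site, alt)
    bub = bs.Bubble(
        path_a=genome[site - k + 1 : site + k],
        path_b=mut[site - k + 1 : site + k],
        k=k,
    )
    idx = bs.index_paths([bub], k)
    start = int(rng.integers(0, 40))
    read = (genome if rng.integers(2) else mut)[start : start + 20]
    if rng.integers(2):
        read = revcomp(read)
    mm_budget = int(rng.integers(0, 3))
    got = {
        (a.path_id, a.strand, a.offset, a.mismatches)
        for a in bs.map_read(read, idx, mm_budget)
    }
    want = set()
    for pid, path in enumerate(idx.path_seqs):
        for strand, off, mm in brute_force_placements(
            read, path, mm_budget, idx.snp_index
        ):
            # seed-and-extend only finds placements sharing an exact k-mer
            seq = read if strand == "+" else revcomp(read)
            s, e = max(0, off), min(len(path), off + len(seq))
            shares_seed = any(
                seq[i - off : i - off + k] == path[i : i + k]
                for i in range(s, e - k + 1)
            )
            if shares_seed:
                want.add((pid, strand, off, mm))
    assert got == want


def test_k_read_coherency_vs_read_coherency():
    # two read groups overlapping by < k: every position covered twice,
    # but the junction k-mer is fully contained in no read
    path = "A" * 20
    k, c = 8, 2
    left = [(0, 12)] * 2  # reads covering positions 0..11
    right = [(10, 20)] * 2  # reads covering 10..19
    assert not bs.k_read_coherent(path, left + right, c, k)
    # plain positional coverage *is* >= 2 everywhere
    cov = np.zeros(20)
    for s, e in left + right:
        cov[s:e] += 1
    assert (cov >= c).all()
    # fully spanning reads restore coherency
    assert bs.k_read_coherent(path, [(0, 20)] * 2, c, k)
    assert not bs.k_read_coherent(path, [(0, 20)] * 1, c, k)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_k_read_coherency_matches_positional_oracle(seed):
    rng = np.random.default_rng(seed)
    plen, k, c = 31, 7, int(rng.integers(1, 4))
    spans = []
    for _ in range(int(rng.integers(0, 15))):
        s = int(rng.integers(0, plen - 1))
        e = int(rng.integers(s + 1, plen + 1))
        spans.append((s, e))
    got = bs.k_read_coherent("A" * plen, spans, c, k)
    want = all(
        sum(1 for s, e in spans if s <= i and i + k <= e) >= c
        for i in range(plen - k + 1)
    )
    assert got == want
    if got:  # k-read-coherency implies read-coherency at the same c
        cov = np.zeros(plen)
        for s, e in spans:
            cov[s:e] += 1
        assert (cov >= c).all()


def test_profile_toy_depths_and_retention(toy_sets, toy_graph):
    bubbles = bs.enumerate_bubbles(toy_graph, 2)
    preds = bs.profile_predictions(bubbles, toy_sets, 2)
    # chimeric strand-mixing bubbles are not k-read-coherent: only the true
    # SNP survives
    assert len(preds) == 1
    prof = preds[0].profile
    assert sorted(prof.depth.flatten().tolist()) == [0, 0, 4, 4]
    # each set supports exactly one path with all four of its reads
    assert set(prof.depth.sum(axis=1).tolist()) == {4}
    assert prof.k_coherent == [True, True]
    # FASTA input: no qualities -> mean PHRED 0 and NA flag
    assert prof.has_quality == [False, False]
    assert prof.mean_phred.sum() == 0.0


def test_depths_are_strand_invariant(toy_sets, toy_graph):
    bubbles = bs.enumerate_bubbles(toy_graph, 2)
    rc_sets = [
        bs.ReadSet.from_sequences([revcomp(s) for s, _ in rs.reads], rs.set_id)
        for rs in toy_sets
    ]
    a = bs.profile_predictions(bubbles, toy_sets, 2)
    b = bs.profile_predictions(bubbles, rc_sets, 2)
    assert len(a) == len(b) == 1
    assert (a[0].profile.depth == b[0].profile.depth).all()
    assert a[0].profile.k_coherent == b[0].profile.k_coherent


def test_quality_at_snp_is_averaged():
    bub = toy_bubble()
    reads = [("ACTGACCTG", "IIIIIIIII"), ("ACTGACCTG", "!!!!!!!!!")]
    rs = bs.ReadSet(set_id=0, reads=reads)
    preds = bs.profile_predictions([bub], [rs], 1)
    assert len(preds) == 1
    prof = preds[0].profile
    # SNP base is read position 4 on both reads: mean of PHRED 40 and 0
    row = int(np.argmax(prof.depth[0]))
    assert prof.depth[0, row] == 2
    assert prof.mean_phred[0, row] == pytest.approx(20.0)


def test_retention_rule_and_both_paths_mode():
    # path_a fully spanned; path_b covered only by two read groups that
    # overlap by < k at the centre (the chimeric-junction signature)
    k = 7
    genome = random_genome(80, seed=70)
    site = 40
    alt = "ACGT"[("ACGT".index(genome[site]) + 1) % 4]
    mut = plant_snp(genome, site, alt)
    bub = bs.Bubble(
        path_a=genome[site - k + 1 : site + k],
        path_b=mut[site - k + 1 : site + k],
        k=k,
    )
    span_a = [genome[site - k - 2 : site + k + 2]] * 3  # spans all of path_a
    left_b = [mut[site - k - 2 : site + 2]] * 3  # ends just past the SNP
    right_b = [mut[site - 1 : site + k + 2]] * 3  # starts just before it
    sets = [bs.ReadSet.from_sequences(span_a + left_b + right_b, 0)]
    kept_any = bs.profile_predictions([bub], sets, 2)
    assert len(kept_any) == 1  # path_a alone satisfies the default rule
    kept_both = bs.profile_predictions([bub], sets, 2, require_both_paths=True)
    assert kept_both == []  # path_b is not k-read-coherent
    # with no spanning reads at all the bubble dies under either rule
    sets2 = [bs.ReadSet.from_sequences(left_b + right_b, 0)]
    assert bs.profile_predictions([bub], sets2, 2) == []


def test_empty_bubble_list_yields_nothing(toy_sets):
    assert bs.profile_predictions([], toy_sets, 2) == []
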