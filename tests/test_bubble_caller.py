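"""Bubble enumeration, branching classes, deduplication, contexts."""

import numpy as np
import pytest

import bubblesnp as bs
from bubblesnp._seq import revcomp
from bubblesnp.bubble_caller import (
    CLEAN,
    SIMPLY_BRANCHING,
    SYMMETRICALLY_BRANCHING,
)

from conftest import plant_snp, random_genome


def brute_force_pairs(graph):
    """Oracle: all pairs of solid 2k-1 strings differing only at the centre.

    Enumerates every string whose k-mers are all solid by DFS over the
    solid set, then pairs strings sharing both flanks; output as canonical
    pair keys.  Only usable on tiny graphs.
    """
    k = graph.k
    oriented = set()
    from bubblesnp._seq import code_to_str, revcomp_code

    for code in graph.solid:
        oriented.add(code_to_str(code, k))
        oriented.add(code_to_str(revcomp_code(code, k), k))

    paths = set()
    for start in oriented:
        stack = [start]
        while stack:
            s = stack.pop()
            if len(s) == 2 * k - 1:
                paths.add(s)
                continue
            for b in "ACGT":
                if s[len(s) - k + 1 :] + b in oriented:
                    stack.append(s + b)
    pairs = set()
    for p in paths:
        for b in "ACGT":
            if b == p[k - 1]:
                continue
            q = p[: k - 1] + b + p[k:]
            if q in paths:
                pairs.add(bs.canonical_pair(p, q))
    return pairs


def graph_from_genomes(genomes, k, c=1):
    return bs.build_graph(
        bs.count_kmers([[g] for g in genomes], k), c
    )


def test_toy_bubble_paths_and_start(toy_graph):
    starts = dict(bs.find_bubble_starts(toy_graph))
    assert set(starts["ACTG"]) == {"A", "T"}
    bub = bs.extend_bubble(toy_graph, "ACTG", "A", "T")
    assert {bub.path_a, bub.path_b} == {"CTGACCT", "CTGTCCT"}
    assert bub.snp_index == 3 and bub.alleles in (("A", "T"), ("T", "A"))


def test_three_extensions_yield_three_pairs():
    # one shared 4-mer start AACCC extended by three alleles
    seqs = []
    for allele in "ACG":
        seqs.append("GTAACCC" + allele + "TGGATC")
    g = graph_from_genomes(seqs, 5)
    pairs = [p for s, p in bs.find_bubble_starts(g) if s == "AACCC"]
    assert len(pairs) == 3


def test_linear_genome_has_no_starts():
    # k chosen so (k-1)-mers are collision-free on a 400 bp random genome
    g = graph_from_genomes([random_genome(400, seed=3)], 13)
    assert list(bs.find_bubble_starts(g)) == []
    assert bs.enumerate_bubbles(g, 2) == []


def test_snp_bubble_found_and_clean_on_random_genome():
    genome = random_genome(600, seed=9)
    site, k = 300, 9
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[site]]
    g = graph_from_genomes([genome, plant_snp(genome, site, alt)], k)
    bubbles = bs.enumerate_bubbles(g, 0)
    assert len(bubbles) == 1
    bub = bubbles[0]
    assert bub.branching_class == CLEAN
    truth = bs.canonical_pair(
        genome[site - k + 1 : site + k],
        plant_snp(genome, site, alt)[site - k + 1 : site + k],
    )
    assert bub.key() == truth


def test_close_snps_produce_no_bubble():
    # two substitutions closer than k block each other's path completion
    genome = random_genome(600, seed=10)
    k = 9
    mut = plant_snp(plant_snp(genome, 300, "A" if genome[300] != "A" else "C"),
                    305, "A" if genome[305] != "A" else "C")
    g = graph_from_genomes([genome, mut], k)
    assert bs.enumerate_bubbles(g, 2) == []
    assert brute_force_pairs(g) == set()


def test_discard_rule_no_common_extension():
    # without the downstream k-mers the extension cannot continue
    small = bs.build_graph(
        bs.count_kmers([["ACTGA", "ACTGT"]], 4), 1
    )
    assert bs.extend_bubble(small, "ACTG", "A", "T") is None


@pytest.mark.parametrize("seed,n_snps", [(21, 6), (22, 12), (23, 20)])
def test_enumeration_matches_brute_force_oracle(seed, n_snps):
    """b=2 enumeration equals the exhaustive solid-path-pair search."""
    rng = np.random.default_rng(seed)
    k = 7
    genome = random_genome(3000, seed=seed + 100)
    sites = rng.choice(np.arange(2 * k, len(genome) - 2 * k), n_snps, replace=False)
    mut = genome
    for s in sites:
        s = int(s)
        mut = plant_snp(mut, s, "ACGT"[(("ACGT".index(mut[s])) + 1) % 4])
    g = graph_from_genomes([genome, mut], k)
    got = {b.key() for b in bs.enumerate_bubbles(g, 2)}
    assert got == brute_force_pairs(g)


def test_policy_sets_nest_and_repeat_snp_needs_b1():
    genome = random_genome(4000, seed=30)
    # second, inexact copy of a 400 bp segment: one mismatch 5 bp left of
    # where a SNP will sit, so the SNP bubble branches (on one path only)
    seg = genome[1000:1400]
    seg_mut = plant_snp(seg, 205, "ACGT"[("ACGT".index(seg[205]) + 1) % 4])
    genome = genome[:2600] + seg_mut + genome[3000:]
    k = 9
    site = 1210
    mut = plant_snp(genome, site, "ACGT"[("ACGT".index(genome[site]) + 2) % 4])
    g = graph_from_genomes([genome, mut], k)
    keys = [{b.key() for b in bs.enumerate_bubbles(g, b)} for b in (0, 1, 2)]
    assert keys[0] <= keys[1] <= keys[2]
    target = bs.canonical_pair(
        genome[site - k + 1 : site + k], mut[site - k + 1 : site + k]
    )
    assert target in keys[1] - keys[0]  # recovered only once branching allowed


def test_branching_classification_simple_and_symmetric():
    k = 7
    genome = random_genome(800, seed=31)
    site = 400
    alt = "ACGT"[("ACGT".index(genome[site]) + 1) % 4]
    mut = plant_snp(genome, site, alt)
    # a divergence on the reference path only: an extra sequence sharing the
    # window just right of the SNP but continuing differently
    branch_point = site + 3
    stem = genome[branch_point - k + 1 : branch_point + 1]
    other = "ACGT"[("ACGT".index(genome[branch_point + 1]) + 1) % 4]
    extra = stem + other + random_genome(30, seed=32)
    g = graph_from_genomes([genome, mut, extra], k)
    bubbles = {b.key(): b for b in bs.enumerate_bubbles(g, 2)}
    target = bs.canonical_pair(
        genome[site - k + 1 : site + k], mut[site - k + 1 : site + k]
    )
    assert target in bubbles
    assert bubbles[target].branching_class == SIMPLY_BRANCHING

    # same divergence planted on *both* alleles with the same extra character
    stem_alt = mut[branch_point - k + 1 : branch_point + 1]
    extra2 = stem_alt + other + random_genome(30, seed=33)
    g2 = graph_from_genomes([genome, mut, extra, extra2], k)
    bubbles2 = {b.key(): b for b in bs.enumerate_bubbles(g2, 2)}
    assert target in bubbles2
    assert bubbles2[target].branching_class == SYMMETRICALLY_BRANCHING


def test_strand_invariance_of_enumeration():
    genome = random_genome(2000, seed=40)
    k = 9
    mut = genome
    for s in (500, 900, 1400):
        mut = plant_snp(mut, s, "ACGT"[("ACGT".index(mut[s]) + 1) % 4])
    fwd = graph_from_genomes([genome, mut], k)
    rev = graph_from_genomes([revcomp(genome), revcomp(mut)], k)
    assert {b.key() for b in bs.enumerate_bubbles(fwd, 2)} == {
        b.key() for b in bs.enumerate_bubbles(rev, 2)
    }


def test_dedup_reports_each_bubble_once(toy_graph):
    bubbles = bs.enumerate_bubbles(toy_graph, 2)
    keys = [b.key() for b in bubbles]
    assert len(keys) == len(set(keys))
    expected = bs.canonical_pair("CTGACCT", "CTGTCCT")
    assert expected in keys


def test_extend_context_toy(toy_graph):
    bub = next(
        b
        for b in bs.enumerate_bubbles(toy_graph, 2)
        if b.key() == bs.canonical_pair("CTGACCT", "CTGTCCT")
    )
    bs.extend_context(toy_graph, bub)
    # hand-walk of the 9-nt toy graph: in the source-sequence orientation the right
    # side extends by exactly one base (G, unique), the left side is blocked
    # at once (both ACTG and CCTG feed the left flank CTG).  The bubble is
    # stored reverse-complemented, so the lengths appear swapped.
    emitted = bub.left_contig + bub.path_a + bub.right_contig
    assert {bub.left_ext_len, bub.right_ext_len} == {0, 1}
    assert emitted in ("CAGGACAG", "CAGGTCAG", revcomp("CAGGACAG"), revcomp("CAGGTCAG"))


def test_extend_context_stops_at_fork_and_on_circles():
    # circular unambiguous genome: the walk must terminate via visited nodes
    k = 5
    circle = "ATGGCTAAGCCTTACGGATC"
    doubled = circle + circle[: 2 * k]  # emulate circularity for k-mers
    site = 10
    alt = "ACGT"[("ACGT".index(circle[site]) + 1) % 4]
    mut_circle = circle[:site] + alt + circle[site + 1 :]
    mut_doubled = mut_circle + mut_circle[: 2 * k]
    g = graph_from_genomes([doubled, mut_doubled], k)
    bubbles = bs.enumerate_bubbles(g, 2)
    assert bubbles
    for bub in bubbles:
        bs.extend_context(g, bub, max_len=500)
        assert bub.left_ext_len <= len(circle)
        assert bub.right_ext_len <= len(circle)


def test_bubble_validation_rejects_bad_paths():
    with pytest.raises(ValueError):
        bs.Bubble(path_a="ACGTACG", path_b="ACGTACG", k=4)
    with pytest.raises(ValueError):
        bs.Bubble(path_a="ACGTACG", path_b="ACCTACC", k=4)
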