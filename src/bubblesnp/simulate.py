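"""Synthetic genomes, cohorts, reads and truth files for end-to-end testing.

Two cohort layouts are generated:

* a *haploid cohort*: n copies of a base genome carrying substitutions whose
  carrier sets follow a decaying sharing law - the expected number of sites
  carried by every member of a specific m-subset is S/(m-1), with
  S = pair_sharing_fraction x genome length.  Drawing each site's carrier
  count j from P(j) proportional to 1/(j(j-1)) on {2..n} and then a uniform
  j-subset realises that target exactly for every m (hockey-stick identity),
  with S(n-1) sites in total.  For n=2 the law degenerates (every site would
  be carried by both copies, hence invisible), so each site is instead
  assigned to exactly one of the two individuals and S sites are drawn.

* *diploid individuals*: two haplotype sequences per individual, built from
  a reference and a variant list; a homozygous variant is placed on both
  haplotypes, a heterozygous one on a single randomly chosen haplotype.

Reads are single-end, drawn uniformly from a uniformly chosen strand until
the requested coverage is reached, with i.i.d. substitution errors (no
indels) and constant PHRED qualities.  All randomness flows from one seed;
identical seeds reproduce identical genomes, reads and truth byte-for-byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import BASES
from .mapping import ReadSet

logger = logging.getLogger(__name__)

_DEFAULT_PHRED = 37  # constant read quality unless error simulation asks otherwise


@dataclass(frozen=True)
class Mutation:
    """One simulated substitution: carriers are *sequence* indices."""

    site: int
    ref: str
    alt: str
    carriers: frozenset


@dataclass
class SimulationTruth:
    """Ground truth of a simulation.

    ``sequences`` holds every simulated haplotype; ``individuals[i]`` lists
    the sequence indices belonging to individual i (one for haploids, two
    for diploids).  A site is a polymorphism *for a subset of individuals*
    iff its carrier pattern is non-constant over that subset's sequences,
    and isolated for the subset iff no other such polymorphism lies within
    k-1 positions on either side.
    """

    reference: str
    sequences: list[str]
    individuals: list[tuple[int, ...]]
    mutations: list[Mutation]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def _subset_seq_ids(self, subset) -> tuple[int, ...]:
        if subset is None:
            subset = range(self.n_individuals)
        return tuple(s for i in subset for s in self.individuals[i])

    def polymorphic_sites(self, subset=None) -> list[Mutation]:
        """Mutations with a non-constant carrier pattern within the subset."""
        seq_ids = set(self._subset_seq_ids(subset))
        out = []
        for m in self.mutations:
            inside = len(m.carriers & seq_ids)
            if 0 < inside < len(seq_ids):
                out.append(m)
        return out

    def isolated_sites(self, k: int, subset=None) -> list[Mutation]:
        """Subset polymorphisms with no other one within k-1 bases."""
        poly = sorted(self.polymorphic_sites(subset), key=lambda m: m.site)
        out = []
        for i, m in enumerate(poly):
            left_ok = i == 0 or m.site - poly[i - 1].site > k - 1
            right_ok = i == len(poly) - 1 or poly[i + 1].site - m.site > k - 1
            if left_ok and right_ok:
                out.append(m)
        return out


def _random_genome(length: int, rng: np.random.Generator) -> str:
    arr = rng.integers(0, 4, size=length)
    return "".join(BASES[b] for b in arr) if length < 1000 else (
        np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes().decode("ascii")
    )


def _apply_mutations(genome: str, muts: list[tuple[int, str]]) -> str:
    arr = bytearray(genome, "ascii")
    for site, alt in muts:
        arr[site] = ord(alt)
    return arr.decode("ascii")


def _carrier_count_law(n: int) -> np.ndarray:
    """P(j) on {2..n} proportional to 1/(j(j-1))."""
    j = np.arange(2, n + 1)
    w = 1.0 / (j * (j - 1.0))
    return w / w.sum()


def simulate_haploid_cohort(
    genome: str | int,
    n_individuals: int,
    pair_sharing_fraction: float,
    seed: int,
) -> tuple[list[str], SimulationTruth]:
    """n mutated copies of a base genome under the decaying sharing scheme.

    ``genome`` is either an explicit sequence or a length (a uniform random
    genome is then drawn from the same seed stream).  See the module
    docstring for the carrier law; S = pair_sharing_fraction * length sites
    are expected in common between any specific pair of individuals.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    rng = np.random.default_rng(seed)
    base = _random_genome(genome, rng) if isinstance(genome, int) else genome.upper()
    length = len(base)
    s_sites = int(round(pair_sharing_fraction * length))
    n_sites = s_sites if n_individuals == 2 else s_sites * (n_individuals - 1)
    if n_sites > length:
        raise ValueError(
            f"infeasible SNP density: {n_sites} sites on a {length} bp genome"
        )
    if n_sites == 0:
        truth = SimulationTruth(
            reference=base,
            sequences=[base] * n_individuals,
            individuals=[(i,) for i in range(n_individuals)],
            mutations=[],
        )
        return [base] * n_individuals, truth

    sites = np.sort(rng.choice(length, size=n_sites, replace=False))
    alt_pick = rng.integers(0, 3, size=n_sites)
    if n_individuals == 2:
        carrier_sets = [frozenset([int(x)]) for x in rng.integers(0, 2, n_sites)]
    else:
        law = _carrier_count_law(n_individuals)
        js = rng.choice(np.arange(2, n_individuals + 1), size=n_sites, p=law)
        carrier_sets = [
            frozenset(int(x) for x in rng.choice(n_individuals, size=int(j), replace=False))
            for j in js
        ]

    mutations = []
    per_ind: list[list[tuple[int, str]]] = [[] for _ in range(n_individuals)]
    for site, pick, carriers in zip(sites, alt_pick, carrier_sets):
        site = int(site)
        ref = base[site]
        alt = [b for b in BASES if b != ref][int(pick)]
        mutations.append(Mutation(site=site, ref=ref, alt=alt, carriers=carriers))
        for ind in carriers:
            per_ind[ind].append((site, alt))
    genomes = [_apply_mutations(base, muts) for muts in per_ind]
    truth = SimulationTruth(
        reference=base,
        sequences=genomes,
        individuals=[(i,) for i in range(n_individuals)],
        mutations=mutations,
    )
    logger.info(
        "haploid cohort: %d individuals, %d SNP sites on %d bp",
        n_individuals,
        n_sites,
        length,
    )
    return genomes, truth


def simulate_diploid_individuals(
    reference: str,
    variants,
    seed: int,
    class_fractions: tuple[float, float, float] = (0.09, 0.69, 0.22),
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Two haplotype sequences per individual from a variant list.

    ``variants`` is either an explicit list of ``(site, alt, genotypes)``
    with one genotype in {0, 1, 2} (alt-allele copies) per individual, or an
    integer count: that many biallelic sites are then drawn for two
    individuals with genotype classes hom-hom / hom-het / het-het in the
    given proportions.  A homozygous variant lands on both haplotypes; a
    heterozygous one on a single haplotype chosen at random.
    """
    rng = np.random.default_rng(seed)
    reference = reference.upper()
    length = len(reference)

    if isinstance(variants, int):
        n_ind = 2
        if variants > length:
            raise ValueError("more variants than genome positions")
        sites = np.sort(rng.choice(length, size=variants, replace=False))
        classes = rng.choice(3, size=variants, p=np.asarray(class_fractions))
        variant_list = []
        for site, cls in zip(sites, classes):
            site = int(site)
            alt = [b for b in BASES if b != reference[site]][int(rng.integers(0, 3))]
            if cls == 0:  # homozygous alt in both
                gts = (2, 2)
            elif cls == 1:  # heterozygous in exactly one individual
                het = int(rng.integers(0, 2))
                gts = tuple(1 if i == het else 0 for i in range(2))
            else:  # heterozygous in both
                gts = (1, 1)
            variant_list.append((site, alt, gts))
    else:
        variant_list = list(variants)
        n_ind = len(variant_list[0][2]) if variant_list else 2

    hap_muts: list[list[tuple[int, str]]] = [[] for _ in range(2 * n_ind)]
    mutations = []
    for site, alt, gts in variant_list:
        if not (0 <= site < length):
            raise ValueError(f"variant position {site} out of range")
        carriers = set()
        for ind, g in enumerate(gts):
            if g == 2:
                chosen = (2 * ind, 2 * ind + 1)
            elif g == 1:
                chosen = (2 * ind + int(rng.integers(0, 2)),)
            else:
                chosen = ()
            for h in chosen:
                hap_muts[h].append((site, alt))
                carriers.add(h)
        mutations.append(
            Mutation(site=site, ref=reference[site], alt=alt, carriers=frozenset(carriers))
        )
    haps = [_apply_mutations(reference, m) for m in hap_muts]
    truth = SimulationTruth(
        reference=reference,
        sequences=haps,
        individuals=[(2 * i, 2 * i + 1) for i in range(n_ind)],
        mutations=mutations,
    )
    return [(haps[2 * i], haps[2 * i + 1]) for i in range(n_ind)], truth


def simulate_reads(
    genomes: Sequence,
    coverage: float,
    read_len: int,
    error_rate: float,
    seed: int,
    *,
    with_quality: bool = True,
    error_phred: int | None = None,
) -> list[ReadSet]:
    """One ReadSet per genome at the requested coverage.

    Each element of ``genomes`` is a sequence or a tuple of sequences (e.g.
    the two haplotypes of a diploid individual, sampled jointly).  Reads are
    uniform over valid start positions and strands; every base is substituted
    with probability ``error_rate`` (uniform wrong base).  Qualities are a
    constant PHRED ``37`` string; with ``error_phred`` set, error positions
    get that (lower) value instead, and with ``with_quality=False`` reads
    carry no qualities at all (FASTA-like).
    """
    from ._seq import revcomp

    rng = np.random.default_rng(seed)
    out = []
    qchar = chr(33 + _DEFAULT_PHRED)
    eqchar = chr(33 + error_phred) if error_phred is not None else qchar
    for set_id, g in enumerate(genomes):
        pool = [g] if isinstance(g, str) else list(g)
        total = sum(len(s) for s in pool)
        if any(read_len > len(s) for s in pool):
            raise ValueError("read length exceeds a source sequence length")
        n_reads = math.ceil(coverage * total / read_len)
        starts_per = np.array([len(s) - read_len + 1 for s in pool])
        cum = np.cumsum(starts_per)
        flat = rng.integers(0, cum[-1], size=n_reads)
        src = np.searchsorted(cum, flat, side="right")
        pos = flat - np.concatenate([[0], cum[:-1]])[src]
        strands = rng.integers(0, 2, size=n_reads)
        n_err = rng.binomial(n_reads * read_len, error_rate)
        err_flat = np.unique(rng.integers(0, n_reads * read_len, size=n_err))
        err_shift = rng.integers(1, 4, size=len(err_flat))
        err_by_read: dict[int, list[tuple[int, int]]] = {}
        for ef, sh in zip(err_flat, err_shift):
            err_by_read.setdefault(int(ef) // read_len, []).append(
                (int(ef) % read_len, int(sh))
            )
        reads = []
        base_idx = {b: i for i, b in enumerate(BASES)}
        for r in range(n_reads):
            seq = pool[src[r]][pos[r] : pos[r] + read_len]
            if strands[r]:
                seq = revcomp(seq)
            errs = err_by_read.get(r)
            qual = qchar * read_len if with_quality else None
            if errs:
                sl = list(seq)
                if qual is not None and error_phred is not None:
                    ql = list(qual)
                for p, sh in errs:
                    sl[p] = BASES[(base_idx[sl[p]] + sh) % 4]
                    if qual is not None and error_phred is not None:
                        ql[p] = eqchar
                seq = "".join(sl)
                if qual is not None and error_phred is not None:
                    qual = "".join(ql)
            reads.append((seq, qual))
        out.append(ReadSet(set_id=set_id, reads=reads, name=f"sim_{set_id}"))
        logger.info(
            "simulated read set %d: %d reads x %d bp (%.1fx)",
            set_id,
            n_reads,
            read_len,
            n_reads * read_len / total,
        )
    return out


def make_truth_paths(
    truth: SimulationTruth, k: int, subset=None
) -> list[tuple[str, str]]:
    """2k-1 path pairs centred on every isolated SNP of a subset.

    For each isolated site the window [site-k+1, site+k-1] is extracted from
    one subset sequence without the substitution and one with it; sites
    closer than k-1 to a sequence end are excluded (and counted in the log).
    """
    seq_ids = truth._subset_seq_ids(subset)
    length = len(truth.reference)
    pairs = []
    skipped = 0
    for m in truth.isolated_sites(k, subset):
        if m.site < k - 1 or m.site > length - k:
            skipped += 1
            continue
        carrier = next(s for s in seq_ids if s in m.carriers)
        non_carrier = next(s for s in seq_ids if s not in m.carriers)
        lo, hi = m.site - k + 1, m.site + k
        ref_path = truth.sequences[non_carrier][lo:hi]
        alt_path = truth.sequences[carrier][lo:hi]
        pairs.append((ref_path, alt_path))
    if skipped:
        logger.info("truth paths: %d isolated SNPs within k-1 of an end skipped", skipped)
    return pairs
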