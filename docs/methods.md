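# Methods

`bubblesnp` calls isolated single-nucleotide polymorphisms directly from raw
read sets, with no reference genome. This note records the model, the
algorithmic choices that were genuinely open, the synthetic data the package
is validated on, and what that validation does and does not show.

## The bubble model

Let k be the k-mer size (default 31, odd recommended) and consider the de
Bruijn graph over the canonical k-mers of all input read sets: nodes are
k-mers, edges are exact (k−1)-overlaps, and a k-mer and its reverse
complement are one node. An *isolated* SNP — a substitution with no other
polymorphism within k−1 bases on either side — produces a *bubble*: two
paths that can be written p·α·q and p·β·q, with p, q shared (k−1)-mers and
α ≠ β the two alleles. Each path is a string of length 2k−1 whose central
base (0-based index k−1) is the polymorphic one.

Detection walks every solid k-mer (both orientations) and looks for two
distinct right extensions; each such pair opens a candidate bubble that is
then completed by k−1 synchronized right extensions, appending only
nucleotides that extend *both* paths. If some step has no shared extension
the bubble is discarded — this is precisely what restricts calls to
isolated SNPs, since a second nearby polymorphism desynchronizes the walk.
Two SNPs closer than k bases therefore produce no call by design.

### Solidity

Only *solid* k-mers enter the graph. The coverage threshold c (default 4)
is applied **per read set**: a k-mer is solid if it reaches c in at least
one input set. The rationale: with m pooled sets at per-sample coverage x,
a pooled threshold compares c against m·x, so at large m recurrent
sequencing errors (expected count ∝ m) slip above any fixed c and riddle
true bubbles with spurious branches; a per-set threshold scales with the
coverage each sample actually has and keeps the error floor independent of
m. A pooled-sum mode (`solidity="pooled"`) is available and is the natural
choice for a single set or when samples are individually very shallow.

### Branching classes and the b policy

Repeats produce extension steps with more than one choice. Each completed
bubble is re-walked in both directions (right extensions of windows
0..k−2, left extensions of windows k−1..1) and classified:

* **clean** — every step had exactly one possible extension on each path;
* **simply branching** — some path had ≥ 2 choices at some step, but the
  two paths never shared the same ≥ 2 nucleotides at one step;
* **symmetrically branching** — some step offered the same ≥ 2 nucleotides
  to both paths, the signature of a two-copy repeat masquerading as a SNP.

`b_policy` keeps clean bubbles only (0, default), clean + simply branching
(1, recovers SNPs sitting in repeats at some precision cost), or all (2).
The left-direction check is performed after path completion; completing
first and classifying second gives the same output as checking during
construction and keeps the walker simple. When a step offers several
shared nucleotides, every choice is explored (bounded by a safety cap of
256 completions per start pair), so b=2 enumeration is exhaustive.

### Deduplication and contexts

A bubble has four equivalent write-ups (swap the two paths, reverse
complement both). The canonical form is the lexicographically smallest
(path_a, path_b) among the four; every SNP is reported once under that
key and output is sorted by it, making runs deterministic. A bubble whose
paths begin at the very first base of a sequence has no start node and is
not enumerated; truth generation applies the same end margin, so the two
bookkeepings agree.

Each call also carries the longest unambiguous sequence context on both
sides: a unitig walk from the shared flanks that appends bases while
exactly one extension exists and the incoming node is not a merge point
(the step off the bubble boundary skips the merge test — the merge there
is the bubble itself), stopping at ambiguity, a previously visited node
(this terminates circular genomes), or `max_context` bases (default 10·k).
Short contexts flag repeat-dense or polymorphism-dense surroundings.

## Read-coherency validation

Graph paths can be chimeric: k-mers from different reads can assemble a
sequence present in no read at all (repeats ≥ 2k shorter than the read
length are the classic cause). Every read of every set is therefore mapped
back onto the 2k−1 paths with a seed-and-extend, gap-free, semi-global
aligner: exact k-mer seeds (both strands) imply diagonal placements,
duplicate placements are collapsed, read overhangs beyond the path ends
are free, at most `max_mismatch` substitutions (default 1, matching
typical error rates) are allowed in the overlap, and **no** substitution
is ever allowed at the polymorphic base — a read covering the SNP is
thereby assigned to exactly the path carrying its allele.

A path is **k-read-coherent** for a read set if every one of its k-mer
windows is fully contained in ≥ c accepted alignments of that set. This is
strictly stronger than requiring every position to be covered c times
(read-coherency): two read stacks overlapping by fewer than k bases cover
every position yet leave the junction window contained in no read, which
is exactly the chimera signature. A prediction is kept if at least one
read set makes at least one of its paths k-read-coherent (the published
retention rule, read literally); `require_both_paths=True` gives the
stricter variant. The same c is reused as the coherency threshold, with an
independent override available in the API.

Survivors carry, per read set and per path, the number of reads covering
the polymorphic base (the allele depth) and their mean PHRED quality at
that base (0 when the set has no qualities, flagged `NA` on output).

## Ranking by the Phi coefficient

Each prediction's evidence is a 2 × m contingency table: rows the two
paths, columns the m read sets, cells the allele depths. The score is

    phi = sqrt(chi² / N)

with chi² the bare Pearson statistic (no continuity correction — the
definition is the bare normalized statistic) and N the table total, which
for two rows is bounded by 1 and for a 2×2 table equals the classical
phi/Matthews coefficient. Columns with zero margin are dropped; fewer than
two informative columns, or an empty row, score 0. Predictions are sorted
by phi descending, ties broken by canonical key.

The normalization by N is what keeps deeply covered repeat bubbles from
out-scoring everything. Error bubbles (one stray read everywhere) and
repeat bubbles (balanced depth everywhere) both sit near 0; a SNP whose
alleles separate the samples sits near 1. The score is uninformative with
one read set and deliberately down-ranks SNPs heterozygous in every
sample — for those, the extension-length filter (`min_ext`) is the right
tool, since false calls have markedly shorter unambiguous contexts.

Marker-grade selection for assay design (`filter_markers`) additionally
applies: total allele depth within [depth_min, depth_max] (inclusive); no
8-base window containing ≥ 6 identical bases in either path (homopolymer
trouble for primer design); depth-weighted mean PHRED at the SNP ≥ 30;
and, when read sets are supplied, a remap with a relaxed substitution
budget that drops any bubble attracting a read aligned with residual
mismatches — such reads betray unmodelled nearby variation. This last
check replaces an external-mapper screen with the package's own aligner;
it is intentionally aggressive and meant for low-error marker panels.

## Synthetic cohorts

The simulator produces the two cohort layouts the tests and the
reproduction script use.

**Haploid cohort with decaying sharing.** n copies of a base genome
(uniform i.i.d. ACGT by default, or a supplied sequence when repeat
structure is wanted) carry substitutions at distinct uniform sites. The
target is that a specific m-subset of individuals shares S/(m−1) sites in
expectation, S = `pair_sharing_fraction` × genome length. Drawing each
site's carrier count j from P(j) ∝ 1/(j(j−1)) on {2..n} and a uniform
j-subset achieves this exactly for every m: the containment probability is
C(j,m)/C(n,m), and Σ_j C(j,m)/(j(j−1)) telescopes by the hockey-stick
identity, giving S(n−1) sites in total. For n = 2 the law degenerates
(both copies would carry everything), so each site is assigned to exactly
one of the two individuals and S sites are drawn — the two genomes then
differ at S positions. A site counts as a polymorphism *for a subset* iff
its carrier pattern is non-constant within the subset, and as isolated iff
no other such polymorphism lies within k−1 bases; truth files hold the
2k−1 window pair (without/with the substitution) for every isolated site,
excluding sites within k−1 of a sequence end.

**Diploid individuals.** Two haplotypes per individual from a reference
and a variant list; homozygous variants land on both haplotypes, a
heterozygous one on a single haplotype chosen uniformly. When only a
variant count is given, two individuals are simulated with genotype
classes hom/hom : hom/het : het/het in proportions 0.09 : 0.69 : 0.22,
the mix observed in human chromosome-wide variant data.

**Reads.** Single-end, fixed length, uniform start and strand, drawn until
coverage × total length bases; each base is substituted independently with
probability `error_rate` (uniform wrong base). Qualities are a constant
PHRED 37 (optionally a lower value at error positions, or absent). No
indels, no coverage waves, no quality decay along the read, no
paired-end structure: the generator reproduces the published simulation
protocol, not a sequencer. Consequently the green tests certify the
algorithmic chain (graph → bubbles → coherency → ranking → evaluation),
not robustness to indel errors or coverage bias on real libraries — on
real data the k-read-coherency and phi filters carry that burden.

All randomness flows from `numpy.random.default_rng(seed)`; identical
seeds give byte-identical genomes, reads, truth files and output.

## Evaluation protocol

A prediction is a true positive iff its canonical 2k−1 pair string-equals
a truth pair (strand- and order-normalized, no alignment slack); each
truth record is consumable once. Unmatched predictions are false
positives, unmatched truth records false negatives; precision =
TP/(TP+FP), recall = TP/(TP+FN). Under b_policy = 1, predictions matching
any simulated polymorphism — isolated or not — are excluded from the false
positives without becoming true positives. A Hamming ≤ 2 near-miss count
is reported for false positives as a debugging aid only.

## Problem sizes used for validation

The packaged checks run two cohorts chosen to mirror the published
two-haploid and 30-haploid experiments at desk scale: (i) 1 Mb genome, two
individuals, 0.1% site density, 40× of 100 bp reads at 0.1% error, k=31,
c=4, b=0; (ii) 200 kb genome, 30 individuals, S = 200 pair-shared sites,
same read model and caller settings. On a uniform random genome these
conditions are repeat-free, so measured precision and recall sit at or
near 100% — at or above the figures reported on real bacterial genomes,
as expected. One documented consequence: with zero false positives the
phi > 0.2 filter cannot *strictly* improve precision (it is already 1),
so that comparison is vacuous under (i); the filter's ≥ 99%-true property
does hold and is asserted.

## Numerical and degenerate-input choices

* k ∈ [3, 63]; k ≤ 31 uses vectorized 2-bit uint64 paths, larger k a
  scalar fallback. Even k is accepted with a warning (palindromic k-mers
  become their own canonical form); odd k avoids the issue entirely.
* Windows containing non-ACGT characters are skipped, never substituted.
* Reads shorter than k are skipped and counted in the log.
* Ties everywhere (ranking, output order, enumeration) break on the
  canonical pair key; there is no hidden iteration-order dependence.
* phi is computed on float64 copies of the depth table; depth 0 forces
  mean PHRED 0.
* `filter_predictions` uses a strict > on phi (a value equal to the
  threshold is dropped) and an inclusive ≥ on extension lengths;
  `filter_markers` depth bounds are inclusive on both ends.

## Known limitations

Only isolated biallelic substitutions are called: indel bubbles (unequal
path lengths), SNP clusters and tri-allelic merging are out of scope
(tri-allelic sites surface as up to three pairwise bubbles for downstream
filters to reconcile). Calls carry no genomic coordinates — localization
requires a reference by definition. The mapper is gap-free, so an indel
inside a read simply costs that read its alignment. The exact k-mer
membership structure favors clarity over the memory footprint of
probabilistic representations; genomes beyond a few hundred Mb of distinct
k-mers will feel it.
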