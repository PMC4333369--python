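"""SNP bubble enumeration, branching classification and context extension.

An isolated substitution turns into a *bubble* in the de Bruijn graph: two
paths of length 2k-1 written p·a·q and p·b·q with p, q shared (k-1)-mers and
a != b the two alleles at the central position k-1.  Bubbles are discovered
from any solid k-mer that right-extends with two distinct nucleotides, then
completed by k-1 synchronised right extensions that must agree on every
appended base; a step with no shared extension discards the bubble, which is
what restricts calls to isolated SNPs.

Branching classes (checked in both directions over the completed paths):

* ``clean`` - every extension step had exactly one choice on each path;
* ``simply_branching`` - some step had >= 2 choices on a path, but the two
  paths never shared two identical extension nucleotides at the same step;
* ``symmetrically_branching`` - some step offered the same >= 2 nucleotides
  to both paths (the signature of a repeat-induced false bubble).

The ``b_policy`` filter keeps clean bubbles only (0, default), clean plus
simply-branching (1), or everything (2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._seq import (
    BASES,
    canonical_code,
    code_to_str,
    encode_seq,
    kmer_codes,
    revcomp,
    revcomp_codes,
    str_to_code,
)
from .kmer_graph import DeBruijnGraph

logger = logging.getLogger(__name__)

CLEAN = "clean"
SIMPLY_BRANCHING = "simply_branching"
SYMMETRICALLY_BRANCHING = "symmetrically_branching"

# safety valve on symmetric-branch exploration of one start pair
_MAX_COMPLETIONS = 256


@dataclass
class Bubble:
    """A pair of 2k-1 paths differing exactly at the central base."""

    path_a: str
    path_b: str
    k: int
    branching_class: str = CLEAN
    left_contig: str = ""
    right_contig: str = ""

    @property
    def snp_index(self) -> int:
        return self.k - 1

    @property
    def left_ext_len(self) -> int:
        return len(self.left_contig)

    @property
    def right_ext_len(self) -> int:
        return len(self.right_contig)

    @property
    def alleles(self) -> tuple[str, str]:
        i = self.snp_index
        return self.path_a[i], self.path_b[i]

    def key(self) -> tuple[str, str]:
        return canonical_pair(self.path_a, self.path_b)

    def __post_init__(self) -> None:
        if len(self.path_a) != 2 * self.k - 1 or len(self.path_b) != 2 * self.k - 1:
            raise ValueError("bubble paths must have length 2k-1")
        i = self.snp_index
        if self.path_a[i] == self.path_b[i]:
            raise ValueError("bubble paths must differ at the central base")
        if (
            self.path_a[:i] != self.path_b[:i]
            or self.path_a[i + 1 :] != self.path_b[i + 1 :]
        ):
            raise ValueError("bubble paths may differ only at the central base")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical representation of a path pair.

    Among the four equivalent write-ups (swap the two paths; reverse
    complement both) the lexicographically smallest (path_a, path_b) tuple
    is chosen, so every SNP has exactly one representation.
    """
    ra, rb = revcomp(a), revcomp(b)
    return min((a, b), (b, a), (ra, rb), (rb, ra))


def _oriented_solid_codes(graph: DeBruijnGraph) -> Iterator[int]:
    """Each solid k-mer in both orientations, without duplication."""
    from ._seq import revcomp_code

    for code in graph.solid:
        yield code
        yield revcomp_code(code, graph.k)


def find_bubble_starts(
    graph: DeBruijnGraph,
) -> Iterator[tuple[str, tuple[str, str]]]:
    """Yield (k-mer, {a, b}) for every solid k-mer with >= 2 right extensions.

    Every solid k-mer is examined on both strands; a k-mer with d >= 2 right
    extensions yields all C(d, 2) unordered pairs.
    """
    k = graph.k
    if graph.solid_array is not None and len(graph.solid_array):
        fwd = graph.solid_array
        for oriented in (fwd, revcomp_codes(fwd, k)):
            deg = graph.right_degree_matrix(oriented)
            hits = np.flatnonzero(deg.sum(axis=1) >= 2)
            for i in hits:
                kmer = code_to_str(int(oriented[i]), k)
                exts = [BASES[a] for a in range(4) if deg[i, a]]
                for a, b in itertools.combinations(exts, 2):
                    yield kmer, (a, b)
    else:
        for code in _oriented_solid_codes(graph):
            exts = graph.right_ext_codes(code)
            if len(exts) >= 2:
                kmer = code_to_str(code, k)
                for a, b in itertools.combinations(exts, 2):
                    yield kmer, (BASES[a], BASES[b])


def extend_bubble_all(
    graph: DeBruijnGraph, start: str, alpha: str, beta: str
) -> list[Bubble]:
    """All completions of the bubble opened at ``start`` by alleles a/b.

    Performs k-1 synchronised right extensions; whenever a step offers
    several nucleotides shared by both paths, every choice is explored (such
    bubbles are symmetrically branching and each completion is returned).
    Returns [] when some step has no shared extension.
    """
    if alpha == beta:
        raise ValueError("bubble alleles must differ")
    k = graph.k
    s = str_to_code(start)
    mask = (1 << (2 * k)) - 1
    ca = ((s << 2) & mask) | str_to_code(alpha)
    cb = ((s << 2) & mask) | str_to_code(beta)
    if not (graph.contains_code(ca) and graph.contains_code(cb)):
        return []

    out: list[Bubble] = []
    # stack of (steps_done, end_a, end_b, appended bases)
    stack: list[tuple[int, int, int, str]] = [(0, ca, cb, "")]
    while stack:
        step, ea, eb, tail = stack.pop()
        if step == k - 1:
            prefix = start[1:]
            out.append(
                Bubble(
                    path_a=prefix + alpha + tail,
                    path_b=prefix + beta + tail,
                    k=k,
                )
            )
            if len(out) >= _MAX_COMPLETIONS:
                logger.warning(
                    "bubble at %s truncated after %d completions", start, len(out)
                )
                break
            continue
        next_a = graph.right_ext_codes(ea)
        common = [x for x in graph.right_ext_codes(eb) if x in next_a]
        for x in common:
            stack.append(
                (
                    step + 1,
                    ((ea << 2) & mask) | x,
                    ((eb << 2) & mask) | x,
                    tail + BASES[x],
                )
            )
    return out


def extend_bubble(
    graph: DeBruijnGraph, start: str, alpha: str, beta: str
) -> Bubble | None:
    """First completion of the bubble, or None when it cannot be completed."""
    done = extend_bubble_all(graph, start, alpha, beta)
    return done[0] if done else None


def _ext_sets_vector(graph: DeBruijnGraph, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Right- and left-extension base masks for every window of a path."""
    k = graph.k
    codes, _ = kmer_codes(encode_seq(path), k)
    right = graph.right_degree_matrix(codes)
    # a left-extends w  <=>  comp(a) right-extends revcomp(w)
    left = graph.right_degree_matrix(revcomp_codes(codes, k))[:, ::-1]
    return right, left


def classify_branching(graph: DeBruijnGraph, bubble: Bubble) -> str:
    """Branching class of a completed bubble, checked in both directions.

    The construction steps are re-walked on the completed paths: right
    extensions of the windows at offsets 0..k-2 and, mirroring the walk,
    left extensions of the windows at offsets k-1..1.
    """
    k = graph.k
    if graph.solid_array is not None:
        ra, la = _ext_sets_vector(graph, bubble.path_a)
        rb, lb = _ext_sets_vector(graph, bubble.path_b)
        steps_a = np.concatenate([ra[: k - 1], la[1:k]])
        steps_b = np.concatenate([rb[: k - 1], lb[1:k]])
        if np.any((steps_a & steps_b).sum(axis=1) >= 2):
            return SYMMETRICALLY_BRANCHING
        if np.all(steps_a.sum(axis=1) == 1) and np.all(steps_b.sum(axis=1) == 1):
            return CLEAN
        return SIMPLY_BRANCHING

    sym = False
    clean = True
    for pa_win, pb_win, ext in _branch_steps(graph, bubble):
        ea, eb = ext
        if len(ea) != 1 or len(eb) != 1:
            clean = False
        if len(set(ea) & set(eb)) >= 2:
            sym = True
    if sym:
        return SYMMETRICALLY_BRANCHING
    return CLEAN if clean else SIMPLY_BRANCHING


def _branch_steps(graph: DeBruijnGraph, bubble: Bubble):
    k = graph.k
    pa, pb = bubble.path_a, bubble.path_b
    for t in range(k - 1):
        wa, wb = pa[t : t + k], pb[t : t + k]
        yield wa, wb, (
            graph.right_ext_codes(str_to_code(wa)),
            graph.right_ext_codes(str_to_code(wb)),
        )
    for t in range(k - 1, 0, -1):
        wa, wb = pa[t : t + k], pb[t : t + k]
        yield wa, wb, (
            graph.left_ext_codes(str_to_code(wa)),
            graph.left_ext_codes(str_to_code(wb)),
        )


_POLICY_KEEP = {
    0: {CLEAN},
    1: {CLEAN, SIMPLY_BRANCHING},
    2: {CLEAN, SIMPLY_BRANCHING, SYMMETRICALLY_BRANCHING},
}


def enumerate_bubbles(graph: DeBruijnGraph, b_policy: int = 0) -> list[Bubble]:
    """Full bubble scan: detect starts, complete, classify, deduplicate.

    Each SNP is reported once in its canonical representation (see
    :func:`canonical_pair`); output is sorted by that key for determinism.
    """
    if b_policy not in _POLICY_KEEP:
        raise ValueError(f"b_policy must be 0, 1 or 2, got {b_policy!r}")
    keep = _POLICY_KEEP[b_policy]
    seen: dict[tuple[str, str], Bubble] = {}
    for start, (a, b) in find_bubble_starts(graph):
        for bubble in extend_bubble_all(graph, start, a, b):
            key = bubble.key()
            if key in seen:
                continue
            canon = Bubble(path_a=key[0], path_b=key[1], k=graph.k)
            canon.branching_class = classify_branching(graph, canon)
            seen[key] = canon
    out = [bub for key, bub in sorted(seen.items()) if bub.branching_class in keep]
    logger.info(
        "enumerated %d distinct bubbles, kept %d at b=%d", len(seen), len(out), b_policy
    )
    return out


def _unitig_walk(graph: DeBruijnGraph, stem_kmer: str, max_len: int, visited: set[int]) -> str:
    """Rightward unitig walk starting past ``stem_kmer`` (a solid k-mer).

    The first step only requires a unique right extension (the reverse fork
    at the bubble boundary is the bubble itself); subsequent steps use the
    full unitig rule: unique forward extension whose target is not reachable
    from elsewhere (unique reverse extension) and not yet visited.
    """
    k = graph.k
    mask = (1 << (2 * k)) - 1
    cur = str_to_code(stem_kmer)
    out: list[str] = []
    first = True
    while len(out) < max_len:
        exts = graph.right_ext_codes(cur)
        if len(exts) != 1:
            break
        nxt = ((cur << 2) & mask) | exts[0]
        if not first and len(graph.left_ext_codes(nxt)) != 1:
            break  # incoming node is a merge point
        canon = canonical_code(nxt, k)
        if canon in visited:
            break
        visited.add(canon)
        out.append(BASES[exts[0]])
        cur = nxt
        first = False
    return "".join(out)


def extend_context(
    graph: DeBruijnGraph, bubble: Bubble, max_len: int | None = None
) -> Bubble:
    """Fill the longest unambiguous left/right contigs flanking a bubble.

    Walks outward from the shared flanks while exactly one extension exists
    and the walk stays on a unitig (the incoming node is not itself a merge
    point), stopping at ambiguity, at an already-visited node, or after
    ``max_len`` appended bases (default 10*k).
    """
    k = graph.k
    if max_len is None:
        max_len = 10 * k
    visited: set[int] = set()
    for path in (bubble.path_a, bubble.path_b):
        codes, _ = (
            kmer_codes(encode_seq(path), k)
            if k <= 31
            else (
                [str_to_code(path[i : i + k]) for i in range(k)],
                None,
            )
        )
        visited.update(canonical_code(int(c), k) for c in codes)

    right = _unitig_walk(graph, bubble.path_a[k - 1 :], max_len, set(visited))
    left_rc = _unitig_walk(
        graph, revcomp(bubble.path_a[:k]), max_len, set(visited)
    )
    bubble.right_contig = right
    bubble.left_contig = revcomp(left_rc)
    return bubble
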