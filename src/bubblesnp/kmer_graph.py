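"""k-mer counting and the solid-k-mer de Bruijn graph.

The graph substrate of the caller: canonical k-mers are counted over the
input read sets, k-mers reaching the coverage threshold ``c`` are kept
("solid"), and the resulting node set supports exact, strand-symmetric
membership and single-nucleotide neighbour queries.  Edges are implicit:
two solid k-mers are linked iff they overlap on k-1 bases, so only the node
set is stored (2-bit packed integers, see :mod:`bubblesnp._seq`).

k should be odd so that no k-mer equals its own reverse complement and the
canonical form is unambiguous; even k is accepted (the toy examples in this
package's tests use k=4) but triggers a warning.

Solidity semantics
------------------
``build_graph`` applied to a single (pooled) count table keeps k-mers whose
pooled count is >= c.  Applied to a list of per-read-set tables it keeps
k-mers reaching c in *at least one* set, which is the threshold the pipeline
uses by default: with many pooled high-coverage sets, a pooled threshold
lets recurrent sequencing errors through, while a per-set threshold scales
with the per-sample coverage the user actually knows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._seq import (
    BASES,
    canonical_code,
    canonical_codes,
    code_to_str,
    encode_seq,
    kmer_codes,
    revcomp_code,
    revcomp_codes,
    str_to_code,
)

logger = logging.getLogger(__name__)

# bases concatenated into one array per chunk before vector counting
_CHUNK_BASES = 8_000_000


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)):
        raise ValueError(f"k must be an integer, got {k!r}")
    if k < 3 or k > 63:
        raise ValueError(f"k must be in [3, 63], got {k}")
    if k % 2 == 0:
        logger.warning(
            "even k=%d admits palindromic k-mers (their own reverse "
            "complement); odd k is recommended",
            k,
        )


def _iter_seqs(read_collection) -> Iterator[str]:
    """Yield plain sequences from a ReadSet or any iterable of reads."""
    reads = getattr(read_collection, "reads", read_collection)
    for r in reads:
        if isinstance(r, str):
            yield r
        else:  # (sequence, quality) pair
            yield r[0]


@dataclass
class KmerCountTable:
    """Canonical k-mer -> pooled occurrence count.

    Counts are stored as parallel sorted ``codes``/``counts`` arrays for
    k <= 31 and as a plain dict of Python ints otherwise; the mapping-style
    accessors below hide the difference.
    """

    k: int
    codes: np.ndarray | None = None
    counts: np.ndarray | None = None
    _dict: dict[int, int] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        if self._dict is not None:
            return len(self._dict)
        return 0 if self.codes is None else len(self.codes)

    def total(self) -> int:
        """Total number of valid k-mer windows counted."""
        if self._dict is not None:
            return sum(self._dict.values())
        return 0 if self.counts is None else int(self.counts.sum())

    def get(self, kmer: str, default: int = 0) -> int:
        code = canonical_code(str_to_code(kmer), self.k)
        if self._dict is not None:
            return self._dict.get(code, default)
        if self.codes is None or len(self.codes) == 0:
            return default
        i = int(np.searchsorted(self.codes, np.uint64(code)))
        if i < len(self.codes) and int(self.codes[i]) == code:
            return int(self.counts[i])
        return default

    def __getitem__(self, kmer: str) -> int:
        v = self.get(kmer, -1)
        if v < 0:
            raise KeyError(kmer)
        return v

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer, 0) > 0

    def items(self) -> Iterator[tuple[str, int]]:
        if self._dict is not None:
            for code, n in self._dict.items():
                yield code_to_str(code, self.k), n
        elif self.codes is not None:
            for code, n in zip(self.codes, self.counts):
                yield code_to_str(int(code), self.k), int(n)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def write_tsv(self, path) -> None:
        """Debug dump: one ``kmer<TAB>count`` line per canonical k-mer."""
        with open(path, "w") as fh:
            for kmer, n in self.items():
                fh.write(f"{kmer}\t{n}\n")


def _count_codes_numpy(read_collections, k: int) -> np.ndarray:
    """Canonical codes of every valid window over the given collections."""
    chunks: list[np.ndarray] = []
    buf: list[np.ndarray] = []
    sep = np.array([4], dtype=np.uint8)
    pending = 0

    def flush() -> None:
        nonlocal pending
        if not buf:
            return
        arr = np.concatenate(buf)
        buf.clear()
        pending = 0
        codes, valid = kmer_codes(arr, k)
        if len(codes):
            canon, _ = canonical_codes(codes[valid], k)
            if len(canon):
                chunks.append(canon)

    for rc in read_collections:
        for seq in _iter_seqs(rc):
            if len(seq) < k:
                continue
            buf.append(encode_seq(seq))
            buf.append(sep)  # separator breaks windows between reads
            pending += len(seq) + 1
            if pending >= _CHUNK_BASES:
                flush()
    flush()
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(chunks)


def _count_python(read_collections, k: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    for rc in read_collections:
        for seq in _iter_seqs(rc):
            s = seq.upper()
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if any(ch not in "ACGT" for ch in w):
                    continue
                code = canonical_code(str_to_code(w), k)
                counts[code] = counts.get(code, 0) + 1
    return counts


def count_kmers(
    read_sets: Sequence, k: int, *, per_set: bool = False
) -> KmerCountTable | list[KmerCountTable]:
    """Count canonical k-mers over read sets pooled together.

    Parameters
    ----------
    read_sets : sequence of read collections (ReadSet objects or iterables of
        sequences / (sequence, quality) pairs).
    k : odd k-mer size in [3, 63].
    per_set : if True, return one table per read set instead of pooling.

    Windows containing a non-ACGT character are skipped; a k-mer and its
    reverse complement share a single counter.
    """
    _check_k(k)
    groups = [[rs] for rs in read_sets] if per_set else [list(read_sets)]
    tables: list[KmerCountTable] = []
    for group in groups:
        if k <= 31:
            canon = _count_codes_numpy(group, k)
            codes, counts = np.unique(canon, return_counts=True)
            tables.append(KmerCountTable(k=k, codes=codes, counts=counts))
        else:
            tables.append(KmerCountTable(k=k, _dict=_count_python(group, k)))
    return tables if per_set else tables[0]


@dataclass
class DeBruijnGraph:
    """Set of solid canonical k-mers with strand-symmetric neighbour queries."""

    k: int
    c: int
    solid: frozenset  # canonical codes as Python ints
    solid_array: np.ndarray | None = None  # sorted uint64 array (k <= 31)

    def __len__(self) -> int:
        return len(self.solid)

    def __contains__(self, kmer: str) -> bool:
        return self.contains_code(str_to_code(kmer))

    def contains_code(self, code: int) -> bool:
        """Membership of an (arbitrarily oriented) k-mer code."""
        return min(code, revcomp_code(code, self.k)) in self.solid

    # -- neighbour queries --------------------------------------------------

    def right_ext_codes(self, code: int) -> list[int]:
        """Bases a (oriented, non-canonical) k-mer code extends right with."""
        mask = (1 << (2 * self.k)) - 1
        stem = (code << 2) & mask
        return [a for a in range(4) if self.contains_code(stem | a)]

    def left_ext_codes(self, code: int) -> list[int]:
        stem = code >> 2
        shift = 2 * (self.k - 1)
        return [a for a in range(4) if self.contains_code((a << shift) | stem)]

    def right_extensions(self, kmer: str) -> set[str]:
        """Nucleotides a such that suffix(kmer, k-1)+a is solid."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        return {BASES[a] for a in self.right_ext_codes(str_to_code(kmer))}

    def left_extensions(self, kmer: str) -> set[str]:
        """Nucleotides a such that a+prefix(kmer, k-1) is solid."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        return {BASES[a] for a in self.left_ext_codes(str_to_code(kmer))}

    # -- bulk neighbour queries (k <= 31 fast path) -------------------------

    def member_mask(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership of oriented codes (canonicalised here)."""
        if self.solid_array is None or len(self.solid_array) == 0:
            return np.zeros(len(codes), dtype=bool)
        canon, _ = canonical_codes(codes, self.k)
        idx = np.searchsorted(self.solid_array, canon)
        idx[idx >= len(self.solid_array)] = len(self.solid_array) - 1
        return self.solid_array[idx] == canon

    def right_degree_matrix(self, codes: np.ndarray) -> np.ndarray:
        """(n, 4) boolean matrix: which bases right-extend each oriented code."""
        mask = np.uint64((1 << (2 * self.k)) - 1)
        stems = (codes << np.uint64(2)) & mask
        out = np.empty((len(codes), 4), dtype=bool)
        for a in range(4):
            out[:, a] = self.member_mask(stems | np.uint64(a))
        return out


def build_graph(
    table: KmerCountTable | Sequence[KmerCountTable], c: int
) -> DeBruijnGraph:
    """Keep k-mers with count >= c and wrap them as a de Bruijn graph.

    ``table`` may be a single pooled :class:`KmerCountTable` (pooled-sum
    solidity) or a list of per-read-set tables (solid iff count >= c in at
    least one set; see module docstring).
    """
    if not isinstance(c, (int, np.integer)) or c < 1:
        raise ValueError(f"coverage threshold c must be an integer >= 1, got {c!r}")
    tables = [table] if isinstance(table, KmerCountTable) else list(table)
    if not tables:
        raise ValueError("no count tables given")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all count tables must share the same k")

    if all(t._dict is None for t in tables):
        parts = [
            t.codes[t.counts >= c]
            for t in tables
            if t.codes is not None and len(t.codes)
        ]
        arr = (
            np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.uint64)
        )
        solid = frozenset(int(x) for x in arr)
        logger.info("graph: %d solid k-mers (k=%d, c=%d)", len(solid), k, c)
        return DeBruijnGraph(k=k, c=c, solid=solid, solid_array=arr)

    keep: set[int] = set()
    for t in tables:
        if t._dict is not None:
            keep.update(code for code, n in t._dict.items() if n >= c)
        elif t.codes is not None:
            keep.update(int(x) for x in t.codes[t.counts >= c])
    arr = None
    if k <= 31:
        arr = np.array(sorted(keep), dtype=np.uint64)
    return DeBruijnGraph(k=k, c=c, solid=frozenset(keep), solid_array=arr)
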