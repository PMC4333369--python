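"""Read remapping onto bubble paths, k-read-coherency and coverage profiling.

A de Bruijn graph alone cannot say whether a predicted path was ever seen in
one read, nor what its coverage or base qualities are: overlapping k-mers
from distinct reads can assemble chimeric paths across repeats.  This module
therefore maps every read of every input set back onto the 2k-1 bubble paths
with a seed-and-extend, gap-free, semi-global aligner (read overhangs beyond
path ends are free; by default one substitution is allowed, but never at the
polymorphic position), and keeps only predictions that at least one read set
renders *k-read-coherent*:

    a path is k-read-coherent for a read set at threshold c if every k-mer
    window of the path is fully contained in >= c accepted read alignments.

This is strictly stronger than plain read-coherency (>= c reads covering
every position) and rejects chimeras stitched from reads that only overlap
the path with their ends.  Per read set and per path, the depth and the mean
PHRED quality of the reads covering the polymorphic base are recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import canonical_codes, encode_seq, kmer_codes, revcomp
from .bubble_caller import Bubble

logger = logging.getLogger(__name__)

_MAP_CHUNK_BASES = 8_000_000


@dataclass
class ReadSet:
    """One input read collection; quality strings are PHRED+33 or None."""

    set_id: int
    reads: list[tuple[str, str | None]]
    name: str = ""

    @property
    def has_quality(self) -> bool:
        return any(q is not None for _, q in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], set_id: int = 0, name: str = ""
    ) -> "ReadSet":
        return cls(set_id=set_id, reads=[(s, None) for s in seqs], name=name)


@dataclass
class Alignment:
    """An accepted gap-free placement of a read on one bubble path."""

    path_id: int  # global path row (2*bubble + 0/1)
    strand: str  # '+' read as given, '-' read reverse complemented
    offset: int  # position of the (oriented) read start on the path
    span: tuple[int, int]  # clipped overlap [start, end) on the path
    mismatches: int
    covers_snp: bool


@dataclass
class CoverageProfile:
    """Per-(read set, path) evidence for one bubble.

    ``depth[s, p]``: accepted alignments of set s on path p covering the
    polymorphic base (allele-matching by construction).  ``mean_phred[s, p]``
    is the mean PHRED at that base over those reads (0 when depth is 0 or
    the set has no qualities).  ``window_cov[s, p, i]`` counts the reads
    fully containing the k-mer window starting at path position i, the
    quantity k-read-coherency thresholds.
    """

    depth: np.ndarray
    mean_phred: np.ndarray
    window_cov: np.ndarray
    k_coherent: list[bool]
    has_quality: list[bool]

    @property
    def n_sets(self) -> int:
        return self.depth.shape[0]

    def snp_depth_table(self) -> np.ndarray:
        """2 x m table of allele-supporting depths (rows = paths)."""
        return self.depth.T.copy()

    def total_depth(self) -> int:
        return int(self.depth.sum())


class PathIndex:
    """Seed index: every k-mer of every path (both strands) -> hit list."""

    def __init__(self, bubbles: Sequence[Bubble], k: int):
        self.k = k
        self.snp_index = k - 1
        self.bubbles = list(bubbles)
        self.path_seqs: list[str] = []
        self.path_arrs: list[np.ndarray] = []
        for bub in self.bubbles:
            for p in (bub.path_a, bub.path_b):
                self.path_seqs.append(p)
                self.path_arrs.append(encode_seq(p))
        self.path_len = 2 * k - 1
        self.n_windows = self.path_len - k + 1  # == k

        canon_l, pid_l, off_l, fwd_l = [], [], [], []
        for pid, arr in enumerate(self.path_arrs):
            codes, valid = kmer_codes(arr, k)
            canon, fwd = canonical_codes(codes, k)
            canon_l.append(canon[valid])
            fwd_l.append(fwd[valid])
            pid_l.append(np.full(valid.sum(), pid, dtype=np.int64))
            off_l.append(np.flatnonzero(valid).astype(np.int64))
        if canon_l and sum(len(x) for x in canon_l):
            canon = np.concatenate(canon_l)
            order = np.argsort(canon, kind="stable")
            self._entry_canon = canon[order]
            self._entry_pid = np.concatenate(pid_l)[order]
            self._entry_off = np.concatenate(off_l)[order]
            self._entry_fwd = np.concatenate(fwd_l)[order]
            self.keys, starts = np.unique(self._entry_canon, return_index=True)
            self._key_start = starts
            self._key_end = np.append(starts[1:], len(self._entry_canon))
        else:
            self.keys = np.empty(0, dtype=np.uint64)
            self._key_start = np.empty(0, dtype=np.int64)
            self._key_end = np.empty(0, dtype=np.int64)
            self._entry_pid = np.empty(0, dtype=np.int64)
            self._entry_off = np.empty(0, dtype=np.int64)
            self._entry_fwd = np.empty(0, dtype=bool)

    def __len__(self) -> int:
        return len(self._entry_pid)


def index_paths(bubbles: Sequence[Bubble], k: int | None = None) -> PathIndex:
    """Build the seed index over every path of every bubble."""
    if k is None:
        if not bubbles:
            raise ValueError("cannot infer k from an empty bubble list")
        k = bubbles[0].k
    return PathIndex(bubbles, k)


def _verify(
    index: PathIndex,
    read_arr: np.ndarray,
    pid: int,
    offset: int,
    max_mismatch: int,
) -> tuple[bool, int, bool, int, int]:
    """Check one placement; returns (accepted, mismatches, covers_snp, s, e)."""
    path_arr = index.path_arrs[pid]
    plen = index.path_len
    rlen = len(read_arr)
    s = max(0, offset)
    e = min(plen, offset + rlen)
    if e - s < index.k:
        return False, 0, False, s, e
    mm = int(
        np.count_nonzero(read_arr[s - offset : e - offset] != path_arr[s:e])
    )
    si = index.snp_index
    covers = s <= si < e
    if covers and read_arr[si - offset] != path_arr[si]:
        return False, mm, covers, s, e  # no substitution at the SNP, ever
    if mm > max_mismatch:
        return False, mm, covers, s, e
    return True, mm, covers, s, e


def map_read(
    read: str, index: PathIndex, max_mismatch: int = 1
) -> list[Alignment]:
    """Semi-global placements of one read over all indexed paths.

    Seed hits (exact k-mers, both strands) imply diagonal placements;
    duplicates from multiple seeds are collapsed, then each placement is
    accepted iff its substitution count over the overlap is <= max_mismatch
    and the polymorphic base, when covered, matches exactly.
    """
    k = index.k
    if len(read) < k:
        return []
    arr = encode_seq(read)
    codes, valid = kmer_codes(arr, k)
    canon, fwd = canonical_codes(codes, k)
    idx = np.searchsorted(index.keys, canon)
    placements: set[tuple[int, bool, int]] = set()
    nkeys = len(index.keys)
    rlen = len(read)
    for pos in np.flatnonzero(valid):
        i = idx[pos]
        if i >= nkeys or index.keys[i] != canon[pos]:
            continue
        for j in range(index._key_start[i], index._key_end[i]):
            pid = int(index._entry_pid[j])
            same = bool(index._entry_fwd[j]) == bool(fwd[pos])
            if same:
                placements.add((pid, True, int(index._entry_off[j]) - int(pos)))
            else:
                placements.add(
                    (pid, False, int(index._entry_off[j]) - (rlen - k - int(pos)))
                )
    out: list[Alignment] = []
    rc_arr = None
    for pid, is_fwd, off in sorted(placements):
        if is_fwd:
            r = arr
        else:
            if rc_arr is None:
                rc_arr = encode_seq(revcomp(read))
            r = rc_arr
        ok, mm, covers, s, e = _verify(index, r, pid, off, max_mismatch)
        if ok:
            out.append(
                Alignment(
                    path_id=pid,
                    strand="+" if is_fwd else "-",
                    offset=off,
                    span=(s, e),
                    mismatches=mm,
                    covers_snp=covers,
                )
            )
    return out


def k_read_coherent(
    path: str,
    placements: Iterable[tuple[int, int] | Alignment],
    c: int,
    k: int | None = None,
) -> bool:
    """k-read-coherency of one path for one read set.

    ``placements`` are accepted alignment spans (clipped to the path); the
    path is k-read-coherent iff every window [i, i+k) with
    i in [0, len(path)-k] is fully contained in >= c spans.  The criterion
    is strand-blind: spans of reads mapped on either strand count alike.
    k defaults to (len(path)+1)//2, the k of a 2k-1 bubble path.
    """
    if k is None:
        k = (len(path) + 1) // 2
    n_win = len(path) - k + 1
    if n_win <= 0:
        return False
    diff = np.zeros(n_win + 1, dtype=np.int64)
    for pl in placements:
        s, e = pl.span if isinstance(pl, Alignment) else pl
        if e - s >= k:
            diff[s] += 1
            diff[e - k + 1] -= 1
    return bool(np.all(np.cumsum(diff[:-1]) >= c))


class _SetAccumulator:
    """Depth / quality / window-coverage tallies for one read set."""

    def __init__(self, n_paths: int, n_windows: int):
        self.depth = np.zeros(n_paths, dtype=np.int64)
        self.phred_sum = np.zeros(n_paths, dtype=np.float64)
        self.win_diff = np.zeros((n_paths, n_windows + 1), dtype=np.int64)
        self.short_reads = 0

    def window_cov(self) -> np.ndarray:
        return np.cumsum(self.win_diff[:, :-1], axis=1)


def _map_read_set(
    read_set: ReadSet, index: PathIndex, max_mismatch: int
) -> _SetAccumulator:
    """Map a whole read set; placements are found vectorised per chunk."""
    k = index.k
    acc = _SetAccumulator(len(index.path_seqs), index.n_windows)
    if len(index.keys) == 0:
        return acc

    reads = read_set.reads
    chunk: list[int] = []
    bases = 0
    for ridx, (seq, _q) in enumerate(reads):
        if len(seq) < k:
            acc.short_reads += 1
            continue
        chunk.append(ridx)
        bases += len(seq) + 1
        if bases >= _MAP_CHUNK_BASES:
            _map_chunk(reads, chunk, index, max_mismatch, acc)
            chunk, bases = [], 0
    if chunk:
        _map_chunk(reads, chunk, index, max_mismatch, acc)
    if acc.short_reads:
        logger.info(
            "read set %d: skipped %d reads shorter than k=%d",
            read_set.set_id,
            acc.short_reads,
            k,
        )
    return acc


def _map_chunk(
    reads, chunk: list[int], index: PathIndex, max_mismatch: int, acc: _SetAccumulator
) -> None:
    k = index.k
    arrs = [encode_seq(reads[r][0]) for r in chunk]
    lens = np.array([len(a) for a in arrs], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lens + 1)])[:-1]
    sep = np.array([4], dtype=np.uint8)
    cat = np.concatenate([x for a in arrs for x in (a, sep)])

    codes, valid = kmer_codes(cat, k)
    canon, fwd = canonical_codes(codes, k)
    idx = np.searchsorted(index.keys, canon)
    idx[idx >= len(index.keys)] = len(index.keys) - 1
    hit = valid & (index.keys[idx] == canon)
    gpos = np.flatnonzero(hit)
    if len(gpos) == 0:
        return
    key_i = idx[gpos]
    local = np.searchsorted(starts, gpos, side="right") - 1
    pos = gpos - starts[local]
    rlen = lens[local]

    counts = index._key_end[key_i] - index._key_start[key_i]
    rep = np.repeat(np.arange(len(gpos)), counts)
    ent = (
        np.repeat(index._key_start[key_i], counts)
        + np.arange(len(rep))
        - np.repeat(np.concatenate([[0], np.cumsum(counts)])[:-1], counts)
    )
    pid = index._entry_pid[ent]
    eoff = index._entry_off[ent]
    same = index._entry_fwd[ent] == fwd[gpos][rep]
    off = np.where(
        same, eoff - pos[rep], eoff - (rlen[rep] - k - pos[rep])
    )
    # pack (read, path, strand, offset) and deduplicate placements
    packed = (
        (local[rep].astype(np.int64) << np.int64(38))
        | (pid.astype(np.int64) << np.int64(17))
        | (same.astype(np.int64) << np.int64(16))
        | (off.astype(np.int64) + np.int64(1 << 15))
    )
    packed = np.unique(packed)

    si = index.snp_index
    last_read = -1
    fwd_arr = rc_arr = None
    qual = None
    for p in packed:
        p = int(p)
        off_i = (p & 0xFFFF) - (1 << 15)
        is_fwd = bool((p >> 16) & 1)
        pid_i = (p >> 17) & 0x1FFFFF
        local_i = p >> 38
        if local_i != last_read:
            last_read = local_i
            fwd_arr = arrs[local_i]
            rc_arr = None
            qual = reads[chunk[local_i]][1]
        if is_fwd:
            r = fwd_arr
        else:
            if rc_arr is None:
                rc_arr = fwd_arr[::-1] ^ 3
                rc_arr[rc_arr > 3] = 4  # keep non-ACGT marked
            r = rc_arr
        ok, _mm, covers, s, e = _verify(index, r, pid_i, off_i, max_mismatch)
        if not ok:
            continue
        if e - s >= k:
            acc.win_diff[pid_i, s] += 1
            acc.win_diff[pid_i, e - k + 1] -= 1
        if covers:
            acc.depth[pid_i] += 1
            if qual is not None:
                j = si - off_i if is_fwd else len(qual) - 1 - (si - off_i)
                acc.phred_sum[pid_i] += ord(qual[j]) - 33
    return


def profile_predictions(
    bubbles: Sequence[Bubble],
    read_sets: Sequence[ReadSet],
    c: int,
    max_mismatch: int = 1,
    *,
    require_both_paths: bool = False,
):
    """Map all read sets to all bubble paths and keep coherent predictions.

    A bubble is retained iff at least one read set makes at least one of its
    paths k-read-coherent at threshold ``c`` (both paths must pass when
    ``require_both_paths`` is set).  Survivors carry a full
    :class:`CoverageProfile`.  Returns a list of
    :class:`~bubblesnp.ranking.SNPPrediction` (phi/rank not yet assigned).
    """
    from .ranking import SNPPrediction

    if not bubbles:
        return []
    k = bubbles[0].k
    index = PathIndex(bubbles, k)
    accs = [_map_read_set(rs, index, max_mismatch) for rs in read_sets]
    covs = [a.window_cov() for a in accs]
    has_q = [rs.has_quality for rs in read_sets]

    out = []
    n_sets = len(read_sets)
    for bi, bub in enumerate(bubbles):
        rows = (2 * bi, 2 * bi + 1)
        depth = np.stack([a.depth[list(rows)] for a in accs])  # (sets, 2)
        phred = np.stack([a.phred_sum[list(rows)] for a in accs])
        wcov = np.stack([cv[list(rows)] for cv in covs])  # (sets, 2, k)
        coh_path = wcov.min(axis=2) >= c  # (sets, 2)
        k_coh = [
            bool(coh_path[s].all() if require_both_paths else coh_path[s].any())
            for s in range(n_sets)
        ]
        if not any(k_coh):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_phred = np.where(depth > 0, phred / np.maximum(depth, 1), 0.0)
        for s in range(n_sets):
            if not has_q[s]:
                mean_phred[s] = 0.0
        profile = CoverageProfile(
            depth=depth,
            mean_phred=mean_phred,
            window_cov=wcov,
            k_coherent=k_coh,
            has_quality=list(has_q),
        )
        out.append(SNPPrediction(bubble=bub, profile=profile))
    logger.info(
        "k-read-coherency kept %d / %d bubbles (c=%d)", len(out), len(bubbles), c
    )
    return out
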