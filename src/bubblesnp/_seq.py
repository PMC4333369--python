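"""Low-level DNA encoding helpers shared by the graph, mapper and simulator.

k-mers are held as 2-bit packed integers (A=0, C=1, G=2, T=3, two bits per
base, first base in the highest bits).  For k <= 31 a k-mer fits in a single
``uint64`` and the bulk routines below operate on whole numpy arrays of codes;
for larger k the same arithmetic is done on Python ints.  Complementation is
``base ^ 3`` in this encoding, which is what makes the vectorised
reverse-complement bit shuffle work.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_BITS = {b: i for i, b in enumerate(BASES)}
_COMP_TABLE = str.maketrans("ACGTacgt", "TGCATGCA")

# byte -> 2-bit code, 4 marks anything that is not A/C/G/T (breaks windows)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-insensitive, ACGT only)."""
    return seq.translate(_COMP_TABLE)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array; non-ACGT characters become 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an encoded sequence, plus a validity mask.

    Returns ``(codes, valid)`` where ``codes[i]`` packs ``arr[i:i+k]`` and
    ``valid[i]`` is False whenever the window overlaps a non-ACGT position.
    Requires k <= 31 (single-word codes).
    """
    if k > 31:
        raise ValueError("vectorised k-mer codes require k <= 31")
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    base = (arr & 3).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | base[j : j + n]
    bad = np.concatenate([np.zeros(1, dtype=np.int64), np.cumsum(arr > 3)])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of an array of packed k-mer codes."""
    x = ~codes
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of both strands) codes and a forward-is-canonical flag."""
    rc = revcomp_codes(codes, k)
    fwd = codes <= rc
    return np.where(fwd, codes, rc), fwd


# ---------------------------------------------------------------------------
# scalar (Python int) versions, valid for any k

def str_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | _BASE_TO_BITS[ch.upper()]
    return code


def code_to_str(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    x = code ^ ((1 << (2 * k)) - 1)  # complement every base
    r = 0
    for _ in range(k):
        r = (r << 2) | (x & 3)
        x >>= 2
    return r


def canonical_code(code: int, k: int) -> int:
    return min(code, revcomp_code(code, k))
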