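"""Reading read sets (FASTA/FASTQ, optionally gzipped) and the prediction
multi-FASTA.

Predictions are serialized as a sorted multi-FASTA: two consecutive records
per SNP (one per allele path, best-ranked SNPs first), each sequence being
``left_contig + path + right_contig``.  The header carries every annotation
the caller produces, in a fixed grammar::

    >SNP_<id>|P_<offset>_<a>/<b>|left_<L>|right_<R>|<class>|C1_<d>|Q1_<q>|...|phi_<v>

where ``offset`` is the 0-based position of the polymorphic base within the
emitted sequence (= left extension length + k - 1), ``a`` the record's own
allele and ``b`` the partner allele, ``Ci``/``Qi`` the SNP-covering read
depth and mean PHRED of read set i on this path (``Qi_NA`` for sets without
qualities), and ``phi`` the Phi coefficient (4 decimals).  This grammar
carries exactly the documented annotation fields but is a format of this
package, not byte-compatible with any other tool's output.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .bubble_caller import Bubble
from .mapping import CoverageProfile, ReadSet
from .ranking import SNPPrediction

logger = logging.getLogger(__name__)


def _open_text(path):
    """Open a possibly gzip-compressed text file (magic-byte sniffing)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_one_file(path) -> list[tuple[str, str | None]]:
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        fh.seek(0)
        if first == ">":
            return [(seq.upper(), None) for _t, seq in SimpleFastaParser(fh)]
        if first == "@":
            reads: list[tuple[str, str | None]] = []
            try:
                for _t, seq, qual in FastqGeneralIterator(fh):
                    if len(seq) != len(qual):
                        raise ValueError(
                            f"{path}: record {len(reads) + 1}: sequence and "
                            f"quality lengths differ ({len(seq)} vs {len(qual)})"
                        )
                    reads.append((seq.upper(), qual))
            except ValueError as e:
                raise ValueError(f"{path}: record {len(reads) + 1}: {e}") from e
            return reads
        raise ValueError(
            f"{path}: cannot detect format (leading {first!r}, expected '>' or '@')"
        )


def read_read_sets(paths: Sequence) -> list[ReadSet]:
    """Load read files as ReadSets, one per file, preserving input order.

    Format (FASTA vs FASTQ) and gzip compression are auto-detected per file;
    mixing formats across files is allowed.  FASTQ qualities are kept as
    Sanger PHRED+33 strings.
    """
    out = []
    for i, path in enumerate(paths):
        reads = _read_one_file(path)
        out.append(ReadSet(set_id=i, reads=reads, name=str(path)))
        logger.info("read set %d: %d reads from %s", i, len(reads), path)
    return out


def _format_header(
    snp_id: int, pred: SNPPrediction, row: int
) -> str:
    bub = pred.bubble
    offset = bub.left_ext_len + bub.k - 1
    own = (bub.path_a, bub.path_b)[row][bub.snp_index]
    other = (bub.path_b, bub.path_a)[row][bub.snp_index]
    parts = [
        f"SNP_{snp_id}",
        f"P_{offset}_{own}/{other}",
        f"left_{bub.left_ext_len}",
        f"right_{bub.right_ext_len}",
        bub.branching_class,
    ]
    prof = pred.profile
    if prof is not None:
        for s in range(prof.n_sets):
            parts.append(f"C{s + 1}_{int(prof.depth[s, row])}")
            q = "NA" if not prof.has_quality[s] else f"{prof.mean_phred[s, row]:.2f}"
            parts.append(f"Q{s + 1}_{q}")
    parts.append(f"phi_{pred.phi:.4f}")
    return "|".join(parts)


def write_predictions(predictions: Sequence[SNPPrediction], out_path) -> None:
    """Write ranked predictions as the sorted multi-FASTA described above."""
    with open(out_path, "w") as fh:
        for snp_id, pred in enumerate(predictions, start=1):
            bub = pred.bubble
            for row, path in enumerate((bub.path_a, bub.path_b)):
                fh.write(f">{_format_header(snp_id, pred, row)}\n")
                fh.write(f"{bub.left_contig}{path}{bub.right_contig}\n")


def _parse_header(title: str) -> dict | None:
    """Parse a prediction header; None when it is not in the grammar."""
    parts = title.split("|")
    if len(parts) < 6 or not parts[0].startswith("SNP_"):
        return None
    try:
        out = {
            "snp_id": int(parts[0][4:]),
            "branching_class": parts[4],
            "phi": float(parts[-1].split("_", 1)[1]),
        }
        p_field = parts[1].split("_")
        out["offset"] = int(p_field[1])
        out["own"], out["other"] = p_field[2].split("/")
        out["left"] = int(parts[2].split("_", 1)[1])
        out["right"] = int(parts[3].split("_", 1)[1])
        depths, quals = [], []
        for f in parts[5:-1]:
            tag, val = f.split("_", 1)
            if tag.startswith("C"):
                depths.append(int(val))
            elif tag.startswith("Q"):
                quals.append(None if val == "NA" else float(val))
        out["depths"] = depths
        out["quals"] = quals
        return out
    except (IndexError, ValueError):
        return None


def read_predictions(path) -> list[SNPPrediction]:
    """Inverse of :func:`write_predictions`; also accepts bare pair files.

    A *bare pair file* is any multi-FASTA whose consecutive record pairs are
    two equal-length sequences differing at their central base (the truth
    format); such records yield predictions without profile annotations.
    """
    with _open_text(path) as fh:
        records = list(SimpleFastaParser(fh))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of records ({len(records)})")
    out: list[SNPPrediction] = []
    for i in range(0, len(records), 2):
        (t1, s1), (t2, s2) = records[i], records[i + 1]
        s1, s2 = s1.upper(), s2.upper()
        if len(s1) != len(s2):
            raise ValueError(
                f"{path}: records {i + 1}/{i + 2}: unequal sequence lengths"
            )
        h1, h2 = _parse_header(t1), _parse_header(t2)
        if h1 is not None and h2 is not None:
            if h1["snp_id"] != h2["snp_id"]:
                raise ValueError(
                    f"{path}: records {i + 1}/{i + 2}: snp_id mismatch "
                    f"({h1['snp_id']} vs {h2['snp_id']})"
                )
            left, right = h1["left"], h1["right"]
            k = h1["offset"] - left + 1
            plen = 2 * k - 1
            path_a = s1[left : left + plen]
            path_b = s2[left : left + plen]
            bub = Bubble(
                path_a=path_a,
                path_b=path_b,
                k=k,
                branching_class=h1["branching_class"],
                left_contig=s1[:left],
                right_contig=s1[left + plen :],
            )
            m = len(h1["depths"])
            depth = np.array([h1["depths"], h2["depths"]]).T
            mean_phred = np.array(
                [
                    [q if q is not None else 0.0 for q in h1["quals"]],
                    [q if q is not None else 0.0 for q in h2["quals"]],
                ]
            ).T
            has_q = [q is not None for q in h1["quals"]]
            profile = CoverageProfile(
                depth=depth,
                mean_phred=mean_phred,
                window_cov=np.zeros((m, 2, k), dtype=np.int64),
                k_coherent=[True] * m,
                has_quality=has_q,
            )
            out.append(SNPPrediction(bubble=bub, profile=profile, phi=h1["phi"]))
        else:
            if len(s1) % 2 == 0:
                raise ValueError(
                    f"{path}: records {i + 1}/{i + 2}: bare pair length must be "
                    f"odd (2k-1), got {len(s1)}"
                )
            k = (len(s1) + 1) // 2
            bub = Bubble(path_a=s1, path_b=s2, k=k)
            out.append(SNPPrediction(bubble=bub, profile=None))
    for rank, pred in enumerate(out, start=1):
        pred.rank = rank
    return out


def write_pair_file(pairs: Sequence[tuple[str, str]], out_path, label: str = "TRUTH"):
    """Write bare 2k-1 path pairs (the truth-file format)."""
    with open(out_path, "w") as fh:
        for i, (a, b) in enumerate(pairs, start=1):
            fh.write(f">{label}_{i}_a\n{a}\n>{label}_{i}_b\n{b}\n")
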