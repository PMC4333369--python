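"""Phi-coefficient scoring, ranking and filtering of SNP predictions.

Each prediction carries a 2 x m contingency table: rows are the two bubble
paths (alleles), columns the m input read sets, cells the number of reads
covering the polymorphic base on that path in that set.  The score is the
Phi coefficient sqrt(chi2 / N) of that table, where chi2 is the bare
Pearson statistic and N the table total.  With two rows the score lies in
[0, 1]: 1 for a perfectly discriminant SNP (each allele private to a
condition), 0 under independence.  Sequencing-error bubbles (one tiny count
everywhere) and repeat bubbles (balanced high counts everywhere) both score
near 0, which is what makes the ranking a false-positive filter; the N
normalisation keeps highly covered repeat bubbles from dominating.  The
score is uninformative for a single read set or for SNPs heterozygous in
every set - those call for the extension-length filter instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.stats import chi2_contingency

from .bubble_caller import canonical_pair

if TYPE_CHECKING:  # pragma: no cover
    from .bubble_caller import Bubble
    from .mapping import CoverageProfile, ReadSet

logger = logging.getLogger(__name__)


@dataclass
class SNPPrediction:
    """A bubble plus its per-dataset evidence, score and rank."""

    bubble: "Bubble"
    profile: "CoverageProfile"
    phi: float = 0.0
    rank: int = 0

    def key(self) -> tuple[str, str]:
        return self.bubble.key()


def phi_coefficient(counts) -> float:
    """Phi coefficient sqrt(chi2/N) of a 2 x m non-negative count table.

    Columns whose margin is zero are dropped first; the score is 0 when
    fewer than two non-empty columns remain or when one row margin is 0
    (the table then carries no association to measure).
    """
    table = np.asarray(counts, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x m table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        return 0.0
    n = table.sum()
    chi2 = chi2_contingency(table, correction=False).statistic
    return float(math.sqrt(chi2 / n))


def rank_predictions(predictions: Sequence[SNPPrediction]) -> list[SNPPrediction]:
    """Score every prediction and sort best-first.

    phi is computed from the per-dataset SNP-covering depths; the sort is
    stable, descending in phi with ties broken by the canonical bubble key,
    and 1-based ranks are assigned.  With a single read set every phi is 0
    (the coefficient needs at least two conditions to discriminate).
    """
    preds = list(predictions)
    single = any(p.profile.n_sets < 2 for p in preds)
    if single:
        logger.warning(
            "phi ranking is uninformative with a single read set; all scores are 0"
        )
    for p in preds:
        p.phi = phi_coefficient(p.profile.snp_depth_table())
    preds.sort(key=lambda p: (-p.phi, p.key()))
    for i, p in enumerate(preds, start=1):
        p.rank = i
    return preds


def filter_predictions(
    predictions: Sequence[SNPPrediction],
    phi_min: float | None = None,
    min_ext: int | None = None,
) -> list[SNPPrediction]:
    """Keep predictions with phi strictly above ``phi_min`` and with both
    unambiguous extensions at least ``min_ext`` long.

    Either criterion is disabled by passing None (or min_ext=0).
    """
    out = []
    for p in predictions:
        if phi_min is not None and not p.phi > phi_min:
            continue
        if min_ext is not None and (
            min(p.bubble.left_ext_len, p.bubble.right_ext_len) < min_ext
        ):
            continue
        out.append(p)
    return out


def _has_homopolymer(seq: str, window: int, count: int) -> bool:
    """True if some length-``window`` window holds >= ``count`` identical bases."""
    if len(seq) < window:
        return False
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if max(w.count(b) for b in set(w)) >= count:
            return True
    return False


def filter_markers(
    predictions: Sequence[SNPPrediction],
    depth_min: int,
    depth_max: int,
    homopolymer_window: int = 8,
    homopolymer_count: int = 6,
    phred_min: float = 30.0,
    read_sets: "Sequence[ReadSet] | None" = None,
    nearby_variant_mismatch: int = 3,
) -> list[SNPPrediction]:
    """Marker-grade selection of predictions for genotyping assays.

    Keeps predictions whose total SNP-covering depth lies in
    [depth_min, depth_max], whose paths contain no homopolymer-rich window
    (>= ``homopolymer_count`` identical bases within any
    ``homopolymer_window`` bases), and whose depth-weighted mean PHRED at
    the polymorphic base is >= ``phred_min``.  When ``read_sets`` is given,
    reads are additionally remapped to the bubble paths with a relaxed
    substitution budget and any bubble attracting a read that aligns with
    mismatches is dropped: residual differences near the SNP betray
    unmodelled neighbouring variation, which ruins primer design.
    """
    if depth_min > depth_max:
        raise ValueError(f"depth_min {depth_min} > depth_max {depth_max}")
    out = []
    for p in predictions:
        depth = p.profile.total_depth()
        if not (depth_min <= depth <= depth_max):
            continue
        if _has_homopolymer(
            p.bubble.path_a, homopolymer_window, homopolymer_count
        ) or _has_homopolymer(p.bubble.path_b, homopolymer_window, homopolymer_count):
            continue
        d = p.profile.depth
        mp = p.profile.mean_phred
        if d.sum() > 0 and any(p.profile.has_quality):
            mean_q = float((mp * d).sum() / d.sum())
        else:
            mean_q = 0.0
        if mean_q < phred_min:
            continue
        out.append(p)

    if read_sets is not None and out:
        from .mapping import PathIndex, map_read

        keep = []
        for p in out:
            index = PathIndex([p.bubble], p.bubble.k)
            dirty = False
            for rs in read_sets:
                for seq, _q in rs.reads:
                    for aln in map_read(seq, index, nearby_variant_mismatch):
                        if aln.mismatches >= 1:
                            dirty = True
                            break
                    if dirty:
                        break
                if dirty:
                    break
            if not dirty:
                keep.append(p)
        out = keep
    return out
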