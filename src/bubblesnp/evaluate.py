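"""Precision/recall of predicted bubbles against simulated truth pairs.

Matching is exact over the 2k-1 strings, normalised for strand and path
order (see :func:`bubblesnp.bubble_caller.canonical_pair`): a prediction
whose canonical pair equals a truth pair is a true positive; every truth
record is consumable once.  Unmatched predictions are false positives,
unmatched truth records false negatives.  When branching bubbles are
allowed (b_policy=1), predictions matching *any* simulated polymorphism -
isolated or not - are excluded from the false positives without being
counted as true positives, mirroring how sensitivity-mode calls that hit
real but non-isolated variation should not be punished.

A near-match diagnostic (Hamming distance <= 2 to some truth pair) is
reported for the false positives, for debugging only; it never changes the
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .bubble_caller import canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    verdicts: list[str]  # per prediction: TP / FP / duplicate / nonisolated
    precision_defined: bool = True
    recall_defined: bool = True
    near_misses: int = 0  # FPs within Hamming 2 of some truth pair


def _as_pairs(objs) -> list[tuple[str, str]]:
    pairs = []
    for o in objs:
        if isinstance(o, tuple):
            a, b = o
        else:  # SNPPrediction or Bubble
            bub = getattr(o, "bubble", o)
            a, b = bub.path_a, bub.path_b
        pairs.append(canonical_pair(a.upper(), b.upper()))
    return pairs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_predictions(
    predictions: Sequence,
    truth_isolated: Sequence,
    truth_all_polymorphisms: Sequence | None = None,
    b_policy: int = 0,
) -> EvaluationResult:
    """Score predictions against the isolated-SNP truth pairs.

    ``predictions`` and the truth sequences may be SNPPredictions, Bubbles
    or raw (path, path) tuples; everything is reduced to canonical 2k-1
    pairs.  ``truth_all_polymorphisms`` is only consulted under b_policy=1
    (see module docstring).
    """
    pred_pairs = _as_pairs(predictions)
    truth_pairs = _as_pairs(truth_isolated)
    if pred_pairs and truth_pairs:
        if len(pred_pairs[0][0]) != len(truth_pairs[0][0]):
            raise ValueError(
                f"prediction and truth path lengths differ "
                f"({len(pred_pairs[0][0])} vs {len(truth_pairs[0][0])}): k mismatch"
            )
    remaining = set(truth_pairs)
    matched_once = set()
    all_poly = (
        set(_as_pairs(truth_all_polymorphisms))
        if truth_all_polymorphisms is not None
        else set()
    )

    verdicts = []
    tp = fp = 0
    near = 0
    for pair in pred_pairs:
        if pair in remaining:
            remaining.discard(pair)
            matched_once.add(pair)
            tp += 1
            verdicts.append("TP")
        elif pair in matched_once:
            verdicts.append("duplicate")
        elif b_policy == 1 and pair in all_poly:
            verdicts.append("nonisolated")
        else:
            fp += 1
            verdicts.append("FP")
            if any(
                _hamming(pair[0], t[0]) + _hamming(pair[1], t[1]) <= 2
                or _hamming(pair[0], t[1]) + _hamming(pair[1], t[0]) <= 2
                for t in truth_pairs[:2000]
            ):
                near += 1
    fn = len(remaining)

    prec_def = (tp + fp) > 0
    rec_def = (tp + fn) > 0
    precision = tp / (tp + fp) if prec_def else 0.0
    recall = tp / (tp + fn) if rec_def else 0.0
    logger.info(
        "evaluation: TP=%d FP=%d FN=%d precision=%.4f recall=%.4f",
        tp,
        fp,
        fn,
        precision,
        recall,
    )
    return EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        verdicts=verdicts,
        precision_defined=prec_def,
        recall_defined=rec_def,
        near_misses=near,
    )
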