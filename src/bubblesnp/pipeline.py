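"""End-to-end orchestration: count -> graph -> bubbles -> remap -> rank -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from . import bubble_caller, kmer_graph, mapping, ranking

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    The defaults are the caller's standard operating point: k=31, minimal
    coverage c=4, no branching bubbles (b_policy=0), one substitution
    allowed during remapping.
    """

    read_files: list[list[str]] = field(default_factory=list)  # one list per set
    k: int = 31
    c: int = 4
    b_policy: int = 0
    max_mismatch: int = 1
    solidity: str = "per-set"  # or "pooled"
    phi_min: float | None = None
    min_ext: int | None = None
    max_context: int | None = None  # default 10*k
    output_prefix: str = "bubblesnp"
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunReport:
    """Stage-by-stage bookkeeping of one run."""

    params: dict
    n_reads: list[int] = field(default_factory=list)
    n_solid_kmers: int = 0
    n_bubbles_enumerated: int = 0
    n_bubbles_kept_policy: int = 0
    n_coherent: int = 0
    n_after_filters: int = 0

    def as_text(self) -> str:
        lines = ["run report"]
        for key, val in self.params.items():
            lines.append(f"  param {key} = {val}")
        lines += [
            f"  reads per set: {self.n_reads}",
            f"  solid k-mers: {self.n_solid_kmers}",
            f"  bubbles (all classes): {self.n_bubbles_enumerated}",
            f"  bubbles kept by branching policy: {self.n_bubbles_kept_policy}",
            f"  predictions k-read-coherent: {self.n_coherent}",
            f"  predictions after filters: {self.n_after_filters}",
        ]
        return "\n".join(lines)


def run_pipeline(
    read_sets: Sequence[mapping.ReadSet],
    k: int = 31,
    c: int = 4,
    b_policy: int = 0,
    max_mismatch: int = 1,
    solidity: str = "per-set",
    phi_min: float | None = None,
    min_ext: int | None = None,
    max_context: int | None = None,
) -> tuple[list[ranking.SNPPrediction], RunReport]:
    """Run the full caller on in-memory read sets; returns ranked predictions."""
    report = RunReport(
        params={
            "k": k,
            "c": c,
            "b_policy": b_policy,
            "max_mismatch": max_mismatch,
            "solidity": solidity,
            "phi_min": phi_min,
            "min_ext": min_ext,
        },
        n_reads=[len(rs) for rs in read_sets],
    )
    if solidity == "per-set":
        tables = kmer_graph.count_kmers(read_sets, k, per_set=True)
        graph = kmer_graph.build_graph(tables, c)
    elif solidity == "pooled":
        table = kmer_graph.count_kmers(read_sets, k)
        graph = kmer_graph.build_graph(table, c)
    else:
        raise ValueError(f"unknown solidity mode {solidity!r}")
    report.n_solid_kmers = len(graph)

    all_bubbles = bubble_caller.enumerate_bubbles(graph, b_policy=2)
    report.n_bubbles_enumerated = len(all_bubbles)
    keep = bubble_caller._POLICY_KEEP[b_policy]
    bubbles = [b for b in all_bubbles if b.branching_class in keep]
    report.n_bubbles_kept_policy = len(bubbles)
    for bub in bubbles:
        bubble_caller.extend_context(graph, bub, max_context)

    predictions = mapping.profile_predictions(
        bubbles, read_sets, c, max_mismatch=max_mismatch
    )
    report.n_coherent = len(predictions)
    predictions = ranking.rank_predictions(predictions)
    if phi_min is not None or min_ext is not None:
        predictions = ranking.filter_predictions(predictions, phi_min, min_ext)
        for i, p in enumerate(predictions, start=1):
            p.rank = i
    report.n_after_filters = len(predictions)
    return predictions, report


def run(config: RunConfig) -> tuple[str, RunReport]:
    """File-to-file run: read the configured inputs, write predictions.

    Returns (path of the prediction multi-FASTA, report).  Zero predictions
    is a success and produces an empty output file.
    """
    from . import io_formats

    flat_sets = []
    for set_files in config.read_files:
        parts = io_formats.read_read_sets(set_files)
        merged = mapping.ReadSet(
            set_id=len(flat_sets),
            reads=[r for p in parts for r in p.reads],
            name=";".join(str(f) for f in set_files),
        )
        flat_sets.append(merged)

    predictions, report = run_pipeline(
        flat_sets,
        k=config.k,
        c=config.c,
        b_policy=config.b_policy,
        max_mismatch=config.max_mismatch,
        solidity=config.solidity,
        phi_min=config.phi_min,
        min_ext=config.min_ext,
        max_context=config.max_context,
    )
    out_path = f"{config.output_prefix}_snps.fa"
    io_formats.write_predictions(predictions, out_path)
    report.params["seed"] = config.seed
    logger.info("wrote %d predictions to %s", len(predictions), out_path)
    return out_path, report
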