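"""End-to-end refinement pipeline used by the CLI and the test harness."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from binrefine.assign import ScaffoldAssignment, assign_scaffolds
from binrefine.edge_binning import EdgeBinning, mark_repetitive, scaffold_to_edge_binning
from binrefine.graph_io import AssemblyGraph, BinningTable
from binrefine.link_graph import KmerIndex, build_link_graph, index_unique_kmers
from binrefine.refine import RefineConfig, RefineReport, refine, regularization_parameters
from binrefine.sparse_mode import sparse_refine_pipeline


@dataclass
class RefineResult:
    refined: EdgeBinning
    assignments: list[ScaffoldAssignment]
    report: RefineReport
    n_read_pairs: int
    alpha: np.ndarray


def refine_binning(
    graph: AssemblyGraph,
    binning: BinningTable,
    config: RefineConfig | None = None,
    libraries: Iterable[tuple[str, str]] = (),
    kmer_index: KmerIndex | None = None,
) -> RefineResult:
    """Run the full pipeline on in-memory inputs.

    Graph + binning → edge binning Y → link graph H (optionally with read
    links) → standard or sparse refinement → scaffold assignment.
    """
    config = config or RefineConfig()
    Y = scaffold_to_edge_binning(graph, binning)
    repetitive = mark_repetitive(graph)
    alpha = regularization_parameters(graph, Y, repetitive, config)
    libraries = list(libraries)
    if libraries and kmer_index is None:
        kmer_index = index_unique_kmers(graph, config.kmer_size)
    H, n_pairs = build_link_graph(graph, libraries, k=config.kmer_size, index=kmer_index)
    if config.sparse:
        refined, report, _ = sparse_refine_pipeline(H, graph, Y, alpha, config)
    else:
        refined, report = refine(H, Y, alpha, config)
    assignments = assign_scaffolds(
        graph, refined, strategy=config.strategy, coverage=config.multiple_coverage
    )
    return RefineResult(refined, assignments, report, n_pairs, alpha)


def assignments_as_sets(
    assignments: Sequence[ScaffoldAssignment], multiple: bool = False
) -> dict[str, set[str]]:
    """Assignment list → {scaffold: labels} (singletons in single mode)."""
    out: dict[str, set[str]] = {}
    for a in assignments:
        if multiple:
            out[a.scaffold] = set(a.labels)
        else:
            out[a.scaffold] = {a.best_label} if a.best_label is not None else set()
    return out
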