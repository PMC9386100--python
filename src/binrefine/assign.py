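"""From refined edge binning back to scaffold assignments.

Each scaffold is scored against every bin from the refined rows of its path
members. Two strategies: *majority length* (each edge votes its full length
for its argmax bin) and *maximum likelihood* (each edge contributes
length × weight to every bin; the default). Output is either a single argmax
label per scaffold or the minimal set of top bins cumulatively explaining at
least 95% of the total score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from binrefine.edge_binning import EdgeBinning
from binrefine.graph_io import AssemblyGraph

MAJORITY_LENGTH = "majority-length"
MAX_LIKELIHOOD = "max-likelihood"


@dataclass
class ScaffoldAssignment:
    """Raw per-bin scores and the chosen label(s) for one scaffold."""

    scaffold: str
    scores: dict[str, float]
    best_label: str | None
    labels: set[str] = field(default_factory=set)


def score_scaffold(
    graph: AssemblyGraph,
    refined: EdgeBinning,
    scaffold: str,
    strategy: str = MAX_LIKELIHOOD,
) -> dict[str, float]:
    """Per-bin raw scores for one scaffold (bp-weighted).

    Rows of the refined matrix are L1-normalized here so weights read as
    containment probabilities. Edges occurring several times in the path
    vote once per occurrence. Edges flagged unbinned (sparse mode) or with
    all-zero rows contribute nothing; a scaffold of only such edges gets an
    empty score map.
    """
    if strategy not in (MAJORITY_LENGTH, MAX_LIKELIHOOD):
        raise ValueError(f"unknown strategy {strategy!r}")
    path = graph.scaffold(scaffold).path
    norm = refined.normalized()
    bins = refined.bins
    scores = np.zeros(len(bins))
    for seg, _ in path:
        i = refined.index(seg)
        if refined.unbinned_mask[i]:
            continue
        row = norm[i]
        if not row.any():
            continue
        length = graph.segments[seg].length
        if strategy == MAX_LIKELIHOOD:
            scores += length * row
        else:
            scores[int(np.argmax(row))] += length  # argmax ties: lowest index = smallest label
    return {b: float(s) for b, s in zip(bins, scores) if s > 0}


def assign_single(scores: dict[str, float]) -> str | None:
    """Argmax bin; ties broken by lexicographically smallest label; None if
    the scaffold has no scores (unbinned)."""
    if not scores:
        return None
    return min(scores, key=lambda b: (-scores[b], b))


def assign_multiple(scores: dict[str, float], coverage: float = 0.95) -> set[str]:
    """Shortest descending-score prefix reaching ≥ coverage of the total.

    Ties at the cut go to the lexicographically smaller label.
    """
    if not scores:
        return set()
    total = sum(scores.values())
    chosen: set[str] = set()
    acc = 0.0
    for label in sorted(scores, key=lambda b: (-scores[b], b)):
        chosen.add(label)
        acc += scores[label]
        if acc >= coverage * total:
            break
    return chosen


def assign_scaffolds(
    graph: AssemblyGraph,
    refined: EdgeBinning,
    strategy: str = MAX_LIKELIHOOD,
    coverage: float = 0.95,
) -> list[ScaffoldAssignment]:
    """Score and assign every scaffold in the graph."""
    out = []
    for scaf in graph.paths:
        scores = score_scaffold(graph, refined, scaf.name, strategy)
        out.append(
            ScaffoldAssignment(
                scaffold=scaf.name,
                scores=scores,
                best_label=assign_single(scores),
                labels=assign_multiple(scores, coverage),
            )
        )
    return out
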