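"""From scaffold binning to soft edge binning.

A scaffold binning labels whole scaffolds, but a long metagenomic scaffold may
traverse repetitive unitigs shared between species. The edge-binning matrix Y
moves the labels down to assembly-graph edges: the row of edge e is the
uniform distribution over the bin labels of all scaffolds containing e, so an
edge shared by scaffolds binned to A and B starts at (A: 1/2, B: 1/2).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from binrefine.graph_io import AssemblyGraph, BinningTable

UNBINNED_LABEL = "__unbinned__"


@dataclass
class EdgeBinning:
    """Soft binning matrix over assembly-graph edges (rows) and bins (columns).

    Rows follow ``segment_ids`` (sorted segment names), columns follow
    ``bins`` (sorted bin labels). ``binned`` flags rows with an initial
    label; ``repetitive`` flags edges occurring more than once across
    scaffold paths. ``unbinned_mask`` is set by sparse-mode refinement for
    edges whose dominant refined weight was the unbinned pseudo-bin.
    """

    segment_ids: list[str]
    bins: list[str]
    matrix: np.ndarray
    binned: np.ndarray
    repetitive: np.ndarray
    unbinned_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n, m = len(self.segment_ids), len(self.bins)
        if self.matrix.shape != (n, m):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {m})")
        if np.any(self.matrix < 0):
            raise ValueError("edge-binning weights must be nonnegative")
        if self.unbinned_mask is None:
            self.unbinned_mask = ~self.matrix.any(axis=1)
        self._index = {s: i for i, s in enumerate(self.segment_ids)}

    def index(self, segment: str) -> int:
        return self._index[segment]

    def row(self, segment: str) -> np.ndarray:
        return self.matrix[self._index[segment]]

    def normalized(self) -> np.ndarray:
        """Row-normalized copy of the matrix (zero rows stay zero)."""
        sums = self.matrix.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.matrix / np.where(sums > 0, sums, 1.0), 0.0)
        return out

    def with_matrix(self, matrix: np.ndarray, unbinned_mask: np.ndarray | None = None) -> "EdgeBinning":
        return EdgeBinning(
            segment_ids=self.segment_ids,
            bins=self.bins,
            matrix=matrix,
            binned=self.binned,
            repetitive=self.repetitive,
            unbinned_mask=unbinned_mask,
        )


def mark_repetitive(graph: AssemblyGraph) -> set[str]:
    """Segments occurring ≥2 times across all scaffold paths.

    Occurrences are counted, not distinct scaffolds: an edge traversed twice
    within one scaffold is just as unreliable as one shared by two scaffolds.
    """
    counts: Counter[str] = Counter()
    for scaf in graph.paths:
        counts.update(seg for seg, _ in scaf.path)
    return {seg for seg, n in counts.items() if n >= 2}


def scaffold_to_edge_binning(graph: AssemblyGraph, binning: BinningTable) -> EdgeBinning:
    """Build the initial edge-binning matrix Y from a scaffold binning.

    For each edge e, C(e) is the set (not multiset) of bin labels over all
    scaffolds containing e; the row of e is 1/|C(e)| on C(e) and zero
    elsewhere. Edges on no binned scaffold get a zero row.
    """
    if not binning.assignments:
        raise ValueError("empty binning: nothing to refine")
    segment_ids = sorted(graph.segments)
    bins = list(binning.bins)
    bin_index = {b: j for j, b in enumerate(bins)}
    seg_index = {s: i for i, s in enumerate(segment_ids)}

    labels_per_edge: dict[int, set[str]] = {}
    for scaf in graph.paths:
        labels = binning.assignments.get(scaf.name)
        if not labels:
            continue
        for seg, _ in scaf.path:
            labels_per_edge.setdefault(seg_index[seg], set()).update(labels)

    Y = np.zeros((len(segment_ids), len(bins)))
    binned = np.zeros(len(segment_ids), dtype=bool)
    for i, labels in labels_per_edge.items():
        binned[i] = True
        w = 1.0 / len(labels)
        for b in labels:
            Y[i, bin_index[b]] = w

    repetitive_set = mark_repetitive(graph)
    repetitive = np.array([s in repetitive_set for s in segment_ids])
    return EdgeBinning(segment_ids, bins, Y, binned, repetitive)
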