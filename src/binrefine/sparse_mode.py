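"""Sparse-binning refinement: distance-damped propagation.

When only a small fraction of the assembly is initially binned, standard
correction-mode refinement would eventually label every edge in a connected
component, inflating and contaminating the few initial bins. Sparse mode
damps each edge's refinability with a distance coefficient β_i ∈ [0, 1] that
decays from 1 on initially labeled edges to 0 on edges farther than a
distance threshold D (default 10 kb of intervening sequence) from any label,
and adds a guarded "unbinned" pseudo-bin that can be held but never
propagated.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass
from math import inf

import networkx as nx
import numpy as np

from binrefine.edge_binning import EdgeBinning
from binrefine.graph_io import AssemblyGraph
from binrefine.refine import (
    CORRECTION,
    RefineConfig,
    RefineReport,
    correction_alpha,
    propagation_operator,
    refine_iterate,
)


@dataclass
class DistanceCoefficients:
    """Per-segment distance to the nearest initially labeled edge (bp of
    intervening sequence) and the damping coefficient β derived from it."""

    segment_ids: list[str]
    dist: np.ndarray  # bp; 0 on labeled, inf when unreachable
    beta: np.ndarray  # in [0, 1]; 1 on labeled, 0 on distant


def graph_distances(
    H: nx.Graph, graph: AssemblyGraph, labeled: set[str]
) -> dict[str, float]:
    """Multi-source shortest-path distance to the nearest labeled edge.

    The cost of a path is the total length of the *intermediate* segments on
    it — the sequence separating the two edges — so an edge directly linked
    to a labeled edge is at distance 0. Unreachable edges get inf.
    """
    if not labeled:
        raise ValueError("no labeled edges")
    dist = {node: inf for node in H.nodes}
    heap: list[tuple[float, str]] = []
    for seg in labeled:
        if seg in dist:
            dist[seg] = 0.0
            heapq.heappush(heap, (0.0, seg))
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        # stepping over u to a neighbor costs length(u), except from a source
        step = 0.0 if u in labeled else float(graph.segments[u].length)
        for v in H.neighbors(u):
            nd = d + step
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def distance_coefficients(
    H: nx.Graph,
    graph: AssemblyGraph,
    labeled: set[str],
    distant: set[str],
    config: RefineConfig,
) -> DistanceCoefficients:
    """β via an auxiliary two-bin propagation.

    Bin 1 marks initially labeled edges, bin 2 marks distant ones; a standard
    correction-mode refinement run over this two-bin problem makes the
    "labeled" weight decay smoothly along the graph. β_i is the labeled
    bin's share of the converged row, pinned to its defining values on the
    endpoint sets (1 on labeled, 0 on distant).
    """
    if labeled & distant:
        raise ValueError("labeled and distant sets overlap")
    segment_ids = sorted(graph.segments)
    idx = {s: i for i, s in enumerate(segment_ids)}
    n = len(segment_ids)
    Y2 = np.zeros((n, 2))
    for s in labeled:
        Y2[idx[s], 0] = 1.0
    for s in distant:
        Y2[idx[s], 1] = 1.0

    aux_config = RefineConfig(
        mode=CORRECTION,
        alpha_default=config.alpha_default,
        length_threshold=config.length_threshold,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
    )
    alpha = np.ones(n)
    for s in labeled | distant:
        alpha[idx[s]] = correction_alpha(graph.segments[s].length, aux_config)

    S = propagation_operator(H, segment_ids)
    F, _ = refine_iterate(S, Y2, alpha, aux_config)

    totals = F.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(totals > 0, F[:, 0] / np.where(totals > 0, totals, 1.0), 0.0)
    beta = np.clip(beta, 0.0, 1.0)
    for s in labeled:
        beta[idx[s]] = 1.0
    for s in distant:
        beta[idx[s]] = 0.0

    dist_map = graph_distances(H, graph, labeled)
    dist = np.array([dist_map[s] for s in segment_ids])
    return DistanceCoefficients(segment_ids, dist, beta)


def sparse_refine(
    H: nx.Graph,
    Y: EdgeBinning,
    alpha: np.ndarray,
    coeffs: DistanceCoefficients,
    config: RefineConfig,
) -> tuple[EdgeBinning, RefineReport]:
    """Run refinement with α′ = α·β and the guarded unbinned pseudo-bin.

    The binning matrix is augmented with a pseudo-bin column set to 1 for
    initially unbinned edges. Each iteration aggregates neighbors with that
    column zeroed, so the pseudo-label is held by (1−α′)·Y but never spreads.
    The returned matrix drops the pseudo-bin; edges left with no real-bin
    weight — distant edges (α′=0 pins them to the pseudo-label) and edges in
    unreachable components — are flagged unbinned. Edges within the distance
    threshold keep their propagated labels: the held pseudo weight measures
    remaining uncertainty but does not veto a real label, since real weights
    attenuate through the graph while the pseudo hold does not.
    """
    if coeffs.segment_ids != Y.segment_ids:
        raise ValueError("distance coefficients indexed differently from Y")
    alpha_prime = np.asarray(alpha, dtype=float) * coeffs.beta

    n, m = Y.matrix.shape
    Y_aug = np.zeros((n, m + 1))
    Y_aug[:, :m] = Y.matrix
    initially_unbinned = ~Y.binned
    Y_aug[initially_unbinned, m] = 1.0

    S = propagation_operator(H, Y.segment_ids)
    F_aug, report = refine_iterate(S, Y_aug, alpha_prime, config, frozen_column=m)

    real = F_aug[:, :m]
    F = real.copy()
    unbinned_mask = real.max(axis=1) <= 1e-12
    F[unbinned_mask] = 0.0
    return Y.with_matrix(F, unbinned_mask=unbinned_mask), report


def sparse_refine_pipeline(
    H: nx.Graph,
    graph: AssemblyGraph,
    Y: EdgeBinning,
    alpha: np.ndarray,
    config: RefineConfig,
) -> tuple[EdgeBinning, RefineReport, DistanceCoefficients]:
    """Distances → β → damped propagation, as run by the CLI."""
    labeled = {s for i, s in enumerate(Y.segment_ids) if Y.binned[i]}
    dist_map = graph_distances(H, graph, labeled)
    distant = {s for s, d in dist_map.items() if d > config.distance_threshold}
    coeffs = distance_coefficients(H, graph, labeled, distant, config)
    refined, report = sparse_refine(H, Y, alpha, coeffs, config)
    return refined, report, coeffs
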