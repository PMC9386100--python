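"""The weighted link graph H over assembly-graph edges.

Nodes of H are the assembly graph's edges (unitigs); a link weight L_ij
measures the evidence that e_i and e_j belong to the same genome. Three
sources contribute: graph adjacency (weight 1), scaffold joins bridging
non-adjacent consecutive path members (weight 1), and read pairs
(paired-end or Hi-C) co-mapped to two segments via unique k-mers, adding
ln(1 + N_ij) for N_ij aligned pairs.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pysam

from binrefine.graph_io import AssemblyGraph

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_adjacency_links(graph: AssemblyGraph) -> nx.Graph:
    """H from assembly-graph adjacency: weight 1 per distinct adjacent pair.

    Every segment is a node (isolated segments keep degree 0); parallel
    oriented links and self-adjacencies collapse — L_ij is 0/1 here.
    """
    H = nx.Graph()
    H.add_nodes_from(graph.segments)
    for pair in graph.undirected_links():
        a, b = sorted(pair)
        H.add_edge(a, b, weight=1.0)
    return H


def add_scaffold_links(H: nx.Graph, graph: AssemblyGraph) -> nx.Graph:
    """Add weight-1 links for consecutive scaffold-path pairs not adjacent in G.

    Assemblers join such pairs to jump over coverage gaps or unresolved
    repeats; bridging them keeps the link graph contiguous. Idempotent:
    existing links keep weight 1.
    """
    for scaf in graph.paths:
        segs = scaf.segments
        for a, b in zip(segs, segs[1:]):
            if a != b and not H.has_edge(a, b):
                H.add_edge(a, b, weight=1.0)
    return H


@dataclass
class KmerIndex:
    """Map from canonical k-mers occurring exactly once in the whole graph to
    their segment. k must be odd so a k-mer is never its own reverse
    complement."""

    k: int
    unique: dict[str, str]

    def __len__(self) -> int:
        return len(self.unique)


def index_unique_kmers(graph: AssemblyGraph, k: int = 31) -> KmerIndex:
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    if not graph.has_sequences():
        raise ValueError(
            "assembly graph carries no sequences (length-only GFA); "
            "read linking requires a GFA with segment sequences"
        )
    counts: Counter[str] = Counter()
    owner: dict[str, str] = {}
    for name in sorted(graph.segments):
        seq = graph.segments[name].sequence or ""
        for i in range(len(seq) - k + 1):
            km = canonical_kmer(seq[i : i + k])
            counts[km] += 1
            owner[km] = name
    unique = {km: owner[km] for km, n in counts.items() if n == 1}
    return KmerIndex(k=k, unique=unique)


def _indexed_positions(index: KmerIndex, read: str) -> list[tuple[int, str]]:
    k = index.k
    hits = []
    for i in range(len(read) - k + 1):
        seg = index.unique.get(canonical_kmer(read[i : i + k]))
        if seg is not None:
            hits.append((i, seg))
    return hits


def _count_nonoverlapping(positions: list[int], k: int) -> int:
    # greedy left-to-right: deterministic and optimal for intervals of equal length
    n = 0
    next_free = -1
    for pos in positions:
        if pos >= next_free:
            n += 1
            next_free = pos + k
    return n


def align_read_pair(index: KmerIndex, read1: str, read2: str) -> set[str]:
    """Map a read pair to segments via unique k-mers.

    The pair is used only if it contains at least two non-overlapping indexed
    k-mers in total. Each read maps to the segment with the plurality of its
    indexed k-mer hits; ties leave the read unassigned. Returns the set of
    mapped segments (0, 1 or 2 elements).
    """
    hits1 = _indexed_positions(index, read1.upper())
    hits2 = _indexed_positions(index, read2.upper())
    total_nonoverlap = _count_nonoverlapping([p for p, _ in hits1], index.k) + _count_nonoverlapping(
        [p for p, _ in hits2], index.k
    )
    if total_nonoverlap < 2:
        return set()
    mapped: set[str] = set()
    for hits in (hits1, hits2):
        if not hits:
            continue
        tally = Counter(seg for _, seg in hits)
        ranked = tally.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # ambiguous read
        mapped.add(ranked[0][0])
    return mapped


def iter_read_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq1, seq2) from a pair of (optionally gzipped) FASTQs."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2):
            yield r1.name, r1.sequence or "", r2.sequence or ""


def count_pair_links(
    index: KmerIndex, pairs: Iterable[tuple[str, str, str]]
) -> Counter[frozenset[str]]:
    """Count aligned read pairs per unordered segment pair.

    Pairs mapping both reads to the same segment carry no between-edge
    information and are dropped.
    """
    counts: Counter[frozenset[str]] = Counter()
    for _, seq1, seq2 in pairs:
        mapped = align_read_pair(index, seq1, seq2)
        if len(mapped) == 2:
            counts[frozenset(mapped)] += 1
    return counts


def add_read_links(H: nx.Graph, pair_counts: Mapping[frozenset[str], int]) -> nx.Graph:
    """Increase link weights by ln(1 + N_ij) for N_ij co-mapped read pairs.

    Counts from all libraries should be summed before calling (the log is
    taken once on the total). Creates the link if absent.
    """
    for pair, n in pair_counts.items():
        if n <= 0:
            continue
        segs = sorted(pair)
        if len(segs) != 2:
            continue
        a, b = segs
        w = H[a][b]["weight"] if H.has_edge(a, b) else 0.0
        H.add_edge(a, b, weight=w + math.log1p(n))
    return H


def build_link_graph(
    graph: AssemblyGraph,
    libraries: Iterable[tuple[str | Path, str | Path]] = (),
    k: int = 31,
    index: KmerIndex | None = None,
) -> tuple[nx.Graph, int]:
    """Full link-graph construction: adjacency + scaffold joins + read links.

    Returns (H, number of aligned cross-segment read pairs).
    """
    H = build_adjacency_links(graph)
    add_scaffold_links(H, graph)
    libraries = list(libraries)
    n_pairs = 0
    if libraries:
        if index is None:
            index = index_unique_kmers(graph, k)
        total: Counter[frozenset[str]] = Counter()
        for path1, path2 in libraries:
            total.update(count_pair_links(index, iter_read_pairs(path1, path2)))
        n_pairs = sum(total.values())
        add_read_links(H, total)
    return H, n_pairs
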