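"""Synthetic mock communities with known genome membership.

The generator emulates the structure the refiner actually consumes: several
genomes, each a chain of unitig-like segments, with a fraction of segments
shared between two genomes (interspecies repeats that create branching and
multi-genome edges), scaffolds broken at those repeats, a partial initial
binning (some scaffolds deliberately unlabeled, repeat-only scaffolds never
labeled), and optionally simulated linking read pairs with recorded
provenance. Sequences are i.i.d. uniform nucleotides — the method uses no
composition signal, so none is simulated.

``evaluate_binning`` scores a scaffold assignment against the ground truth
at the nucleotide level (per-base purity / completeness / F1 with a greedy
majority bin→genome mapping), in the style of AMBER.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from binrefine.graph_io import AssemblyGraph, BinningTable, Scaffold, Segment, canonical_link

PE_MODE = "pe"
HIC_MODE = "hic"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults describe the standard test scenario: 5 genomes of 40 segments
    each (3–10 kb), 5% of segments shared between genome pairs, and half of
    the unique scaffolds left out of the initial binning — a mid-quality
    binner's output on a small mock community.
    """

    n_genomes: int = 5
    segments_per_genome: tuple[int, int] = (40, 40)
    segment_length: tuple[int, int] = (3000, 10000)
    shared_fraction: float = 0.05
    gap_break_probability: float = 0.5
    unlabeled_fraction: float = 0.5
    min_label_length: int = 0
    n_read_pairs: int = 0
    read_length: int = 100
    read_mode: str = PE_MODE
    with_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("shared_fraction", "unlabeled_fraction", "gap_break_probability"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if self.shared_fraction > 0 and self.n_genomes < 2:
            raise ValueError("shared segments need at least two genomes")


@dataclass
class TruthBinning:
    """Ground truth: genome membership per segment (repeats carry several)
    and the source genome of each scaffold."""

    segment_truth: dict[str, set[str]]
    scaffold_truth: dict[str, str]
    shared_segments: set[str] = field(default_factory=set)
    genome_paths: dict[str, list[str]] = field(default_factory=dict)

    def genome_length(self, graph: AssemblyGraph, genome: str) -> int:
        return sum(
            graph.segments[s].length
            for s, genomes in self.segment_truth.items()
            if genome in genomes
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _contig_chunks(n: int, is_shared: list[bool], gap_after: list[bool]) -> list[list[int]]:
    """Split a circular genome path into contigs: maximal runs of unique
    segments, delimited by shared (repeat) segments and by gap breaks."""
    if not any(is_shared) and not any(gap_after):
        return [list(range(n))]
    start = next(i for i in range(n) if is_shared[(i - 1) % n] or gap_after[(i - 1) % n])
    chunks: list[list[int]] = []
    cur: list[int] = []
    j = start
    for _ in range(n):
        if is_shared[j]:
            if cur:
                chunks.append(cur)
                cur = []
        else:
            cur.append(j)
            if gap_after[j]:
                chunks.append(cur)
                cur = []
        j = (j + 1) % n
    if cur:
        chunks.append(cur)
    return chunks


def generate_community(spec: CommunitySpec) -> tuple[AssemblyGraph, TruthBinning]:
    """Build a multi-genome assembly graph with known membership.

    Each genome is a circular path of segments (bacterial chromosomes);
    shared repeat segments are spliced into the paths of two distinct
    genomes, welding the cycles together at branching nodes. Graph links
    follow path adjacency. Scaffolds model assembler contigs: maximal runs
    of unique segments, broken at every shared repeat (the repeat unitig is
    its own entity, part of no contig) and additionally at a fraction of
    unique junctions (contig ends at coverage dips and local tangles where
    the graph connection survives). Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo_s, hi_s = spec.segments_per_genome
    lo_l, hi_l = spec.segment_length
    genomes = [f"genome{g + 1}" for g in range(spec.n_genomes)]

    segments: dict[str, Segment] = {}
    segment_truth: dict[str, set[str]] = {}

    def new_segment(name: str) -> str:
        length = int(rng.integers(lo_l, hi_l + 1))
        seq = _random_seq(rng, length) if spec.with_sequences else None
        segments[name] = Segment(name, length, seq)
        segment_truth[name] = set()
        return name

    paths: dict[str, list[str]] = {}
    for g in genomes:
        n_seg = int(rng.integers(lo_s, hi_s + 1))
        path = [new_segment(f"{g}_u{i + 1}") for i in range(n_seg)]
        for s in path:
            segment_truth[s].add(g)
        paths[g] = path

    total_unique = sum(len(p) for p in paths.values())
    n_shared = int(round(spec.shared_fraction * total_unique))
    if n_shared > 0 and spec.n_genomes < 2:
        raise ValueError("cannot share segments with a single genome")
    shared: set[str] = set()
    for r in range(n_shared):
        name = new_segment(f"rep{r + 1}")
        shared.add(name)
        ga, gb = rng.choice(len(genomes), size=2, replace=False)
        for g in (genomes[ga], genomes[gb]):
            pos = int(rng.integers(1, len(paths[g])))  # interior insert
            paths[g].insert(pos, name)
            segment_truth[name].add(g)

    links = set()
    for g in genomes:
        p = paths[g]
        for a, b in zip(p, p[1:] + p[:1]):  # circular closure
            links.add(canonical_link((a, "+"), (b, "+")))

    scaffolds: list[Scaffold] = []
    scaffold_truth: dict[str, str] = {}
    for g in genomes:
        p = paths[g]
        n = len(p)
        is_shared = [s in shared for s in p]
        gap_after = [
            not is_shared[i]
            and not is_shared[(i + 1) % n]
            and bool(rng.random() < spec.gap_break_probability)
            for i in range(n)
        ]
        for i, chunk in enumerate(_contig_chunks(n, is_shared, gap_after)):
            name = f"{g}_scaffold{i + 1}"
            scaffolds.append(Scaffold(name, tuple((p[x], "+") for x in chunk)))
            scaffold_truth[name] = g

    graph = AssemblyGraph(segments=segments, links=links, paths=scaffolds)
    truth = TruthBinning(segment_truth, scaffold_truth, shared, dict(paths))
    return graph, truth


def mask_binning(
    truth: TruthBinning, spec: CommunitySpec, graph: AssemblyGraph
) -> BinningTable:
    """Partial initial binning, as a real binner would produce.

    Scaffolds consisting entirely of shared segments are never labeled;
    scaffolds shorter than ``min_label_length`` are never labeled. Of the
    remaining eligible scaffolds, a per-genome round(unlabeled_fraction · n)
    are dropped, drawn without replacement with probability proportional to
    inverse length — composition and coverage profiles stabilize with
    length, so binners miss short contigs preferentially. Labels are the
    true genomes.
    """
    rng = np.random.default_rng([spec.seed, 1])
    by_genome: dict[str, list[tuple[str, int]]] = {}
    for scaf in graph.paths:
        segs = scaf.segments
        if all(s in truth.shared_segments for s in segs):
            continue
        length = sum(graph.segments[s].length for s in segs)
        if length < spec.min_label_length:
            continue
        by_genome.setdefault(truth.scaffold_truth[scaf.name], []).append((scaf.name, length))

    assignments: dict[str, set[str]] = {}
    for genome in sorted(by_genome):
        items = sorted(by_genome[genome])
        n_drop = int(round(spec.unlabeled_fraction * len(items)))
        weights = np.array([1.0 / length for _, length in items])
        weights /= weights.sum()
        drop_idx = rng.choice(len(items), size=n_drop, replace=False, p=weights)
        drop = {items[i][0] for i in drop_idx}
        for name, _ in items:
            if name not in drop:
                assignments[name] = {genome}
    return BinningTable(assignments=assignments)


def simulate_read_pairs(
    graph: AssemblyGraph,
    truth: TruthBinning,
    spec: CommunitySpec,
    out1: str | Path | None = None,
    out2: str | Path | None = None,
) -> list[tuple[str, str, str, tuple[str, str, str]]]:
    """Simulate within-genome linking read pairs.

    PE mode draws both mates from the same or adjacent segments of a genome
    path; Hi-C mode draws the two segments uniformly from the genome
    (long-range contacts). Mate 2 is reverse-complemented. Returns
    (name, seq1, seq2, (genome, segment1, segment2)) tuples with provenance
    also recorded in the read name; optionally writes a FASTQ pair.
    """
    if not graph.has_sequences():
        raise ValueError("read simulation needs segment sequences")
    if spec.read_mode not in (PE_MODE, HIC_MODE):
        raise ValueError(f"unknown read mode {spec.read_mode!r}")
    rng = np.random.default_rng([spec.seed, 2])
    genome_paths = truth.genome_paths
    if not genome_paths:
        genome_paths = {
            g: sorted(s for s, gs in truth.segment_truth.items() if g in gs)
            for g in set(truth.scaffold_truth.values())
        }
    genomes = sorted(genome_paths)

    L = spec.read_length
    pairs = []
    from binrefine.link_graph import revcomp

    for i in range(spec.n_read_pairs):
        g = genomes[int(rng.integers(0, len(genomes)))]
        segs = genome_paths[g]
        if spec.read_mode == HIC_MODE:
            s1 = segs[int(rng.integers(0, len(segs)))]
            s2 = segs[int(rng.integers(0, len(segs)))]
        else:
            j = int(rng.integers(0, len(segs)))
            s1 = segs[j]
            s2 = segs[(j + int(rng.integers(0, 2))) % len(segs)]
        if graph.segments[s1].length < L or graph.segments[s2].length < L:
            continue
        seq1_full = graph.segments[s1].sequence or ""
        seq2_full = graph.segments[s2].sequence or ""
        p1 = int(rng.integers(0, len(seq1_full) - L + 1))
        p2 = int(rng.integers(0, len(seq2_full) - L + 1))
        name = f"pair{i}_{g}_{s1}_{s2}"
        pairs.append((name, seq1_full[p1 : p1 + L], revcomp(seq2_full[p2 : p2 + L]), (g, s1, s2)))

    if out1 is not None and out2 is not None:
        with open(out1, "w") as f1, open(out2, "w") as f2:
            for name, seq1, seq2, _ in pairs:
                f1.write(f"@{name}/1\n{seq1}\n+\n{'I' * len(seq1)}\n")
                f2.write(f"@{name}/2\n{seq2}\n+\n{'I' * len(seq2)}\n")
    return pairs


@dataclass
class BinMetrics:
    bin: str
    genome: str | None
    assigned_bp: int
    purity: float
    completeness: float
    f1: float


@dataclass
class EvalReport:
    """Nucleotide-level binning quality against the ground truth."""

    per_bin: list[BinMetrics]
    mean_purity: float
    mean_completeness: float
    mean_f1: float
    unbinned_fraction: float

    def summary(self) -> str:
        lines = [
            f"length-weighted mean purity       {100 * self.mean_purity:6.2f}%",
            f"length-weighted mean completeness {100 * self.mean_completeness:6.2f}%",
            f"length-weighted mean F1           {100 * self.mean_f1:6.2f}%",
            f"unbinned length fraction          {100 * self.unbinned_fraction:6.2f}%",
        ]
        return "\n".join(lines)


def evaluate_binning(
    result: dict[str, set[str]],
    truth: TruthBinning,
    graph: AssemblyGraph,
) -> EvalReport:
    """Per-base purity / completeness / F1 of a scaffold assignment.

    Every (scaffold, bin) assignment attributes each path segment occurrence's
    length to the bin, split by the segment's true genome set. Bins map to
    genomes greedily by correctly-attributable length; purity is the mapped
    genome's share of the bin, completeness the bin's recovered share of the
    genome, F1 their harmonic mean. Means are weighted by assigned length.
    Metrics are invariant to bin relabeling.
    """
    # bin -> genome -> bp attributable to that genome; and total per bin
    credit: dict[str, dict[str, float]] = {}
    total_bp: dict[str, float] = {}
    for scaf_name, labels in result.items():
        path = graph.scaffold(scaf_name).path
        for label in labels:
            for seg, _ in path:
                length = graph.segments[seg].length
                total_bp[label] = total_bp.get(label, 0.0) + length
                for g in truth.segment_truth[seg]:
                    credit.setdefault(label, {}).setdefault(g, 0.0)
                    credit[label][g] += length

    per_bin: list[BinMetrics] = []
    for label in sorted(total_bp):
        genome_credit = credit.get(label, {})
        if genome_credit:
            genome = min(genome_credit, key=lambda g: (-genome_credit[g], g))
            correct = genome_credit[genome]
        else:
            genome, correct = None, 0.0
        assigned = total_bp[label]
        purity = correct / assigned if assigned else 0.0
        if genome is not None:
            glen = truth.genome_length(graph, genome)
            completeness = min(correct / glen, 1.0) if glen else 0.0
        else:
            completeness = 0.0
        f1 = (
            2 * purity * completeness / (purity + completeness)
            if purity + completeness > 0
            else 0.0
        )
        per_bin.append(BinMetrics(label, genome, int(assigned), purity, completeness, f1))

    weights = np.array([m.assigned_bp for m in per_bin], dtype=float)
    if weights.sum() > 0:
        w = weights / weights.sum()
        mean_purity = float(np.dot(w, [m.purity for m in per_bin]))
        mean_completeness = float(np.dot(w, [m.completeness for m in per_bin]))
        mean_f1 = float(np.dot(w, [m.f1 for m in per_bin]))
    else:
        mean_purity = mean_completeness = mean_f1 = 0.0

    assigned_scaffolds = {s for s, labels in result.items() if labels}
    unassigned_bp = sum(
        sum(graph.segments[seg].length for seg, _ in scaf.path)
        for scaf in graph.paths
        if scaf.name not in assigned_scaffolds
    )
    total_scaffold_bp = sum(
        sum(graph.segments[seg].length for seg, _ in scaf.path) for scaf in graph.paths
    )
    unbinned_fraction = unassigned_bp / total_scaffold_bp if total_scaffold_bp else 0.0
    return EvalReport(per_bin, mean_purity, mean_completeness, mean_f1, unbinned_fraction)
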