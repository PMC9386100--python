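"""Read and write the formats the refiner touches.

Assembly graphs come in as GFA 1.0 (S/L/P records). Segments are
strand-collapsed: a unitig and its reverse complement are one node, since the
refiner labels sequences, not strands. Scaffold binnings are plain two-column
TSVs (scaffold name, bin label) as emitted by MetaBAT2/VAMB-style binners;
repeated scaffold rows are accepted as multi-label input so refiners can be
chained. Refined binnings go out as a TSV carrying the raw per-bin scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from binrefine.assign import ScaffoldAssignment

logger = logging.getLogger(__name__)

OrientedSegment = tuple[str, str]  # (segment id, "+" or "-")
Link = tuple[OrientedSegment, OrientedSegment]

_FLIP = {"+": "-", "-": "+"}


class GFAParseError(ValueError):
    """Malformed GFA record; message names the offending line."""


@dataclass(frozen=True)
class Segment:
    """One assembly-graph edge (unitig): a sequence with a length."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"segment {self.name!r} has length {self.length} < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"segment {self.name!r}: sequence/length mismatch")


@dataclass(frozen=True)
class Scaffold:
    """A named path through the assembly graph.

    ``path`` concatenates all subpaths of the GFA P-line; gap/jump joins
    (semicolon-separated subpaths) become ordinary consecutive pairs that are
    simply not adjacent in the graph — scaffold-link construction turns those
    into links later.
    """

    name: str
    path: tuple[OrientedSegment, ...]

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(seg for seg, _ in self.path)


def canonical_link(a: OrientedSegment, b: OrientedSegment) -> Link:
    """Canonical form of an oriented link: (a,o1)->(b,o2) and its reverse
    complement (b,flip o2)->(a,flip o1) map to the same key."""
    fwd = (a, b)
    rev = ((b[0], _FLIP[b[1]]), (a[0], _FLIP[a[1]]))
    return min(fwd, rev)


@dataclass
class AssemblyGraph:
    """Assembly graph G: segments (edges in assembler parlance), oriented
    links between their ends, and named scaffold paths."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[Link] = field(default_factory=set)
    paths: list[Scaffold] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = {p.name for p in self.paths}
        if len(names) != len(self.paths):
            raise ValueError("duplicate scaffold names")
        for (a, _), (b, _) in self.links:
            for seg in (a, b):
                if seg not in self.segments:
                    raise ValueError(f"link references unknown segment {seg!r}")
        for p in self.paths:
            for seg, orient in p.path:
                if seg not in self.segments:
                    raise ValueError(
                        f"path {p.name!r} references unknown segment {seg!r}"
                    )
                if orient not in ("+", "-"):
                    raise ValueError(f"path {p.name!r}: bad orientation {orient!r}")

    @property
    def scaffold_names(self) -> list[str]:
        return [p.name for p in self.paths]

    def scaffold(self, name: str) -> Scaffold:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(name)

    def undirected_links(self) -> set[frozenset[str]]:
        """Strand-collapsed adjacencies between distinct segments."""
        return {
            frozenset((a, b))
            for (a, _), (b, _) in self.links
            if a != b
        }

    def has_sequences(self) -> bool:
        return all(s.sequence is not None for s in self.segments.values())

    def total_length(self) -> int:
        return sum(s.length for s in self.segments.values())


def _parse_oriented(token: str, lineno: int) -> OrientedSegment:
    if len(token) < 2 or token[-1] not in "+-":
        raise GFAParseError(f"line {lineno}: bad oriented segment {token!r}")
    return token[:-1], token[-1]


def read_gfa(path: str | Path) -> AssemblyGraph:
    """Parse a GFA 1.0 file (S, L and P records; others ignored).

    Segment length is taken from the sequence, or from the ``LN:i:`` tag when
    the sequence is ``*``. P-line paths may contain semicolon-separated
    subpaths (jumps over coverage gaps); these are concatenated into one
    ordered path.
    """
    segments: dict[str, Segment] = {}
    links: set[Link] = set()
    raw_paths: list[tuple[str, list[OrientedSegment], int]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            rec = fields[0]
            if rec == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S record needs name and sequence")
                name, seq = fields[1], fields[2]
                tags = fields[3:]
                if seq == "*":
                    length = None
                    for tag in tags:
                        if tag.startswith("LN:i:"):
                            length = int(tag[5:])
                    if length is None:
                        raise GFAParseError(
                            f"line {lineno}: segment {name!r} has no sequence and no LN tag"
                        )
                    segments[name] = Segment(name, length)
                else:
                    segments[name] = Segment(name, len(seq), seq.upper())
            elif rec == "L":
                if len(fields) < 5:
                    raise GFAParseError(f"line {lineno}: L record needs 4 fields")
                a = (fields[1], fields[2])
                b = (fields[3], fields[4])
                if a[1] not in "+-" or b[1] not in "+-":
                    raise GFAParseError(f"line {lineno}: bad link orientation")
                links.add(canonical_link(a, b))
            elif rec == "P":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: P record needs name and path")
                name, pathspec = fields[1], fields[2]
                oriented: list[OrientedSegment] = []
                for subpath in pathspec.split(";"):
                    for token in subpath.split(","):
                        token = token.strip()
                        if token:
                            oriented.append(_parse_oriented(token, lineno))
                if not oriented:
                    raise GFAParseError(f"line {lineno}: empty path {name!r}")
                raw_paths.append((name, oriented, lineno))

    paths = []
    for name, oriented, lineno in raw_paths:
        for seg, _ in oriented:
            if seg not in segments:
                raise GFAParseError(
                    f"line {lineno}: path {name!r} references unknown segment {seg!r}"
                )
        paths.append(Scaffold(name, tuple(oriented)))
    return AssemblyGraph(segments=segments, links=links, paths=paths)


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    """Write a graph back to GFA 1.0 (deterministic record order)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.segments):
            seg = graph.segments[name]
            if seg.sequence is None:
                fh.write(f"S\t{name}\t*\tLN:i:{seg.length}\n")
            else:
                fh.write(f"S\t{name}\t{seg.sequence}\n")
        for (a, oa), (b, ob) in sorted(graph.links):
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")
        for scaf in graph.paths:
            spec = ",".join(f"{seg}{o}" for seg, o in scaf.path)
            fh.write(f"P\t{scaf.name}\t{spec}\t*\n")


@dataclass
class BinningTable:
    """Scaffold binning B: map from scaffold names to (sets of) bin labels.

    ``bins`` is the sorted list of distinct labels C; sorted order defines the
    column order of every binning matrix downstream (determinism).
    """

    assignments: dict[str, set[str]]
    bins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        observed = sorted({b for labels in self.assignments.values() for b in labels})
        if not self.bins:
            self.bins = observed
        if len(set(self.bins)) != len(self.bins):
            raise ValueError("duplicate bin labels")
        missing = set(observed) - set(self.bins)
        if missing:
            raise ValueError(f"labels {missing} used but not listed in bins")


def read_binning(path: str | Path, graph: AssemblyGraph) -> BinningTable:
    """Read a two-column TSV scaffold binning.

    Scaffolds named in the TSV but absent from the graph are dropped with a
    warning; scaffolds in the graph but absent from the TSV are simply
    unbinned. An empty file, or a file matching no graph scaffold, is an
    error: there is nothing to refine.
    """
    known = set(graph.scaffold_names)
    assignments: dict[str, set[str]] = {}
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            scaffold, label = fields[0], fields[1]
            if scaffold not in known:
                n_unknown += 1
                continue
            assignments.setdefault(scaffold, set()).add(label)
    if n_unknown:
        logger.warning("%d binning rows name scaffolds absent from the graph; dropped", n_unknown)
    if not assignments:
        raise ValueError(f"{path}: no binning rows match scaffolds in the graph")
    return BinningTable(assignments=assignments)


REFINED_HEADER = "#scaffold\tbin\tscore"


def write_refined(
    results: Iterable["ScaffoldAssignment"],
    path: str | Path,
    multiple: bool = False,
) -> None:
    """Write refined scaffold assignments with raw per-bin scores.

    Single mode: one row per scaffold (its chosen bin and that bin's score).
    Multiple mode: one row per (scaffold, assigned bin). Rows are sorted by
    scaffold name then bin label.
    """
    rows: list[tuple[str, str, float]] = []
    for res in results:
        if multiple:
            for label in sorted(res.labels):
                rows.append((res.scaffold, label, res.scores.get(label, 0.0)))
        else:
            label = res.best_label
            if label is not None:
                rows.append((res.scaffold, label, res.scores.get(label, 0.0)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write(REFINED_HEADER + "\n")
        for scaffold, label, score in rows:
            fh.write(f"{scaffold}\t{label}\t{score:.6g}\n")


def read_refined(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a refined-binning TSV back into {scaffold: {bin: score}}."""
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            scaffold, label, score = line.split("\t")
            out.setdefault(scaffold, {})[label] = float(score)
    return out
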