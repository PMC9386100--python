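"""Per-bin read extraction for MAG reassembly.

A bin's supporting edges are those whose normalized refined weight for the
bin exceeds a threshold t (default 0.1). A read pair belongs to a bin's read
set when at least one mate maps (by unique k-mers) to a supporting edge.
Because edges can support several bins, read sets may overlap — by design:
reads from shared repeats should be available to every genome that carries
them. Mate pairing and input order are preserved in the per-bin FASTQ pair.
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from binrefine.edge_binning import EdgeBinning
from binrefine.link_graph import KmerIndex, align_read_pair


@dataclass
class BinReadSets:
    """Read-pair names per bin plus each bin's supporting edge set."""

    reads: dict[str, list[str]] = field(default_factory=dict)
    supporting: dict[str, set[str]] = field(default_factory=dict)


def supporting_edges(refined: EdgeBinning, bin_label: str, t: float = 0.1) -> set[str]:
    """Edges whose row-normalized weight for ``bin_label`` is strictly > t."""
    if not 0.0 <= t < 1.0:
        raise ValueError("threshold t must be in [0, 1)")
    j = refined.bins.index(bin_label)
    norm = refined.normalized()
    col = norm[:, j].copy()
    col[refined.unbinned_mask] = 0.0
    return {refined.segment_ids[i] for i in range(len(col)) if col[i] > t}


def sanitize_label(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", label)


def _format_record(rec, mate: str) -> str:
    name = rec.name if rec.name.endswith(("/1", "/2")) else f"{rec.name}/{mate}"
    qual = rec.quality if rec.quality else "I" * len(rec.sequence or "")
    return f"@{name}\n{rec.sequence}\n+\n{qual}\n"


def _open_write(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def extract_bin_reads(
    refined: EdgeBinning,
    library: tuple[str | Path, str | Path],
    index: KmerIndex,
    t: float = 0.1,
    out_dir: str | Path | None = None,
    gzip_output: bool = False,
) -> BinReadSets:
    """Split a paired-end library into per-bin read sets.

    Each pair is aligned once against the shared unique-k-mer index; bin
    membership is then an edge-set lookup, which is equivalent to aligning
    against each bin's supporting edges separately. When ``out_dir`` is
    given, <bin>_R1.fastq[.gz] / <bin>_R2.fastq[.gz] files are written with
    pairing preserved.
    """
    support = {b: supporting_edges(refined, b, t) for b in refined.bins}
    edge_to_bins: dict[str, set[str]] = {}
    for b, edges in support.items():
        for e in edges:
            edge_to_bins.setdefault(e, set()).add(b)

    result = BinReadSets(reads={b: [] for b in refined.bins}, supporting=support)
    writers = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_output else ".fastq"
        for b in refined.bins:
            safe = sanitize_label(b)
            writers[b] = (
                _open_write(out_dir / f"{safe}_R1{ext}"),
                _open_write(out_dir / f"{safe}_R2{ext}"),
            )
    try:
        with pysam.FastxFile(str(library[0])) as f1, pysam.FastxFile(str(library[1])) as f2:
            for r1, r2 in zip(f1, f2):
                mapped = align_read_pair(index, r1.sequence or "", r2.sequence or "")
                bins_hit: set[str] = set()
                for seg in mapped:
                    bins_hit |= edge_to_bins.get(seg, set())
                pair_name = r1.name[:-2] if r1.name.endswith(("/1", "/2")) else r1.name
                for b in bins_hit:
                    result.reads[b].append(pair_name)
                    if b in writers:
                        w1, w2 = writers[b]
                        w1.write(_format_record(r1, "1"))
                        w2.write(_format_record(r2, "2"))
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()
    return result
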