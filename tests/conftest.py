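import numpy as np
import pytest

from binrefine.graph_io import AssemblyGraph, Scaffold, Segment, canonical_link


def make_graph(segment_lengths, links=(), paths=(), sequences=None):
    """Small assembly-graph builder for tests.

    segment_lengths: {name: bp}; links: iterable of (a, b) pairs (plus
    orientation tuples accepted); paths: {scaffold: [segment, ...]}.
    """
    sequences = sequences or {}
    segments = {
        name: Segment(name, length, sequences.get(name))
        for name, length in segment_lengths.items()
    }
    link_set = set()
    for link in links:
        a, b = link
        if isinstance(a, str):
            a, b = (a, "+"), (b, "+")
        link_set.add(canonical_link(a, b))
    scaffolds = [
        Scaffold(name, tuple((s, "+") for s in segs)) for name, segs in dict(paths).items()
    ]
    return AssemblyGraph(segments=segments, links=link_set, paths=scaffolds)


@pytest.fixture
def chain_graph():
    """a–b–c chain, one scaffold over all three."""
    return make_graph(
        {"a": 1000, "b": 2000, "c": 1500},
        links=[("a", "b"), ("b", "c")],
        paths={"s1": ["a", "b", "c"]},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
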