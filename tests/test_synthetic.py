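import networkx as nx
import numpy as np
import pytest

from binrefine.graph_io import write_gfa
from binrefine.link_graph import build_adjacency_links
from binrefine.synthetic import (
    CommunitySpec,
    evaluate_binning,
    generate_community,
    mask_binning,
    simulate_read_pairs,
)

SMALL = dict(segments_per_genome=(8, 8), segment_length=(200, 400))


class TestGenerateCommunity:
    def test_deterministic_under_seed(self, tmp_path):
        spec = CommunitySpec(n_genomes=3, seed=5, **SMALL)
        for run in ("one", "two"):
            g, _ = generate_community(spec)
            write_gfa(g, tmp_path / f"{run}.gfa")
        assert (tmp_path / "one.gfa").read_bytes() == (tmp_path / "two.gfa").read_bytes()

    def test_no_sharing_gives_disjoint_components(self):
        spec = CommunitySpec(n_genomes=4, shared_fraction=0.0, seed=1, **SMALL)
        g, truth = generate_community(spec)
        H = build_adjacency_links(g)
        assert nx.number_connected_components(H) == 4
        assert all(len(v) == 1 for v in truth.segment_truth.values())

    def test_shared_segment_structure(self):
        # 2 genomes x 10 segments, 5% shared -> exactly one repeat
        spec = CommunitySpec(
            n_genomes=2,
            segments_per_genome=(10, 10),
            segment_length=(200, 400),
            shared_fraction=0.05,
            seed=3,
        )
        g, truth = generate_community(spec)
        assert len(truth.shared_segments) == 1
        (rep,) = truth.shared_segments
        assert len(truth.segment_truth[rep]) == 2
        H = build_adjacency_links(g)
        assert H.degree(rep) >= 4  # welded into both circular paths
        # the repeat belongs to no contig
        assert all(rep not in scaf.segments for scaf in g.paths)

    def test_scaffolds_partition_unique_segments(self):
        spec = CommunitySpec(n_genomes=3, shared_fraction=0.1, seed=9, **SMALL)
        g, truth = generate_community(spec)
        seen = [s for scaf in g.paths for s in scaf.segments]
        unique = [s for s in g.segments if s not in truth.shared_segments]
        assert sorted(seen) == sorted(unique)  # each unique segment in exactly one contig
        for scaf in g.paths:
            assert truth.scaffold_truth[scaf.name] in {
                g_ for s in scaf.segments for g_ in truth.segment_truth[s]
            }

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec(n_genomes=1, shared_fraction=0.5)
        with pytest.raises(ValueError):
            CommunitySpec(unlabeled_fraction=1.5)


class TestMaskBinning:
    def test_zero_unlabeled_keeps_everything(self):
        spec = CommunitySpec(n_genomes=2, unlabeled_fraction=0.0, seed=2, **SMALL)
        g, truth = generate_community(spec)
        table = mask_binning(truth, spec, g)
        assert set(table.assignments) == set(truth.scaffold_truth)
        for scaf, labels in table.assignments.items():
            assert labels == {truth.scaffold_truth[scaf]}

    def test_full_masking_empty(self):
        spec = CommunitySpec(n_genomes=2, unlabeled_fraction=1.0, seed=2, **SMALL)
        g, truth = generate_community(spec)
        assert mask_binning(truth, spec, g).assignments == {}

    def test_min_length_filter(self):
        spec = CommunitySpec(
            n_genomes=2, unlabeled_fraction=0.0, min_label_length=700, seed=4, **SMALL
        )
        g, truth = generate_community(spec)
        table = mask_binning(truth, spec, g)
        for scaf in table.assignments:
            length = sum(g.segments[s].length for s in g.scaffold(scaf).segments)
            assert length >= 700

    def test_unlabeled_count_per_genome(self):
        spec = CommunitySpec(n_genomes=3, unlabeled_fraction=0.5, seed=6, **SMALL)
        g, truth = generate_community(spec)
        table = mask_binning(truth, spec, g)
        for genome in {truth.scaffold_truth[s] for s in truth.scaffold_truth}:
            eligible = [s for s, g_ in truth.scaffold_truth.items()]
            total = sum(1 for s in truth.scaffold_truth.values() if s == genome)
            kept = sum(1 for s in table.assignments if truth.scaffold_truth[s] == genome)
            assert kept == total - int(round(0.5 * total))


class TestSimulateReadPairs:
    def test_pairs_stay_within_genome(self, tmp_path):
        spec = CommunitySpec(n_genomes=3, n_read_pairs=50, read_length=60, seed=8, **SMALL)
        g, truth = generate_community(spec)
        pairs = simulate_read_pairs(g, truth, spec)
        assert pairs
        for _, _, _, (genome, s1, s2) in pairs:
            assert genome in truth.segment_truth[s1]
            assert genome in truth.segment_truth[s2]

    def test_zero_pairs_empty_files(self, tmp_path):
        spec = CommunitySpec(n_genomes=2, n_read_pairs=0, seed=8, **SMALL)
        g, truth = generate_community(spec)
        out1, out2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        pairs = simulate_read_pairs(g, truth, spec, out1, out2)
        assert pairs == []
        assert out1.read_text() == "" and out2.read_text() == ""


class TestEvaluateBinning:
    def _toy(self):
        spec = CommunitySpec(
            n_genomes=2, shared_fraction=0.0, unlabeled_fraction=0.0, seed=10, **SMALL
        )
        g, truth = generate_community(spec)
        return g, truth

    def test_perfect_assignment(self):
        g, truth = self._toy()
        result = {s: {genome} for s, genome in truth.scaffold_truth.items()}
        rep = evaluate_binning(result, truth, g)
        assert rep.mean_purity == pytest.approx(1.0)
        assert rep.mean_completeness == pytest.approx(1.0)
        assert rep.mean_f1 == pytest.approx(1.0)
        assert rep.unbinned_fraction == 0.0

    def test_half_genome_bin(self):
        g, truth = self._toy()
        genome = "genome1"
        scafs = sorted(s for s, g_ in truth.scaffold_truth.items() if g_ == genome)
        lengths = {
            s: sum(g.segments[x].length for x in g.scaffold(s).segments) for s in scafs
        }
        total = sum(lengths.values())
        # take a prefix of contigs covering ~half the genome
        acc, half = 0, []
        for s in scafs:
            if acc >= total / 2:
                break
            half.append(s)
            acc += lengths[s]
        rep = evaluate_binning({s: {"binX"} for s in half}, truth, g)
        (m,) = rep.per_bin
        assert m.genome == genome
        assert m.purity == pytest.approx(1.0)
        assert m.completeness == pytest.approx(acc / total)
        expected_f1 = 2 * m.completeness / (1 + m.completeness)
        assert m.f1 == pytest.approx(expected_f1)

    def test_label_permutation_invariant(self):
        g, truth = self._toy()
        result = {s: {genome} for s, genome in truth.scaffold_truth.items()}
        swapped = {
            s: {"genome2" if genome == "genome1" else "genome1"}
            for s, (genome,) in ((s, tuple(v)) for s, v in result.items())
        }
        rep1 = evaluate_binning(result, truth, g)
        rep2 = evaluate_binning(swapped, truth, g)
        assert rep1.mean_f1 == pytest.approx(rep2.mean_f1)
        assert rep1.mean_purity == pytest.approx(rep2.mean_purity)

    def test_empty_result(self):
        g, truth = self._toy()
        rep = evaluate_binning({}, truth, g)
        assert rep.mean_f1 == 0.0
        assert rep.unbinned_fraction == 1.0
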