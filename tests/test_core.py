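import numpy as np
import pytest

from dscls.communities import assign_roles, clique_percolation_refine, louvain_partition
from dscls.core import (
    DSCLS,
    DSCLSMap,
    DsclsParams,
    compare_variants,
    consensus_dscls,
    identify_dscls,
    propose_mutations,
)
from dscls.correlation import ndcc_matrix
from dscls.ensemble_io import ResidueAnnotation
from dscls.graph import build_graph, centrality_profile
from dscls.synthetic import default_three_block_spec, sample_correlated_ensemble
from oracles import variant_matcher
from test_graph import graph_from_edges


def _analyze(g, annotation=None, params=DsclsParams()):
    prof = centrality_profile(g)
    part = clique_percolation_refine(g, louvain_partition(g, seed=0), k=3)
    roles = assign_roles(g, part)
    return identify_dscls(g, prof, part, roles, annotation=annotation, params=params)


def k5_plus_fringe():
    """A K5 hub cluster (0-4) plus a sparse fringe so degree percentiles vary."""
    edges = [(i, j, 0.9) for i in range(5) for j in range(i + 1, 5)]
    edges += [(5, 6, 0.3), (7, 8, 0.3), (6, 9, 0.3)]
    return graph_from_edges(10, edges)


def simple_map(sets, n_residues=30, label="v"):
    return DSCLSMap(
        variant_label=label,
        dscls_list=[
            DSCLS(id=k, residues=frozenset(s), seed_hubs=frozenset(),
                  internal_edges=(), source_metric="NDCC")
            for k, s in enumerate(sets)
        ],
        n_residues=n_residues,
    )


class TestIdentify:
    def test_k5_hub_cluster_is_one_dscls(self):
        g = k5_plus_fringe()
        m = _analyze(g, params=DsclsParams(weak_degree_min=0.5, grow_weight_min=0.5))
        assert len(m.dscls_list) == 1
        assert m.dscls_list[0].residues == frozenset(range(5))
        assert m.coverage_fraction == pytest.approx(0.5)

    def test_catalytic_exclusion_dominates(self):
        g = k5_plus_fringe()
        ann = ResidueAnnotation(catalytic_pocket=frozenset(range(5)))
        m = _analyze(g, annotation=ann,
                     params=DsclsParams(weak_degree_min=0.5, grow_weight_min=0.5))
        assert m.dscls_list == []
        assert m.coverage_fraction == 0.0
        assert m.excluded_catalytic == frozenset(range(5))

    def test_excluded_sets_disjoint_from_members(self):
        g = k5_plus_fringe()
        m = _analyze(g)
        for d in m.dscls_list:
            assert not (d.residues & m.excluded_catalytic)
            assert not (d.residues & m.excluded_weak)
            assert d.seed_hubs <= d.residues

    def test_hub_dscls_spans_blocks_on_planted_fixture(self):
        spec = default_three_block_spec(n_frames=2000, seed=4)
        ens, truth = sample_correlated_ensemble(spec)
        g = build_graph(ndcc_matrix(ens, superpose=False), corr_min=0.4)
        m = _analyze(g, params=DsclsParams(grow_weight_min=0.4))
        containing = [d for d in m.dscls_list if truth.hub_residues <= d.residues]
        assert containing
        blocks = {truth.block_assignment[i] for i in containing[0].residues}
        assert len(blocks) >= 2

    def test_raising_thresholds_never_increases_coverage(self):
        spec = default_three_block_spec(n_frames=1500, seed=5)
        ens, _ = sample_correlated_ensemble(spec)
        g = build_graph(ndcc_matrix(ens, superpose=False), corr_min=0.4)
        cov = []
        for weak_min, grow_min in [(0.0, 0.4), (5.0, 0.5), (10.0, 0.6)]:
            m = _analyze(g, params=DsclsParams(weak_degree_min=weak_min,
                                               grow_weight_min=grow_min))
            cov.append(m.coverage_fraction)
        assert cov[0] >= cov[1] >= cov[2]

    def test_relabeling_invariance(self):
        edges = [(i, j, 0.9) for i in range(5) for j in range(i + 1, 5)]
        edges += [(5, 6, 0.3), (7, 8, 0.3), (6, 9, 0.3)]
        g1 = graph_from_edges(10, edges)
        perm = {i: (i + 3) % 10 for i in range(10)}
        g2 = graph_from_edges(10, [(perm[i], perm[j], w) for i, j, w in edges])
        params = DsclsParams(weak_degree_min=0.5, grow_weight_min=0.5)
        m1 = _analyze(g1, params=params)
        m2 = _analyze(g2, params=params)
        sets1 = {frozenset(perm[i] for i in d.residues) for d in m1.dscls_list}
        sets2 = {d.residues for d in m2.dscls_list}
        assert sets1 == sets2


class TestConsensus:
    def test_identical_maps_are_idempotent(self):
        g = k5_plus_fringe()
        m = _analyze(g, params=DsclsParams(weak_degree_min=0.5, grow_weight_min=0.5))
        cons = consensus_dscls(m, m)
        assert [d.residues for d in cons.dscls_list] == [d.residues for d in m.dscls_list]
        assert cons.dscls_list[0].source_metric == "consensus"

    def test_disjoint_maps_give_empty_consensus(self):
        a = simple_map([{0, 1, 2, 3}])
        b = simple_map([{10, 11, 12, 13}])
        cons = consensus_dscls(a, b)
        assert cons.dscls_list == []
        assert cons.coverage_fraction == 0.0

    def test_half_overlap_keeps_intersection(self):
        a = simple_map([{0, 1, 2, 3, 4, 5}])
        b = simple_map([{3, 4, 5, 6, 7, 8}])  # jaccard 3/9 >= 0.25
        cons = consensus_dscls(a, b)
        assert cons.covered_residues == frozenset({3, 4, 5})

    def test_residue_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_dscls(simple_map([{0}], 10), simple_map([{0}], 20))


class TestCompare:
    def test_self_comparison_is_silent(self):
        m = simple_map([{0, 1, 2, 3}, {10, 11, 12}, {20, 21, 22, 23}])
        comp = compare_variants(m, m)
        assert comp.events == []
        assert comp.coverage_delta == 0.0
        assert all(j == 1.0 for _, _, j in comp.matching)

    def test_fusion_detected(self):
        wt = simple_map([{0, 1, 2, 3}, {5, 6, 7, 8}])
        mut = simple_map([{0, 1, 2, 3, 5, 6, 7, 8}])
        comp = compare_variants(wt, mut)
        kinds = [e["kind"] for e in comp.events]
        assert kinds == ["fusion"]
        assert comp.events[0]["wt_ids"] == [0, 1]

    def test_loss_gain_and_relocation(self):
        wt = simple_map([{0, 1, 2, 3}, {10, 11, 12, 13}])
        mut = simple_map([{2, 3, 4, 5}, {20, 21, 22}])
        comp = compare_variants(wt, mut)
        kinds = sorted(e["kind"] for e in comp.events)
        assert kinds == ["gain", "loss", "relocation"]

    def test_matches_independent_matcher_on_random_maps(self, rng):
        for _ in range(50):
            n_wt = int(rng.integers(0, 5))
            n_mut = int(rng.integers(0, 5))
            universe = np.arange(40)
            wt_sets = [frozenset(rng.choice(universe, size=rng.integers(3, 10),
                                            replace=False).tolist()) for _ in range(n_wt)]
            mut_sets = [frozenset(rng.choice(universe, size=rng.integers(3, 10),
                                             replace=False).tolist()) for _ in range(n_mut)]
            comp = compare_variants(simple_map(wt_sets, 40), simple_map(mut_sets, 40))
            links, events = variant_matcher(wt_sets, mut_sets)
            assert {(w, m) for w, m, _ in comp.matching} == links
            got = sorted(
                (e["kind"], tuple(e["wt_ids"]), tuple(e["mut_ids"])) for e in comp.events
            )
            assert got == events

    def test_residue_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_variants(simple_map([], 10), simple_map([], 12))


class TestPropose:
    def test_nothing_to_propose_when_all_stabilizing(self):
        g = k5_plus_fringe()
        m = _analyze(g, params=DsclsParams(weak_degree_min=0.5, grow_weight_min=0.5))
        out = propose_mutations(g, m, "F" * 10)
        assert out == []

    def test_adjacent_alanine_strengthens_existing(self):
        edges = [(i, j, 0.9) for i in range(5) for j in range(i + 1, 5)]
        edges += [(4, 6, 0.8), (7, 8, 0.3), (8, 9, 0.3)]
        g = graph_from_edges(10, edges)
        m = _analyze(g, params=DsclsParams(weak_degree_min=0.5, grow_weight_min=0.85))
        assert m.covered_residues == frozenset(range(5))
        seq = "FFFFF" + "A" + "FFFF"  # only residue 5... adjacent? no: use 6
        seq = "FFFFFFAFFF"  # residue 6 is the alanine adjacent to the K5
        out = propose_mutations(g, m, seq)
        assert len(out) == 1
        c = out[0]
        assert (c.residue_index, c.current_aa, c.proposed_aa, c.rationale) == (
            6, "A", "F", "strengthen_existing",
        )
        assert c.adjacency_score == pytest.approx(0.8)

    def test_catalytic_and_stabilizing_residues_never_proposed(self):
        spec = default_three_block_spec(n_frames=1500, seed=6)
        ens, _ = sample_correlated_ensemble(spec)
        g = build_graph(ndcc_matrix(ens, superpose=False), corr_min=0.4)
        ann = ResidueAnnotation(catalytic_pocket=frozenset({5, 25, 45}))
        m = _analyze(g, annotation=ann, params=DsclsParams(grow_weight_min=0.4))
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("AVLIMTSDNQKREFYW"), size=60))
        out = propose_mutations(g, m, seq, annotation=ann, top_n=60)
        for c in out:
            assert c.residue_index not in ann.catalytic_pocket
            assert c.proposed_aa in set("FYWREK")
            assert c.current_aa not in set("FYWREK")
            assert c.proposed_aa != c.current_aa

    def test_planted_hub_neighbor_valine_ranked(self):
        spec = default_three_block_spec(n_frames=2000, seed=7)
        ens, truth = sample_correlated_ensemble(spec)
        g = build_graph(ndcc_matrix(ens, superpose=False), corr_min=0.4)
        m = _analyze(g, params=DsclsParams(grow_weight_min=0.4))
        hub = next(iter(truth.hub_residues))
        assert any(hub in d.residues for d in m.dscls_list)
        neighbor = 11  # sequence neighbor-of-hub within block 0, valine below
        seq = "".join("V" if i == neighbor else "F" for i in range(60))
        out = propose_mutations(g, m, seq, top_n=5)
        # the valine borders the hub DSCLS and is the only mutable residue
        assert out and out[0].residue_index == neighbor
        assert out[0].proposed_aa == "F"

    def test_sequence_length_mismatch_rejected(self):
        g = k5_plus_fringe()
        m = _analyze(g)
        with pytest.raises(ValueError):
            propose_mutations(g, m, "AAA")
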