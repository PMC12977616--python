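import networkx as nx
import numpy as np
import pytest

from cytopan.errors import InvalidParameterError, InvalidSequenceError
from cytopan.homolog_cluster import (
    BBHPair,
    ClusterParams,
    bidirectional_best_hit,
    build_graph,
    mcl_cluster,
    pairwise_similarity,
    transfer_annotations,
)
from cytopan.mhc_detect import GeneRecord


def _gene(gid, genome, protein):
    return GeneRecord(gid, genome, "", protein)


class TestPairwiseSimilarity:
    def test_identical_sequences_full_identity(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        score, ident = pairwise_similarity(seq, seq)
        self_score, _ = pairwise_similarity(seq, seq)
        assert ident == 100.0
        assert score == self_score

    def test_symmetry(self, rng):
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            a = "".join(rng.choice(aa, size=20))
            b = "".join(rng.choice(aa, size=25))
            sa, ia = pairwise_similarity(a, b)
            sb, ib = pairwise_similarity(b, a)
            assert sa == pytest.approx(sb)
            assert ia == pytest.approx(ib)

    def test_invalid_residue_rejected(self):
        with pytest.raises(InvalidSequenceError):
            pairwise_similarity("MK!", "MK")


class TestBuildGraph:
    def test_identical_pair_weight_one(self):
        genes = [_gene("a", "g1", "MKTAYIAKQR"), _gene("b", "g2", "MKTAYIAKQR")]
        graph = build_graph(genes)
        assert graph.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_unrelated_random_sequences_stay_unlinked(self, rng):
        """Empirical null: random 60-mers fall below the 0.3 threshold."""
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        genes = [
            _gene(f"r{i}", f"g{i}", "".join(rng.choice(aa, size=60)))
            for i in range(20)
        ]
        graph = build_graph(genes)
        assert graph.number_of_edges() == 0

    def test_threshold_one_keeps_only_identical_pairs(self):
        genes = [
            _gene("a", "g1", "MKTAYIAKQRQISFVK"),
            _gene("b", "g2", "MKTAYIAKQRQISFVK"),
            _gene("c", "g3", "MKTAYIGKQRQISFVK"),  # one substitution
        ]
        graph = build_graph(genes, ClusterParams(edge_threshold=1.0))
        assert set(graph.edges) == {("a", "b")}

    def test_duplicate_ids_rejected(self):
        genes = [_gene("a", "g1", "MK"), _gene("a", "g2", "MK")]
        with pytest.raises(InvalidParameterError):
            build_graph(genes)


class TestMclCluster:
    def _clique_graph(self):
        g = nx.Graph()
        for grp, members in (("x", "abc"), ("y", "def")):
            for m in members:
                g.add_node(m, genome_id=grp)
            for i in members:
                for j in members:
                    if i < j:
                        g.add_edge(i, j, weight=0.9)
        return g

    @pytest.mark.parametrize("inflation", [1.0, 1.5, 5.0])
    def test_two_cliques_two_clusters(self, inflation):
        clusters = mcl_cluster(self._clique_graph(), inflation=inflation)
        memberships = sorted(frozenset(c.gene_ids) for c in clusters)
        assert memberships == [frozenset("abc"), frozenset("def")]

    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        clusters = mcl_cluster(g, inflation=1.5)
        assert sorted(len(c) for c in clusters) == [1, 1, 1, 1]

    def test_partition_property(self, small_pangenome):
        genes = small_pangenome.all_genes()
        graph = build_graph(genes)
        clusters = mcl_cluster(graph, inflation=1.5)
        all_members = [gid for c in clusters for gid in c.gene_ids]
        assert len(all_members) == len(set(all_members)) == len(genes)

    def test_disconnected_components_never_merge(self, small_pangenome):
        graph = build_graph(small_pangenome.all_genes())
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(graph)):
            for n in comp:
                comp_of[n] = i
        for c in mcl_cluster(graph, inflation=1.0):
            comps = {comp_of[g] for g in c.gene_ids}
            assert len(comps) == 1

    def test_planted_families_recovered_at_default_inflation(
        self, small_pangenome
    ):
        """>=90% of truth-table families come back as exact clusters."""
        sim = small_pangenome
        graph = build_graph(sim.all_genes())
        clusters = mcl_cluster(graph, inflation=1.5)
        cluster_sets = {frozenset(c.gene_ids) for c in clusters}
        truth = sim.truth[~sim.truth.is_singleton]
        # duplicates are genuine family members and must co-cluster
        families = truth.groupby("family_id")["gene_id"].apply(frozenset)
        recovered = sum(1 for fam in families if fam in cluster_sets)
        assert recovered / len(families) >= 0.9

    def test_rejects_bad_inflation(self):
        with pytest.raises(InvalidParameterError):
            mcl_cluster(nx.Graph([("a", "b")]), inflation=0.5)


class TestBidirectionalBestHit:
    def _graph(self, edges, genomes):
        g = nx.Graph()
        for node, genome in genomes.items():
            g.add_node(node, genome_id=genome)
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        return g

    def test_single_gene_each_side(self):
        g = self._graph([("a1", "b1", 0.8)], {"a1": "A", "b1": "B"})
        pairs = bidirectional_best_hit("A", "B", g)
        assert pairs == [BBHPair("a1", "b1", 0.8, tie=False)]

    def test_equal_scoring_paralogs_flagged_as_tie(self):
        g = self._graph(
            [("a1", "b1", 0.7), ("a1", "b2", 0.7)],
            {"a1": "A", "b1": "B", "b2": "B"},
        )
        pairs = bidirectional_best_hit("A", "B", g)
        assert len(pairs) == 1
        assert pairs[0].gene_b == "b1"  # lexicographic tie-break
        assert pairs[0].tie

    def test_non_reciprocal_best_hits_excluded(self):
        g = self._graph(
            [("a1", "b1", 0.9), ("a2", "b1", 0.95)],
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        pairs = bidirectional_best_hit("A", "B", g)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a2", "b1")]

    def test_simulated_orthologs_recovered(self, small_pangenome):
        """At modest divergence BBH pairs match the truth table for
        genomes without duplicated families."""
        sim = small_pangenome
        graph = build_graph(sim.all_genes())
        truth = sim.truth
        g_a, g_b = "g01", "g02"
        dup_fams = set(
            truth[truth.is_duplicate & truth.genome.isin([g_a, g_b])].family_id
        )
        expected = {}
        for fam, sub in truth[~truth.is_singleton & ~truth.is_duplicate].groupby(
            "family_id"
        ):
            if fam in dup_fams:
                continue
            in_a = sub[sub.genome == g_a].gene_id.tolist()
            in_b = sub[sub.genome == g_b].gene_id.tolist()
            if len(in_a) == 1 and len(in_b) == 1:
                expected[in_a[0]] = in_b[0]
        pairs = {
            p.gene_a: p.gene_b for p in bidirectional_best_hit(g_a, g_b, graph)
        }
        hits = sum(1 for a, b in expected.items() if pairs.get(a) == b)
        assert hits / len(expected) >= 0.9


class TestTransferAnnotations:
    def test_unambiguous_name_copied(self):
        names = transfer_annotations(
            {"ref1": "ppcA"}, [BBHPair("ref1", "t1", 0.9)], ["t1"]
        )
        assert names == {"t1": "ppcA"}

    def test_paralogs_get_numeric_suffixes(self):
        pairs = [BBHPair("refA", "t1", 0.9), BBHPair("refB", "t2", 0.8)]
        names = transfer_annotations(
            {"refA": "ppcA", "refB": "ppcA"}, pairs, ["t1", "t2"]
        )
        assert names == {"t1": "ppcA_1", "t2": "ppcA_2"}

    def test_no_hit_becomes_hypothetical(self):
        names = transfer_annotations({"refA": "ppcA"}, [], ["t1"])
        assert names == {"t1": "hypothetical"}
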