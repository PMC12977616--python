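import numpy as np
import pytest

from cytopan.errors import InvalidParameterError, InvalidSequenceError
from cytopan.genetic_code import has_internal_stop, translate_cds
from cytopan.mhc_detect import count_heme_motifs
from cytopan.synthetic_data import (
    SimParams,
    evolve_cds,
    random_cds,
    simulate_pangenome,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_leaves_sit_at_divergence_depth(self):
        tree = simulate_tree(2, seed=5, divergence=0.2)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert depths == pytest.approx([0.2, 0.2])

    def test_same_seed_gives_identical_newick(self):
        a = simulate_tree(10, seed=7).as_string(schema="newick")
        b = simulate_tree(10, seed=7).as_string(schema="newick")
        assert a == b

    def test_leaf_count_and_ultrametricity(self):
        tree = simulate_tree(16, seed=7, divergence=0.3)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 16
        depths = [leaf.distance_from_root() for leaf in leaves]
        assert depths == pytest.approx([0.3] * 16)
        assert len({leaf.taxon.label for leaf in leaves}) == 16

    def test_rejects_single_genome(self):
        with pytest.raises(InvalidParameterError):
            simulate_tree(1, seed=0)


class TestEvolveCds:
    def test_zero_branch_is_identity(self, rng):
        cds = random_cds(100, rng)
        assert evolve_cds(cds, 0.0, omega=1.0, seed=1) == cds

    def test_tiny_omega_allows_only_synonymous_changes(self, rng):
        cds = random_cds(200, rng)
        out = evolve_cds(cds, 1.0, omega=1e-12, seed=2)
        assert translate_cds(out) == translate_cds(cds)
        assert out != cds  # synonymous changes did happen on a long branch

    def test_internal_stop_rejected(self):
        with pytest.raises(InvalidSequenceError):
            evolve_cds("ATGTAAAAA", 0.1, omega=1.0, seed=0)

    def test_locked_positions_are_immutable(self, rng):
        cds = random_cds(100, rng)
        locked = frozenset(range(30, 60))
        out = evolve_cds(cds, 2.0, omega=1.0, locked_positions=locked, seed=3)
        assert all(out[i] == cds[i] for i in locked)

    def test_no_internal_stops_after_long_branch(self, rng):
        cds = random_cds(150, rng)
        out = evolve_cds(cds, 2.0, omega=1.0, seed=4)
        assert not has_internal_stop(out)

    def test_determinism(self, rng):
        cds = random_cds(100, rng)
        assert evolve_cds(cds, 0.5, 0.5, seed=9) == evolve_cds(
            cds, 0.5, 0.5, seed=9
        )


class TestSimulatePangenome:
    def test_identical_seed_identical_output(self):
        p = SimParams(n_genomes=4, n_core=3, n_accessory=4,
                      singleton_rate=1.0, seed=11)
        a, b = simulate_pangenome(p), simulate_pangenome(p)
        assert a.truth.equals(b.truth)
        assert [g.cds for g in a.all_genes()] == [g.cds for g in b.all_genes()]
        assert a.tree.as_string(schema="newick") == b.tree.as_string(
            schema="newick"
        )

    def test_truth_table_consistent_with_genomes(self, small_pangenome):
        sim = small_pangenome
        gene_ids = {g.gene_id for g in sim.all_genes()}
        assert set(sim.truth.gene_id) == gene_ids
        n_singletons_truth = int(sim.truth.is_singleton.sum())
        n_singletons_genes = sum(
            1 for g in sim.all_genes() if "|sing" in g.gene_id
        )
        assert n_singletons_truth == n_singletons_genes

    def test_singleton_families_unique_to_one_genome(self, small_pangenome):
        truth = small_pangenome.truth
        singles = truth[truth.is_singleton]
        per_family = singles.groupby("family_id")["genome"].nunique()
        assert (per_family == 1).all()

    def test_motif_counts_survive_evolution(self, small_pangenome):
        """Locked positions + motif guard keep each family's CXXCH count
        constant across every genome."""
        sim = small_pangenome
        genes = {g.gene_id: g for g in sim.all_genes()}
        fam_rows = sim.truth[sim.truth.family_id.str.startswith("acc")]
        for fam, sub in fam_rows.groupby("family_id"):
            counts = {
                count_heme_motifs(genes[gid].protein)
                for gid in sub.gene_id
            }
            assert len(counts) == 1, f"{fam} motif count drifted: {counts}"

    def test_no_internal_stops_anywhere(self, small_pangenome):
        for g in small_pangenome.all_genes():
            assert not has_internal_stop(g.cds)
            assert translate_cds(g.cds) == g.protein

    def test_core_everywhere_when_nothing_is_lost(self):
        p = SimParams(
            n_genomes=5, n_core=4, n_accessory=3, presence_prob=1.0,
            singleton_rate=0.0, dup_prob=0.0, seed=13,
            gene_length_codons=(40, 60),
        )
        sim = simulate_pangenome(p)
        fams = sim.truth[~sim.truth.is_singleton]
        per_family = fams.groupby("family_id")["genome"].nunique()
        assert (per_family == 5).all()
        assert not sim.truth.is_singleton.any()

    def test_forced_duplication(self):
        p = SimParams(
            n_genomes=4, n_core=2, n_accessory=1, presence_prob=1.0,
            singleton_rate=0.0, dup_prob=1.0, seed=17,
            gene_length_codons=(40, 60),
        )
        sim = simulate_pangenome(p)
        acc = sim.truth[sim.truth.family_id == "acc0000"]
        for genome, sub in acc.groupby("genome"):
            assert len(sub) >= 2  # original + duplicate
            assert sub.is_duplicate.any()

    def test_omega_classes_follow_localization(self, small_pangenome):
        truth = small_pangenome.truth
        acc = truth[truth.family_id.str.startswith("acc")]
        mapping = acc.groupby("localization")["omega_class"].unique()
        assert set(mapping["IM"]) == {"low"}
        assert set(mapping["periplasm"]) == {"mid"}
        assert set(mapping["ppc"]) == {"high"}
        assert set(mapping["OM_ext"]) == {"high"}

    def test_paralog_pool_generator_contract(self):
        from cytopan.synthetic_data import simulate_ortholog_paralog_pool

        orth, para = simulate_ortholog_paralog_pool(
            n_genomes=5, n_paralogs_per_genome=2, seed=3
        )
        assert len(orth) == 5 and len(para) == 10
        assert len({len(s) for s in orth + para}) == 1  # no indels
        assert all(count_heme_motifs(s) == 3 for s in orth + para)
        orth2, _ = simulate_ortholog_paralog_pool(
            n_genomes=5, n_paralogs_per_genome=2, seed=3
        )
        assert orth == orth2

    def test_divergent_families_generator_contract(self):
        from cytopan.synthetic_data import simulate_divergent_families

        fams = simulate_divergent_families(
            n_families=3, members_per_family=4, seed=3
        )
        assert len(fams) == 3
        assert all(len(f) == 4 for f in fams)
        assert all(
            count_heme_motifs(s) == 6 for f in fams for s in f
        )

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            SimParams(n_genomes=1)
        with pytest.raises(InvalidParameterError):
            SimParams(presence_prob=1.5)
        with pytest.raises(InvalidParameterError):
            SimParams(omega_core=0.0)
        with pytest.raises(InvalidParameterError):
            SimParams(gene_length_codons=(10, 20))
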