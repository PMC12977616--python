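import numpy as np
import pytest

from cytopan.curation import (
    KEPT,
    REMOVED_HEMES,
    REMOVED_LENGTH,
    REMOVED_PARALOG,
    curate,
    curate_cluster,
    resolve_paralogs,
    synteny_support,
)
from cytopan.errors import InvalidParameterError
from cytopan.homolog_cluster import HomologCluster, build_graph, mcl_cluster
from cytopan.mhc_detect import GeneRecord


def _gene(gid, genome, n_res, hemes):
    return GeneRecord(gid, genome, "", "A" * n_res, heme_count=hemes)


def _cluster(genes):
    return HomologCluster(
        cluster_id="C0",
        gene_ids=tuple(g.gene_id for g in genes),
        genome_ids=tuple(g.genome_id for g in genes),
    )


class TestCurateCluster:
    def test_length_rule_boundary_at_twenty_percent(self):
        genes = {
            "ref": _gene("ref", "gref", 100, 3),
            "at_edge": _gene("at_edge", "g1", 120, 3),
            "over": _gene("over", "g2", 121, 3),
            "under": _gene("under", "g3", 79, 3),
        }
        rep = curate_cluster(_cluster(genes.values()), genes, "ref")
        assert rep.status["at_edge"] == KEPT
        assert rep.status["over"] == REMOVED_LENGTH
        assert rep.status["under"] == REMOVED_LENGTH

    def test_heme_rule_boundary_at_plus_minus_two(self):
        genes = {
            "ref": _gene("ref", "gref", 100, 3),
            "edge": _gene("edge", "g1", 100, 5),
            "over": _gene("over", "g2", 100, 6),
            "one": _gene("one", "g3", 100, 1),
        }
        rep = curate_cluster(_cluster(genes.values()), genes, "ref")
        assert rep.status["edge"] == KEPT
        assert rep.status["over"] == REMOVED_HEMES
        assert rep.status["one"] == KEPT  # |1-3| = 2

    def test_identical_members_all_kept(self):
        genes = {f"g{i}": _gene(f"g{i}", f"gen{i}", 100, 3) for i in range(4)}
        rep = curate_cluster(_cluster(genes.values()), genes, "g0")
        assert all(s == KEPT for s in rep.status.values())

    def test_missing_reference_raises(self):
        genes = {"a": _gene("a", "g1", 100, 3)}
        with pytest.raises(InvalidParameterError):
            curate_cluster(_cluster(genes.values()), genes, "ref")

    def test_loosening_tolerances_never_shrinks_kept_set(self, rng):
        genes = {"ref": _gene("ref", "gref", 100, 4)}
        for i in range(30):
            genes[f"m{i}"] = _gene(
                f"m{i}", f"gen{i}",
                int(rng.integers(60, 160)), int(rng.integers(0, 9)),
            )
        cluster = _cluster(genes.values())
        kept_tight = set(
            curate_cluster(cluster, genes, "ref", 0.10, 1).kept
        )
        kept_loose = set(
            curate_cluster(cluster, genes, "ref", 0.30, 3).kept
        )
        assert kept_tight <= kept_loose

    def test_idempotent(self):
        genes = {
            "ref": _gene("ref", "gref", 100, 3),
            "keep": _gene("keep", "g1", 110, 4),
            "drop": _gene("drop", "g2", 150, 4),
        }
        rep1 = curate_cluster(_cluster(genes.values()), genes, "ref")
        kept_genes = {g: genes[g] for g in rep1.kept}
        rep2 = curate_cluster(_cluster(kept_genes.values()), kept_genes, "ref")
        assert set(rep2.kept) == set(rep1.kept)
        assert all(s == KEPT for s in rep2.status.values())


class TestSyntenySupport:
    def _setup(self):
        orders = {
            "R": ["r0", "r1", "r2", "REF", "r4", "r5", "r6"],
            "T": ["t0", "t1", "t2", "TGT", "t4", "t5", "t6"],
        }
        gene_to_genome = {g: "R" for g in orders["R"]}
        gene_to_genome.update({g: "T" for g in orders["T"]})
        # flanks share clusters pairwise: r_i with t_i
        cluster_of = {}
        for i in range(7):
            cluster_of[f"r{i}"] = f"F{i}"
            cluster_of[f"t{i}"] = f"F{i}"
        cluster_of["REF"] = "FX"
        cluster_of["TGT"] = "FX"
        return orders, gene_to_genome, cluster_of

    def test_identical_neighborhood_full_support(self):
        orders, g2g, cof = self._setup()
        support, denom = synteny_support("TGT", "REF", orders, g2g, cof)
        assert (support, denom) == (6, 6)

    def test_shuffled_neighborhood_no_support(self):
        orders, g2g, cof = self._setup()
        for i in range(7):
            cof[f"t{i}"] = f"G{i}"  # different clusters everywhere
        support, _ = synteny_support("TGT", "REF", orders, g2g, cof)
        assert support == 0

    def test_contig_edge_truncates_denominator(self):
        orders, g2g, cof = self._setup()
        orders["T"] = orders["T"][3:]  # TGT now first on its contig
        support, denom = synteny_support("TGT", "REF", orders, g2g, cof)
        assert denom == 3
        assert support == 3


class TestResolveParalogs:
    def _report_and_genes(self):
        genes = {
            "ref": _gene("ref", "gref", 100, 3),
            "p1": _gene("p1", "g1", 100, 3),
            "p2": _gene("p2", "g1", 100, 3),
            "solo": _gene("solo", "g2", 100, 3),
        }
        cluster = _cluster(genes.values())
        report = curate_cluster(cluster, genes, "ref")
        return report, genes

    def test_single_member_genomes_untouched(self):
        report, genes = self._report_and_genes()
        resolve_paralogs(report, genes, {"p1": 6, "p2": 0, "solo": 0})
        assert report.status["solo"] == KEPT

    def test_unique_supported_member_kept(self):
        report, genes = self._report_and_genes()
        resolve_paralogs(report, genes, {"p1": 5, "p2": 0})
        assert report.status["p1"] == KEPT
        assert report.status["p2"] == REMOVED_PARALOG

    def test_no_support_removes_both(self):
        report, genes = self._report_and_genes()
        resolve_paralogs(report, genes, {"p1": 0, "p2": 1})
        assert report.status["p1"] == REMOVED_PARALOG
        assert report.status["p2"] == REMOVED_PARALOG

    def test_ambiguous_support_removes_both(self):
        report, genes = self._report_and_genes()
        resolve_paralogs(report, genes, {"p1": 4, "p2": 4})
        assert report.status["p1"] == REMOVED_PARALOG
        assert report.status["p2"] == REMOVED_PARALOG

    def test_at_most_one_kept_per_genome(self, small_pangenome):
        sim = small_pangenome
        genes = {g.gene_id: g for g in sim.all_genes()}
        graph = build_graph(sim.all_genes())
        clusters = mcl_cluster(graph, inflation=1.5)
        cluster_of = {g: c.cluster_id for c in clusters for g in c.gene_ids}
        reference = "g01"
        for c in clusters:
            refs = [g for g, gn in zip(c.gene_ids, c.genome_ids)
                    if gn == reference]
            if not refs:
                continue
            rep = curate(
                c, genes, sorted(refs)[0],
                gene_orders=sim.gene_orders, cluster_of=cluster_of,
            )
            per_genome = {}
            for gid in rep.kept:
                if gid == rep.reference_member:
                    continue
                per_genome.setdefault(genes[gid].genome_id, []).append(gid)
            assert all(len(v) <= 1 for v in per_genome.values())


class TestSyntenyOnSimulatedData:
    def test_orthologs_outscore_relocated_duplicates(self, small_pangenome):
        """Orthologs keep their neighborhoods; duplicates are inserted
        at random positions, so ortholog synteny support should win in
        nearly all cases."""
        sim = small_pangenome
        genes = {g.gene_id: g for g in sim.all_genes()}
        truth = sim.truth
        # family clusters straight from truth (oracle clustering)
        cluster_of = {
            r.gene_id: r.family_id for r in truth.itertuples()
        }
        g2g = {gid: genes[gid].genome_id for gid in genes}
        wins = ties_or_losses = 0
        dups = truth[truth.is_duplicate]
        for row in dups.itertuples():
            ortholog = f"{row.genome}|{row.family_id}"
            ref_row = truth[
                (truth.family_id == row.family_id)
                & (truth.genome != row.genome)
                & (~truth.is_duplicate)
            ]
            if ortholog not in genes or ref_row.empty:
                continue
            ref_gene = ref_row.gene_id.iloc[0]
            s_orth, _ = synteny_support(
                ortholog, ref_gene, sim.gene_orders, g2g, cluster_of
            )
            s_dup, _ = synteny_support(
                row.gene_id, ref_gene, sim.gene_orders, g2g, cluster_of
            )
            if s_orth > s_dup:
                wins += 1
            else:
                ties_or_losses += 1
        assert wins >= 1
        assert wins / (wins + ties_or_losses) >= 0.8
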