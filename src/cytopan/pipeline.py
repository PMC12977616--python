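"""End-to-end orchestration: detect -> cluster -> curate -> dnds ->
stats -> pangenome (-> profile on request).

Every stage writes a TSV into the output directory and contributes to a
manifest recording parameters, seeds and per-stage record counts, so a
rerun with the same configuration reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .codon_dnds import estimate_dnds_cds
from .curation import curate
from .errors import InvalidParameterError
from .homolog_cluster import (
    ClusterParams,
    build_graph,
    clusters_to_rows,
    mcl_cluster,
)
from .io import (
    read_genome_dir,
    read_newick,
    read_tsv,
    write_pangenome,
    write_tsv,
)
from .mhc_detect import detect_table, is_mhc
from .pangenome import accumulation_curve, cluster_spectrum
from .stats_compare import compare_by_localization, compare_core_vs_mhc
from .synthetic_data import SimParams, simulate_pangenome

log = logging.getLogger("cytopan")

DEFAULT_CONFIG: dict = {
    "simulate": None,          # SimParams fields, or None to load from disk
    "ffn_dir": None,
    "tree": None,
    "gene_order": None,
    "reference_genome": None,
    "min_hemes": 2,
    "patterns": ["CxxCH"],
    "inflation": 1.5,
    "edge_threshold": 0.3,
    "length_tol": 0.20,
    "heme_tol": 2,
    "synteny_window": 3,
    "min_synteny_support": 2,
    "alpha": 0.05,
    "bin10_inclusive": True,
    "seed": 0,
}


def _load_inputs(config: Mapping, outdir: Path):
    if config.get("simulate") is not None:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", config.get("seed", 0))
        params = SimParams(**sim_kwargs)
        sim = simulate_pangenome(params)
        write_pangenome(sim, outdir / "simulated")
        reference = config.get("reference_genome") or sorted(sim.genomes)[0]
        return sim.genomes, sim.tree, sim.gene_orders, reference, asdict(params)
    if not config.get("ffn_dir") or not config.get("tree"):
        raise InvalidParameterError(
            "config must provide either 'simulate' or 'ffn_dir' + 'tree'"
        )
    genomes = read_genome_dir(config["ffn_dir"], patterns=config["patterns"])
    tree = read_newick(config["tree"])
    if config.get("gene_order"):
        df = read_tsv(config["gene_order"])
        gene_orders = {
            g: list(sub.sort_values("position")["gene_id"])
            for g, sub in df.groupby("genome")
        }
    else:
        gene_orders = {g: [x.gene_id for x in genes] for g, genes in genomes.items()}
    reference = config.get("reference_genome")
    if not reference:
        raise InvalidParameterError("reference_genome required for real data")
    return genomes, tree, gene_orders, reference, None


def run_pipeline(config: Mapping | None = None, out_dir="cytopan_out") -> dict:
    """Run the full analysis; returns a dict of in-memory stage outputs.

    Aborts with the failing stage named; files already written are
    retained for inspection.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }
    results: dict = {}
    stage = "load"
    try:
        genomes, tree, gene_orders, reference, sim_params = _load_inputs(
            cfg, outdir
        )
        if reference not in genomes:
            raise InvalidParameterError(
                f"reference genome {reference!r} absent from inputs"
            )
        if sim_params:
            manifest["stages"]["simulate"] = {"params": sim_params}
        all_genes = [g for gid in sorted(genomes) for g in genomes[gid]]
        gene_map = {g.gene_id: g for g in all_genes}
        results.update(
            genomes=genomes, tree=tree, gene_orders=gene_orders,
            reference=reference,
        )

        stage = "detect"
        mhc_table = detect_table(
            all_genes, patterns=cfg["patterns"], min_hemes=cfg["min_hemes"]
        )
        write_tsv(mhc_table, outdir / "mhc_table.tsv")
        manifest["stages"]["detect"] = {
            "n_genes": len(mhc_table),
            "n_mhc": int(mhc_table["is_mhc"].sum()),
        }
        results["mhc_table"] = mhc_table

        stage = "cluster"
        cparams = ClusterParams(
            inflation=cfg["inflation"], edge_threshold=cfg["edge_threshold"]
        )
        graph = build_graph(all_genes, cparams)
        clusters = mcl_cluster(graph, inflation=cparams.inflation)
        write_tsv(pd.DataFrame(clusters_to_rows(clusters)),
                  outdir / "clusters.tsv")
        manifest["stages"]["cluster"] = {
            "n_clusters": len(clusters),
            "inflation": cparams.inflation,
        }
        results["graph"] = graph
        results["clusters"] = clusters
        cluster_of = {
            gid: c.cluster_id for c in clusters for gid in c.gene_ids
        }

        stage = "curate"
        n_genomes = len(genomes)
        reports = []
        curated_rows = []
        for c in clusters:
            ref_members = sorted(
                gid for gid, gn in zip(c.gene_ids, c.genome_ids)
                if gn == reference
            )
            if not ref_members:
                continue
            c.reference_member = ref_members[0]
            report = curate(
                c, gene_map, c.reference_member,
                gene_orders=gene_orders, cluster_of=cluster_of,
                length_tol=cfg["length_tol"], heme_tol=cfg["heme_tol"],
                window=cfg["synteny_window"],
                min_support=cfg["min_synteny_support"],
            )
            reports.append(report)
            for gid, status in report.status.items():
                curated_rows.append(
                    {
                        "cluster_id": c.cluster_id, "gene_id": gid,
                        "genome_id": gene_map[gid].genome_id,
                        "status": status,
                        "is_reference_member": gid == c.reference_member,
                    }
                )
        curated = pd.DataFrame(curated_rows)
        write_tsv(curated, outdir / "curated.tsv")
        manifest["stages"]["curate"] = {
            "n_clusters_with_reference": len(reports),
            "n_kept": int((curated["status"] == "kept").sum())
            if len(curated) else 0,
        }
        results["curation_reports"] = reports

        stage = "dnds"
        dnds_rows = []
        cluster_by_id = {c.cluster_id: c for c in clusters}
        for report in reports:
            c = cluster_by_id[report.cluster_id]
            ref_gene = gene_map[report.reference_member]
            spans_all = len(set(c.genome_ids)) == n_genomes
            gene_class = (
                "MHC" if is_mhc(ref_gene, cfg["min_hemes"])
                else ("core" if spans_all else "accessory")
            )
            for gid in report.kept:
                if gid == report.reference_member:
                    continue
                member = gene_map[gid]
                r = estimate_dnds_cds(
                    ref_gene.cds, member.cds,
                    id_a=ref_gene.gene_id, id_b=gid,
                )
                dnds_rows.append(
                    {
                        "cluster_id": c.cluster_id,
                        "genome_id": member.genome_id,
                        "gene_id": gid,
                        "gene_class": gene_class,
                        "localization": member.localization,
                        "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                        "dS": r.dS, "dN": r.dN, "omega": r.omega,
                        "status": r.status,
                    }
                )
        dnds = pd.DataFrame(dnds_rows)
        write_tsv(dnds, outdir / "dnds.tsv")
        manifest["stages"]["dnds"] = {
            "n_comparisons": len(dnds),
            "n_missing_omega": int(dnds["omega"].isna().sum())
            if len(dnds) else 0,
        }
        results["dnds"] = dnds

        stage = "stats"
        stats_rows = []
        for genome_id in sorted(genomes):
            if genome_id == reference:
                continue
            tr = compare_core_vs_mhc(dnds, genome_id, alpha=cfg["alpha"])
            stats_rows.append(
                {
                    "genome_id": genome_id, "test": tr.test,
                    "transformed": tr.transformed, "p": tr.p,
                    "tier": tr.tier, "n_core": tr.n_a, "n_mhc": tr.n_b,
                    "n_dropped_nonpositive": tr.n_dropped_nonpositive,
                    "status": tr.status,
                }
            )
        stats_table = pd.DataFrame(stats_rows)
        write_tsv(stats_table, outdir / "stats.tsv")
        if len(dnds):
            loc = compare_by_localization(
                dnds[dnds["localization"] != "unknown"]
                if (dnds["localization"] != "unknown").sum() else dnds,
                alpha=cfg["alpha"],
            )
            write_tsv(loc.pairwise, outdir / "localization_pairwise.tsv")
            results["localization"] = loc
        n_sig = sum(1 for r in stats_rows if r["tier"] != "ns")
        manifest["stages"]["stats"] = {
            "n_genomes_tested": len(stats_rows),
            "n_significant": n_sig,
        }
        results["stats"] = stats_table

        stage = "pangenome"
        mhc_ids = set(mhc_table.loc[mhc_table["is_mhc"], "gene_id"])
        mhc_by_genome = {
            gid: [g for g in genomes[gid] if g.gene_id in mhc_ids]
            for gid in genomes
        }
        mhc_nodes = [g.gene_id for gs in mhc_by_genome.values() for g in gs]
        if len(mhc_nodes) >= 2:
            mhc_graph = graph.subgraph(mhc_nodes)
            mhc_clusters = mcl_cluster(mhc_graph, inflation=cparams.inflation)
            spectrum = cluster_spectrum(
                mhc_clusters, bin10_inclusive=cfg["bin10_inclusive"]
            )
            spec_rows = [
                {
                    "cluster_id": cid, "n_genomes": n,
                    "bin": ("1" if n <= 1 else
                            "2-9" if n < (10 if cfg["bin10_inclusive"] else 11)
                            else ">=10"),
                }
                for cid, n in spectrum.genome_counts.items()
            ]
            write_tsv(pd.DataFrame(spec_rows), outdir / "spectrum.tsv")
            curve = accumulation_curve(
                mhc_by_genome, tree, reference, cparams, graph=mhc_graph
            )
            write_tsv(curve.to_frame(), outdir / "curve.tsv")
            manifest["stages"]["pangenome"] = {
                "n_mhc_clusters": len(mhc_clusters),
                "spectrum_bins": spectrum.bin_counts,
                "final_total": curve.n_clusters_total[-1],
                "final_shared": curve.n_clusters_shared[-1],
            }
            results["spectrum"] = spectrum
            results["curve"] = curve
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    results["manifest"] = manifest
    return results
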