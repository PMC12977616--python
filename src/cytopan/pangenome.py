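"""Cluster-size spectra and phylogenetic-distance-ordered accumulation.

The two figures of merit for an expanding gene pool: (i) the spectrum of
homolog cluster sizes (how many genomes carry each family, binned into
singletons, 2-9 genomes, and >=10 genomes), and (ii) the accumulation
curve obtained by adding genomes one at a time in order of patristic
distance from the reference and re-clustering from scratch at each
step.  A pool fed by per-genome unique genes keeps rising; counting
only clusters found in two or more genomes restores saturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

from .errors import InvalidParameterError, MissingLeafError
from .homolog_cluster import (
    ClusterParams,
    HomologCluster,
    build_graph,
    mcl_cluster,
)
from .mhc_detect import GeneRecord


def patristic_distance(
    tree: dendropy.Tree, reference_leaf: str, leaf: str
) -> float:
    """Sum of branch lengths on the path between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for name in (reference_leaf, leaf):
        if name not in taxa:
            raise MissingLeafError(f"leaf {name!r} not in tree")
    return float(pdm.patristic_distance(taxa[reference_leaf], taxa[leaf]))


def distances_from(
    tree: dendropy.Tree, reference_leaf: str
) -> dict[str, float]:
    """Patristic distance of every leaf from the reference leaf."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label}
    if reference_leaf not in taxa:
        raise MissingLeafError(f"leaf {reference_leaf!r} not in tree")
    ref = taxa[reference_leaf]
    return {
        label: (0.0 if label == reference_leaf
                else float(pdm.patristic_distance(ref, t)))
        for label, t in taxa.items()
    }


@dataclass
class ClusterSpectrum:
    """Per-cluster genome counts binned as {1}, {2-9}, {>=10}."""

    genome_counts: dict[str, int]
    bin_counts: dict[str, int]
    proportions: dict[str, float]
    bin10_inclusive: bool = True

    BINS = ("1", "2-9", ">=10")


def cluster_spectrum(
    clusters: Sequence[HomologCluster],
    bin10_inclusive: bool = True,
) -> ClusterSpectrum:
    """Bin clusters by the number of distinct genomes represented.

    ``bin10_inclusive`` places clusters spanning exactly 10 genomes in
    the top bin (the default convention); the alternative reading
    (top bin strictly more than 10) widens the middle bin to 2-10.
    """
    cutoff = 10 if bin10_inclusive else 11
    genome_counts = {c.cluster_id: len(c.genomes) for c in clusters}
    bins = {"1": 0, "2-9": 0, ">=10": 0}
    for n in genome_counts.values():
        if n <= 1:
            bins["1"] += 1
        elif n < cutoff:
            bins["2-9"] += 1
        else:
            bins[">=10"] += 1
    total = len(genome_counts) or 1
    proportions = {k: v / total for k, v in bins.items()}
    return ClusterSpectrum(
        genome_counts=genome_counts,
        bin_counts=bins,
        proportions=proportions,
        bin10_inclusive=bin10_inclusive,
    )


@dataclass
class AccumulationCurve:
    """Genomes in order of patristic distance from the reference, with
    cumulative cluster counts (all clusters / clusters in >=2 genomes)."""

    genome_ids: list[str]
    distances: list[float]
    n_clusters_total: list[int]
    n_clusters_shared: list[int]
    tie_flags: list[bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.genome_ids) + 1),
                "genome_id": self.genome_ids,
                "distance": self.distances,
                "n_clusters_total": self.n_clusters_total,
                "n_clusters_shared": self.n_clusters_shared,
                "distance_tie": self.tie_flags,
            }
        )


def order_by_distance(
    genome_ids: Sequence[str],
    tree: dendropy.Tree,
    reference: str,
) -> tuple[list[str], list[float], list[bool]]:
    """Reference first, then genomes by increasing patristic distance;
    ties broken lexicographically and flagged."""
    if reference not in genome_ids:
        raise InvalidParameterError(
            f"reference genome {reference!r} not among inputs"
        )
    dist = distances_from(tree, reference)
    missing = [g for g in genome_ids if g not in dist]
    if missing:
        raise MissingLeafError(f"genomes not on tree: {missing}")
    ordered = sorted(genome_ids, key=lambda g: (dist[g], g))
    distances = [dist[g] for g in ordered]
    flags = [
        (i > 0 and distances[i] == distances[i - 1])
        or (i + 1 < len(ordered) and distances[i] == distances[i + 1])
        for i in range(len(ordered))
    ]
    return ordered, distances, flags


def accumulation_curve(
    genes_by_genome: Mapping[str, Sequence[GeneRecord]],
    tree: dendropy.Tree,
    reference: str,
    params: ClusterParams | None = None,
    graph: nx.Graph | None = None,
) -> AccumulationCurve:
    """Accumulation of homolog clusters with genomes added in order of
    patristic distance from the reference.

    The clustering is recomputed from scratch at every step on the
    genomes accumulated so far.  Pairwise similarities do not depend on
    which genomes are present, so the all-vs-all graph is built once and
    each step runs MCL on the induced subgraph — identical to
    re-running the whole stage per step.  A prebuilt ``graph`` may be
    passed to reuse alignments across analyses.
    """
    params = params or ClusterParams()
    genome_ids = sorted(genes_by_genome)
    ordered, distances, flags = order_by_distance(genome_ids, tree, reference)
    if graph is None:
        all_genes = [g for gid in genome_ids for g in genes_by_genome[gid]]
        graph = build_graph(all_genes, params)
    totals: list[int] = []
    shared: list[int] = []
    so_far: list[str] = []
    for genome in ordered:
        so_far.append(genome)
        node_set = [
            g.gene_id for gid in so_far for g in genes_by_genome[gid]
        ]
        if not node_set:
            totals.append(0)
            shared.append(0)
            continue
        sub = graph.subgraph(node_set)
        clusters = mcl_cluster(sub, inflation=params.inflation)
        totals.append(len(clusters))
        shared.append(sum(1 for c in clusters if len(c.genomes) >= 2))
    return AccumulationCurve(
        genome_ids=ordered,
        distances=distances,
        n_clusters_total=totals,
        n_clusters_shared=shared,
        tie_flags=flags,
    )
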