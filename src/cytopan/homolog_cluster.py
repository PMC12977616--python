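"""All-vs-all protein similarity, Markov clustering and bidirectional
best hits — an OrthoMCL-style homolog-calling stage at desk scale.

BLASTP is replaced by exact global alignment under BLOSUM62 with affine
gaps (open 11, extend 1); edge weights are alignment scores normalized
by the smaller of the two self-scores, a bounded monotone surrogate for
bitscore normalization.  The similarity graph is partitioned with the
Markov Cluster (MCL) algorithm, whose inflation parameter controls
clustering stringency (1 = loosest, 5 = most stringent in the
three-point stringency sweep used throughout the pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidParameterError, InvalidSequenceError
from .mhc_detect import GeneRecord

#: the stringency sweep used for robustness checks
INFLATION_SWEEP = (1.0, 1.5, 5.0)


@dataclass(frozen=True)
class ClusterParams:
    inflation: float = 1.5
    edge_threshold: float = 0.3
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.inflation < 1.0:
            raise InvalidParameterError("inflation must be >= 1")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise InvalidParameterError("edge_threshold must be in [0, 1]")


@dataclass
class HomologCluster:
    """A set of genes grouped as homologs (one MCL cluster)."""

    cluster_id: str
    gene_ids: tuple[str, ...]
    genome_ids: tuple[str, ...]
    reference_member: str | None = None

    def __post_init__(self):
        if not self.gene_ids:
            raise InvalidParameterError("cluster must have members")

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(self.genome_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


def _make_aligner(params: ClusterParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


_DEFAULT_PARAMS = ClusterParams()


def _check_residues(seq: str, aligner: Align.PairwiseAligner) -> None:
    bad = set(seq) - set(aligner.substitution_matrix.alphabet)
    if bad:
        raise InvalidSequenceError(f"invalid residues {sorted(bad)}")


def pairwise_similarity(
    protein_a: str,
    protein_b: str,
    params: ClusterParams = _DEFAULT_PARAMS,
) -> tuple[float, float]:
    """Global alignment score and percent identity of two proteins.

    Identity is computed over aligned columns where neither sequence is
    gapped.  Symmetric in its arguments.
    """
    if not protein_a or not protein_b:
        raise InvalidSequenceError("empty protein sequence")
    aligner = _make_aligner(params)
    _check_residues(protein_a, aligner)
    _check_residues(protein_b, aligner)
    aln = aligner.align(protein_a, protein_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = cols = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    identity = 100.0 * matches / cols if cols else 0.0
    return float(aln.score), identity


def alignment_score(
    protein_a: str,
    protein_b: str,
    aligner: Align.PairwiseAligner,
) -> float:
    """Score-only fast path (no traceback)."""
    return float(aligner.score(protein_a, protein_b))


def build_graph(
    genes: Sequence[GeneRecord],
    params: ClusterParams = _DEFAULT_PARAMS,
) -> nx.Graph:
    """All-vs-all normalized similarity graph.

    Edge weight = score(a, b) / min(selfscore(a), selfscore(b)), clipped
    to [0, 1]; edges below ``edge_threshold`` are dropped.  Every gene
    is a node (isolated genes included), carrying its genome id.
    """
    if len(genes) < 2:
        raise InvalidParameterError("need at least 2 genes to build a graph")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("duplicate gene ids in input")
    aligner = _make_aligner(params)
    for g in genes:
        _check_residues(g.protein, aligner)
    graph = nx.Graph()
    self_scores = {}
    for g in genes:
        s = alignment_score(g.protein, g.protein, aligner)
        self_scores[g.gene_id] = s
        graph.add_node(g.gene_id, genome_id=g.genome_id, self_score=s)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            denom = min(self_scores[a.gene_id], self_scores[b.gene_id])
            if denom <= 0:
                continue
            raw = alignment_score(a.protein, b.protein, aligner)
            w = min(1.0, max(0.0, raw / denom))
            if w >= params.edge_threshold:
                graph.add_edge(a.gene_id, b.gene_id, weight=w)
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    prune_threshold: float = 1e-6,
    convergence: float = 1e-8,
    max_iterations: int = 200,
) -> list[HomologCluster]:
    """Partition a similarity graph with the Markov Cluster algorithm.

    Self-loops are set to each node's maximum incident edge weight
    (standard regularization; 1.0 for isolated nodes), columns are
    normalized to stochastic form, and expansion (matrix squaring) is
    alternated with inflation (elementwise power + renormalization) and
    pruning until the matrix change falls below ``convergence``.
    Clusters are read off attractor rows; the result is always a
    partition of the node set, and disconnected components are never
    merged (MCL cannot create probability flow between components).
    """
    if inflation < 1.0:
        raise InvalidParameterError("inflation must be >= 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise InvalidParameterError("empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    loop = m.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iterations):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune_threshold] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        inflated /= colsums
        if np.abs(inflated - m).max() < convergence:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iterations} iterations; "
            "emitting the current partition",
            RuntimeWarning,
            stacklevel=2,
        )

    # attractors have mass on their own diagonal; each attractor row
    # lists its cluster members.  Overlapping rows are merged so the
    # result is a strict partition.
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    assigned = np.zeros(n, dtype=bool)
    for i in attractors:
        members = np.nonzero(m[i] > prune_threshold)[0]
        for j in members:
            union(j, i)
            assigned[j] = True
    # numerically orphaned nodes attach to their strongest column entry
    for j in range(n):
        if not assigned[j]:
            i = int(np.argmax(m[:, j]))
            union(j, i)

    groups: dict[int, list[str]] = {}
    for i, node in enumerate(nodes):
        groups.setdefault(find(i), []).append(node)
    clusters = []
    for k, members in enumerate(
        sorted(groups.values(), key=lambda ms: ms[0])
    ):
        members = sorted(members)
        clusters.append(
            HomologCluster(
                cluster_id=f"C{k:05d}",
                gene_ids=tuple(members),
                genome_ids=tuple(
                    graph.nodes[g].get("genome_id", "?") for g in members
                ),
            )
        )
    return clusters


@dataclass(frozen=True)
class BBHPair:
    gene_a: str
    gene_b: str
    weight: float
    tie: bool = False


def bidirectional_best_hit(
    genome_a: str,
    genome_b: str,
    graph: nx.Graph,
) -> list[BBHPair]:
    """Ortholog pairs by bidirectional best hit on the similarity graph.

    (x, y) is reported when y is x's best-weight partner among genome_b
    genes and x is y's among genome_a genes.  Score ties are broken
    lexicographically by gene id and flagged.
    """
    genes_a = sorted(
        n for n, d in graph.nodes(data=True) if d.get("genome_id") == genome_a
    )
    genes_b = sorted(
        n for n, d in graph.nodes(data=True) if d.get("genome_id") == genome_b
    )
    if not genes_a or not genes_b:
        raise InvalidParameterError("both genomes need at least one gene")

    def best_partner(gene: str, pool: set[str]) -> tuple[str, float, bool] | None:
        cands = [
            (nbr, graph.edges[gene, nbr]["weight"])
            for nbr in graph.neighbors(gene)
            if nbr in pool
        ]
        if not cands:
            return None
        top = max(w for _, w in cands)
        tied = sorted(nbr for nbr, w in cands if w == top)
        return tied[0], top, len(tied) > 1

    pool_a, pool_b = set(genes_a), set(genes_b)
    best_ab = {g: best_partner(g, pool_b) for g in genes_a}
    best_ba = {g: best_partner(g, pool_a) for g in genes_b}
    pairs = []
    for x in genes_a:
        hit = best_ab[x]
        if hit is None:
            continue
        y, w, tie_x = hit
        back = best_ba[y]
        if back is not None and back[0] == x:
            pairs.append(BBHPair(x, y, w, tie=tie_x or back[2]))
    return pairs


def transfer_annotations(
    reference_names: dict[str, str],
    bbh_pairs: Iterable[BBHPair],
    target_gene_order: Sequence[str],
) -> dict[str, str]:
    """Copy reference gene names to targets through BBH pairs.

    When k > 1 target genes best-hit reference genes bearing one name,
    they become ``<name>_1 .. _k`` in target gene order — the failure
    mode that turns paralogous periplasmic cytochromes into arbitrary
    suffixed annotations.  Targets without a hit are "hypothetical".
    """
    hit_name: dict[str, str] = {}
    for p in bbh_pairs:
        ref, tgt = (
            (p.gene_a, p.gene_b)
            if p.gene_a in reference_names
            else (p.gene_b, p.gene_a)
        )
        if ref in reference_names:
            hit_name[tgt] = reference_names[ref]
    by_name: dict[str, list[str]] = {}
    for tgt in target_gene_order:
        if tgt in hit_name:
            by_name.setdefault(hit_name[tgt], []).append(tgt)
    names: dict[str, str] = {}
    for name, targets in by_name.items():
        if len(targets) == 1:
            names[targets[0]] = name
        else:
            for i, tgt in enumerate(targets, start=1):
                names[tgt] = f"{name}_{i}"
    for tgt in target_gene_order:
        names.setdefault(tgt, "hypothetical")
    return names


def clusters_to_rows(
    clusters: Iterable[HomologCluster],
) -> list[dict]:
    rows = []
    for c in clusters:
        for gid, genome in zip(c.gene_ids, c.genome_ids):
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "gene_id": gid,
                    "genome_id": genome,
                    "is_reference_member": gid == c.reference_member,
                }
            )
    return rows
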