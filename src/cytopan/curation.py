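"""Cluster curation for safe ortholog comparisons.

Before pairwise dN/dS is computed against the reference genome, each
homolog cluster containing a reference sequence is filtered: members
must be within 20% of the reference protein length and carry a heme
count within +/-2 of the reference; genomes contributing several
surviving members (candidate paralogs) are resolved by local gene-order
(synteny) support, keeping the unique member whose neighborhood matches
the reference neighborhood, or dropping the genome's members entirely
when no unique candidate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import InvalidParameterError
from .homolog_cluster import HomologCluster
from .mhc_detect import GeneRecord

KEPT = "kept"
REMOVED_LENGTH = "removed_length"
REMOVED_HEMES = "removed_hemes"
REMOVED_PARALOG = "removed_unresolved_paralog"


@dataclass
class CurationReport:
    """Per-gene curation status for one cluster."""

    cluster_id: str
    reference_member: str
    status: dict[str, str]
    length_tol: float
    heme_tol: int
    min_support: int | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return sorted(g for g, s in self.status.items() if s == KEPT)


def curate_cluster(
    cluster: HomologCluster,
    genes: Mapping[str, GeneRecord],
    reference_member: str,
    length_tol: float = 0.20,
    heme_tol: int = 2,
) -> CurationReport:
    """Apply the length and heme-count rules relative to the reference.

    A member is kept iff |len - len_ref| <= length_tol * len_ref and
    |hemes - hemes_ref| <= heme_tol.  The reference member itself is
    always kept.  Length is checked first, so a member failing both
    rules is recorded as removed for length.
    """
    if reference_member not in cluster.gene_ids:
        raise InvalidParameterError(
            f"reference member {reference_member} absent from cluster "
            f"{cluster.cluster_id}"
        )
    ref = genes[reference_member]
    len_ref = len(ref.protein)
    status: dict[str, str] = {}
    for gid in cluster.gene_ids:
        if gid == reference_member:
            status[gid] = KEPT
            continue
        g = genes[gid]
        if abs(len(g.protein) - len_ref) > length_tol * len_ref:
            status[gid] = REMOVED_LENGTH
        elif abs(g.heme_count - ref.heme_count) > heme_tol:
            status[gid] = REMOVED_HEMES
        else:
            status[gid] = KEPT
    return CurationReport(
        cluster_id=cluster.cluster_id,
        reference_member=reference_member,
        status=status,
        length_tol=length_tol,
        heme_tol=heme_tol,
    )


def synteny_support(
    gene_id: str,
    ref_gene_id: str,
    gene_orders: Mapping[str, Sequence[str]],
    gene_to_genome: Mapping[str, str],
    cluster_of: Mapping[str, str],
    window: int = 3,
) -> tuple[int, int]:
    """Count conserved flanking positions between a gene and the
    reference gene.

    Each of the up-to-2*window flanking positions of ``gene`` counts as
    supported when its gene's homolog cluster also occurs among the
    reference gene's flanking window (gene-order insertions and
    deletions shift offsets, so matching is against the whole reference
    window rather than the offset-identical position).  Returns
    (support, denominator); the denominator is the number of existing
    flank positions of ``gene`` (truncated at contig edges).
    """
    order_g = gene_orders[gene_to_genome[gene_id]]
    order_r = gene_orders[gene_to_genome[ref_gene_id]]
    pos_g = order_g.index(gene_id)
    pos_r = order_r.index(ref_gene_id)
    ref_flank_clusters = set()
    for off in range(-window, window + 1):
        if off == 0:
            continue
        ir = pos_r + off
        if 0 <= ir < len(order_r):
            c = cluster_of.get(order_r[ir])
            if c is not None:
                ref_flank_clusters.add(c)
    support = denom = 0
    for off in range(-window, window + 1):
        if off == 0:
            continue
        ig = pos_g + off
        if not 0 <= ig < len(order_g):
            continue
        denom += 1
        cg = cluster_of.get(order_g[ig])
        if cg is not None and cg in ref_flank_clusters:
            support += 1
    return support, denom


def resolve_paralogs(
    report: CurationReport,
    genes: Mapping[str, GeneRecord],
    synteny_supports: Mapping[str, int],
    min_support: int = 2,
) -> CurationReport:
    """Resolve genomes with multiple kept members using synteny support.

    For each genome with more than one kept member, the unique member
    with support >= ``min_support`` is kept if exactly one qualifies;
    otherwise all that genome's members are removed (unresolved
    paralogs).  The reference member is exempt.  Idempotent: a second
    application changes nothing, since surviving genomes have one
    member.
    """
    by_genome: dict[str, list[str]] = {}
    for gid, s in report.status.items():
        if s != KEPT or gid == report.reference_member:
            continue
        by_genome.setdefault(genes[gid].genome_id, []).append(gid)
    for genome, members in sorted(by_genome.items()):
        if len(members) <= 1:
            continue
        qualified = [
            g for g in sorted(members)
            if synteny_supports.get(g, 0) >= min_support
        ]
        if len(qualified) == 1:
            for g in members:
                if g != qualified[0]:
                    report.status[g] = REMOVED_PARALOG
        else:
            for g in members:
                report.status[g] = REMOVED_PARALOG
            report.notes.append(
                f"{genome}: {len(members)} unresolved paralogs removed"
            )
    report.min_support = min_support
    return report


def curate(
    cluster: HomologCluster,
    genes: Mapping[str, GeneRecord],
    reference_member: str,
    gene_orders: Mapping[str, Sequence[str]] | None = None,
    cluster_of: Mapping[str, str] | None = None,
    length_tol: float = 0.20,
    heme_tol: int = 2,
    window: int = 3,
    min_support: int = 2,
) -> CurationReport:
    """Full curation: length/heme filters, then paralog resolution.

    When gene orders are unavailable, paralog resolution falls back to
    zero synteny support, i.e. every multi-member genome is dropped.
    """
    report = curate_cluster(
        cluster, genes, reference_member, length_tol=length_tol,
        heme_tol=heme_tol,
    )
    gene_to_genome = {gid: genes[gid].genome_id for gid in cluster.gene_ids}
    supports: dict[str, int] = {}
    if gene_orders is not None and cluster_of is not None:
        for gid in report.kept:
            if gid == reference_member:
                continue
            try:
                supports[gid], _ = synteny_support(
                    gid, reference_member, gene_orders, gene_to_genome,
                    cluster_of, window=window,
                )
            except (KeyError, ValueError):
                supports[gid] = 0
    return resolve_paralogs(report, genes, supports, min_support=min_support)
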