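"""Tree-structured synthetic pangenomes with planted selection strengths.

The generator emulates the salient features of a clade of metal-reducing
bacteria: a genome phylogeny; "core" gene families present in every
genome under strong purifying selection; accessory multiheme-cytochrome
(MHC) families carrying 2-12 CXXCH heme motifs, evolving under weaker
constraint and subject to per-genome loss and duplication; and fresh
singleton genes unique to single genomes.  Every downstream stage of the
pipeline (motif detection, clustering, curation, dN/dS, pangenome
curves, profile scoring, statistics) can therefore be exercised against
a known truth table without any external genome download.

Selection is modeled as a proposal/acceptance process on point
mutations: proposals are Poisson in the branch length, synonymous
changes are accepted with probability min(1, 1/omega) and nonsynonymous
ones with min(1, omega), so the realized dN/dS equals the planted omega
by construction when the transition/transversion proposal ratio kappa
is 1.  Heme-motif codons are locked (immutable), so motif counts survive
evolution exactly.  There are no indels: all members of a family share
the ancestor's length.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidSequenceError
from .genetic_code import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    TRANSITION,
    codons_of,
    translate_cds,
)
from .mhc_detect import (
    DEFAULT_PATTERNS,
    GeneRecord,
    count_heme_motifs,
    make_gene_record,
)

HEME_PATTERN = "CxxCH"

#: minimum codons per planted heme motif.  Real multiheme cytochromes
#: run from ~1 heme per 25 residues (peptide-minimized triheme carriers)
#: upward, so one motif per 15 codons is a dense but realistic packing;
#: it keeps unrelated motif-bearing genes from being dominated by
#: shared motif residues.
HEME_SPACING_CODONS = 15

#: planted localization -> selection-strength class
LOCALIZATION_TO_OMEGA_CLASS = {
    "IM": "low",            # inner-membrane quinone oxidoreductases
    "periplasm": "mid",     # complexed/enzymatic periplasmic cytochromes
    "ppc": "high",          # free periplasmic triheme-like carriers
    "OM_ext": "high",       # outer-surface / extracellular cytochromes
}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic pangenome.

    ``divergence`` is the expected number of proposed point mutations
    per nucleotide site from root to tip; planted omegas are the
    acceptance-ratio selection strengths for the three localization
    classes plus the core genome.
    """

    n_genomes: int = 12
    n_core: int = 30
    n_accessory: int = 20
    presence_prob: float = 0.6
    singleton_rate: float = 5.0
    dup_prob: float = 0.1
    omega_core: float = 0.1
    omega_mhc_low: float = 0.1
    omega_mhc_mid: float = 0.5
    omega_mhc_high: float = 1.0
    kappa: float = 1.0
    divergence: float = 0.2
    gene_length_codons: tuple[int, int] = (60, 150)
    heme_motifs_per_mhc: tuple[int, int] = (2, 12)
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 2:
            raise InvalidParameterError("n_genomes must be >= 2")
        for name in ("presence_prob", "dup_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        for name in (
            "omega_core",
            "omega_mhc_low",
            "omega_mhc_mid",
            "omega_mhc_high",
            "kappa",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.singleton_rate < 0 or self.divergence < 0:
            raise InvalidParameterError("rates must be non-negative")
        lo, hi = self.gene_length_codons
        if lo < 30 or hi < lo:
            raise InvalidParameterError("gene length range must be >= 30 codons")
        mlo, mhi = self.heme_motifs_per_mhc
        if mlo < 1 or mhi < mlo:
            raise InvalidParameterError("bad heme motif range")

    def omega_for_class(self, omega_class: str) -> float:
        return {
            "core": self.omega_core,
            "low": self.omega_mhc_low,
            "mid": self.omega_mhc_mid,
            "high": self.omega_mhc_high,
        }[omega_class]


@dataclass
class SimulatedPangenome:
    """Output bundle: genomes, tree, gene orders and the truth table."""

    genomes: dict[str, list[GeneRecord]]
    tree: dendropy.Tree
    gene_orders: dict[str, list[str]]
    truth: pd.DataFrame
    params: SimParams

    def all_genes(self) -> list[GeneRecord]:
        return [g for genome in self.genomes.values() for g in genome]


def simulate_tree(
    n_genomes: int, seed: int, divergence: float = 0.2
) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) genome tree and rescale its branch
    lengths so the mean root-to-tip depth equals ``divergence``.

    The process starts with two lineages at the root; waiting times
    between birth events are exponential with rate equal to the number
    of extant lineages, and a final exponential waiting time is appended
    after the last split so terminal branches have positive length.
    Pure-birth trees are ultrametric, so after rescaling every tip sits
    at depth ``divergence`` exactly.  Leaves are labeled g01, g02, ...
    """
    if n_genomes < 2:
        raise InvalidParameterError("need at least 2 genomes for a tree")
    rng = np.random.default_rng(int(seed))
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # (node, birth_time) of each extant lineage
    active: list[tuple[dendropy.Node, float]] = [
        (root.new_child(), 0.0),
        (root.new_child(), 0.0),
    ]
    t = 0.0
    while len(active) < n_genomes:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node, born = active.pop(int(rng.integers(k)))
        node.edge.length = t - born
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / n_genomes)
    factor = divergence / t_end if t_end > 0 else 1.0
    for node, born in active:
        node.edge.length = t_end - born
    width = max(2, len(str(n_genomes)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"g{i:0{width}d}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def evolve_cds(
    ancestor_cds: str,
    branch_length: float,
    omega: float,
    kappa: float = 1.0,
    locked_positions: frozenset[int] | set[int] = frozenset(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    preserve_motif_patterns: tuple[str, ...] | None = None,
) -> str:
    """Evolve a CDS along one branch under proposal/acceptance selection.

    Poisson(branch_length x length) point mutations are proposed; each
    picks a uniform site and an alternative base (the transition partner
    weighted ``kappa`` against the two transversions).  Proposals that
    touch a locked position or would create a stop codon are rejected
    outright; synonymous proposals are accepted with probability
    min(1, 1/omega) and nonsynonymous ones with min(1, omega).  When
    ``preserve_motif_patterns`` is given, nonsynonymous proposals that
    would change the protein's heme-motif count are also rejected, so
    planted motif counts are exact invariants of evolution.

    Returns a CDS of identical length with no internal stop codons and
    locked positions untouched.
    """
    ancestor_cds = ancestor_cds.upper()
    if len(ancestor_cds) % 3 != 0:
        raise InvalidSequenceError("ancestor CDS length not a multiple of 3")
    # raises InvalidSequenceError on internal stops:
    protein = translate_cds(ancestor_cds, allow_terminal_stop=False)
    if branch_length < 0:
        raise InvalidParameterError("branch_length must be >= 0")
    if omega <= 0 or kappa <= 0:
        raise InvalidParameterError("omega and kappa must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    seq = list(ancestor_cds)
    prot = list(protein)
    n_sites = len(seq)
    locked = frozenset(locked_positions)
    if preserve_motif_patterns:
        motif_count = count_heme_motifs(protein, preserve_motif_patterns)

    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)

    n_proposals = rng.poisson(branch_length * n_sites)
    for _ in range(n_proposals):
        site = int(rng.integers(n_sites))
        if site in locked:
            continue
        old = seq[site]
        ts = TRANSITION[old]
        tvs = [b for b in BASES if b != old and b != ts]
        total = kappa + 2.0
        u = rng.random() * total
        new = ts if u < kappa else tvs[0] if u < kappa + 1.0 else tvs[1]
        ci = site // 3
        codon = seq[3 * ci : 3 * ci + 3]
        codon[site % 3] = new
        new_codon = "".join(codon)
        if new_codon in STOP_CODONS:
            continue
        new_aa = CODON_TO_AA[new_codon]
        synonymous = new_aa == prot[ci]
        accept_p = p_syn if synonymous else p_non
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        if not synonymous and preserve_motif_patterns:
            candidate = prot.copy()
            candidate[ci] = new_aa
            if (
                count_heme_motifs("".join(candidate), preserve_motif_patterns)
                != motif_count
            ):
                continue
        seq[site] = new
        prot[ci] = new_aa
    return "".join(seq)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A uniform-random stop-free CDS of ``n_codons`` codons."""
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _plant_motifs(
    cds: str, n_motifs: int, rng: np.random.Generator
) -> tuple[str, frozenset[int]]:
    """Overwrite ``n_motifs`` non-overlapping 5-codon CXXCH motifs at
    random codon positions; returns the new CDS and the locked
    nucleotide positions (the C, C and H codons of each motif)."""
    n_codons = len(cds) // 3
    if n_motifs * 5 > n_codons:
        raise InvalidParameterError(
            f"{n_motifs} motifs do not fit in {n_codons} codons"
        )
    # sample non-overlapping start codons by sequential rejection
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_motifs:
        cand = int(rng.integers(n_codons - 4))
        if all(abs(cand - s) >= 5 for s in starts):
            starts.append(cand)
        attempts += 1
        if attempts > 10000:  # fall back to a deterministic packing
            starts = [5 * i for i in range(n_motifs)]
            break
    starts.sort()
    cys = ("TGC", "TGT")
    his = ("CAC", "CAT")
    codons = codons_of(cds)
    locked: set[int] = set()
    for s in starts:
        codons[s] = cys[int(rng.integers(2))]
        codons[s + 1] = _random_x_codon(rng)
        codons[s + 2] = _random_x_codon(rng)
        codons[s + 3] = cys[int(rng.integers(2))]
        codons[s + 4] = his[int(rng.integers(2))]
        for ci in (s, s + 3, s + 4):
            locked.update(range(3 * ci, 3 * ci + 3))
    out = "".join(codons)
    # planted motifs must be the only ones (regenerate x-codons if a
    # chance motif appeared elsewhere is handled by the caller's count)
    return out, frozenset(locked)


def _random_x_codon(rng: np.random.Generator) -> str:
    return SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]


def make_mhc_ancestor(
    n_codons: int, n_motifs: int, rng: np.random.Generator
) -> tuple[str, frozenset[int]]:
    """Random stop-free ancestor carrying exactly ``n_motifs`` CXXCH
    motifs at locked positions."""
    for _ in range(200):
        cds, locked = _plant_motifs(random_cds(n_codons, rng), n_motifs, rng)
        if count_heme_motifs(translate_cds(cds), DEFAULT_PATTERNS) == n_motifs:
            return cds, locked
    raise RuntimeError("could not plant exact motif count")  # pragma: no cover


def _evolve_family_on_tree(
    tree: dendropy.Tree,
    ancestor: str,
    omega: float,
    kappa: float,
    locked: frozenset[int],
    rng: np.random.Generator,
    preserve_motifs: bool,
) -> dict[str, str]:
    """Evolve one gene family down the tree; returns leaf -> CDS."""
    patterns = DEFAULT_PATTERNS if preserve_motifs else None
    seqs: dict[int, str] = {id(tree.seed_node): ancestor}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        child_seq = evolve_cds(
            parent_seq,
            branch_length=bl,
            omega=omega,
            kappa=kappa,
            locked_positions=locked,
            rng=rng,
            preserve_motif_patterns=patterns,
        )
        seqs[id(node)] = child_seq
        if node.is_leaf():
            leaves[node.taxon.label] = child_seq
    return leaves


def simulate_pangenome(params: SimParams) -> SimulatedPangenome:
    """Simulate a full pangenome under ``params``.

    Core families (omega_core, no motifs) are present in every genome.
    Accessory MHC families carry locked CXXCH motifs, a planted
    localization and the matching omega class, and are retained per
    genome with ``presence_prob``; retained copies are duplicated with
    ``dup_prob`` (the paralog is re-evolved over half the root-to-tip
    divergence and placed at a random genome position).  Per genome,
    Poisson(``singleton_rate``) fresh motif-bearing genes are created de
    novo, emulating cytochromes without homologs in any other strain.
    """
    rng = np.random.default_rng(params.seed)
    tree_seed = int(rng.integers(2**31 - 1))
    tree = simulate_tree(params.n_genomes, tree_seed, params.divergence)
    genome_ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    lo_len, hi_len = params.gene_length_codons
    lo_h, hi_h = params.heme_motifs_per_mhc
    locs = ("IM", "periplasm", "ppc", "OM_ext")

    family_leaf_seqs: dict[str, dict[str, str]] = {}
    family_meta: dict[str, dict] = {}

    # --- core families: everywhere, no motifs, strong constraint
    for k in range(params.n_core):
        fam = f"core{k:04d}"
        n_codons = int(rng.integers(lo_len, hi_len + 1))
        ancestor = random_cds(n_codons, rng)
        family_leaf_seqs[fam] = _evolve_family_on_tree(
            tree, ancestor, params.omega_core, params.kappa,
            frozenset(), rng, preserve_motifs=False,
        )
        family_meta[fam] = {
            "omega_class": "core", "localization": "unknown",
            "locked": frozenset(), "present": set(genome_ids),
        }

    # --- accessory MHC families: motif-bearing, lost/retained per genome
    for k in range(params.n_accessory):
        fam = f"acc{k:04d}"
        localization = locs[k % len(locs)]
        omega_class = LOCALIZATION_TO_OMEGA_CLASS[localization]
        omega = params.omega_for_class(omega_class)
        n_codons = int(rng.integers(lo_len, hi_len + 1))
        n_motifs = min(
            int(rng.integers(lo_h, hi_h + 1)),
            max(lo_h, n_codons // HEME_SPACING_CODONS),
        )
        ancestor, locked = make_mhc_ancestor(n_codons, n_motifs, rng)
        leaf_seqs = _evolve_family_on_tree(
            tree, ancestor, omega, params.kappa, locked, rng,
            preserve_motifs=True,
        )
        present = {
            g for g in genome_ids if rng.random() < params.presence_prob
        }
        family_leaf_seqs[fam] = leaf_seqs
        family_meta[fam] = {
            "omega_class": omega_class, "localization": localization,
            "locked": locked, "present": present,
        }

    genomes: dict[str, list[GeneRecord]] = {g: [] for g in genome_ids}
    gene_orders: dict[str, list[str]] = {}
    rows: list[dict] = []
    family_order = [f"core{k:04d}" for k in range(params.n_core)] + [
        f"acc{k:04d}" for k in range(params.n_accessory)
    ]

    for genome in genome_ids:
        order: list[str] = []
        extras: list[GeneRecord] = []

        for fam in family_order:
            meta = family_meta[fam]
            if genome not in meta["present"]:
                continue
            cds = family_leaf_seqs[fam][genome]
            gid = f"{genome}|{fam}"
            rec = make_gene_record(
                gid, genome, cds, localization=meta["localization"]
            )
            genomes[genome].append(rec)
            order.append(gid)
            rows.append(
                {
                    "family_id": fam, "genome": genome, "gene_id": gid,
                    "omega_class": meta["omega_class"],
                    "localization": meta["localization"],
                    "is_singleton": False, "is_duplicate": False,
                }
            )
            # duplication: re-evolved paralog, relocated randomly
            if fam.startswith("acc") and rng.random() < params.dup_prob:
                dup_cds = evolve_cds(
                    cds,
                    branch_length=params.divergence / 2.0,
                    omega=params.omega_for_class(meta["omega_class"]),
                    kappa=params.kappa,
                    locked_positions=meta["locked"],
                    rng=rng,
                    preserve_motif_patterns=DEFAULT_PATTERNS,
                )
                dup_id = f"{genome}|{fam}|dup"
                extras.append(
                    make_gene_record(
                        dup_id, genome, dup_cds,
                        localization=meta["localization"],
                    )
                )
                rows.append(
                    {
                        "family_id": fam, "genome": genome, "gene_id": dup_id,
                        "omega_class": meta["omega_class"],
                        "localization": meta["localization"],
                        "is_singleton": False, "is_duplicate": True,
                    }
                )

        # de novo singletons, unique to this genome
        n_singletons = int(rng.poisson(params.singleton_rate))
        for s in range(n_singletons):
            n_codons = int(rng.integers(lo_len, hi_len + 1))
            n_motifs = min(
                int(rng.integers(lo_h, hi_h + 1)),
                max(lo_h, n_codons // HEME_SPACING_CODONS),
            )
            cds, _ = make_mhc_ancestor(n_codons, n_motifs, rng)
            sid = f"{genome}|sing{s:04d}"
            extras.append(make_gene_record(sid, genome, cds))
            rows.append(
                {
                    "family_id": f"{genome}|sing{s:04d}", "genome": genome,
                    "gene_id": sid, "omega_class": "high",
                    "localization": "unknown",
                    "is_singleton": True, "is_duplicate": False,
                }
            )

        # insert duplicates and singletons at random replicon positions
        for rec in extras:
            genomes[genome].append(rec)
            pos = int(rng.integers(len(order) + 1))
            order.insert(pos, rec.gene_id)
        gene_orders[genome] = order

    truth = pd.DataFrame(
        rows,
        columns=[
            "family_id", "genome", "gene_id", "omega_class",
            "localization", "is_singleton", "is_duplicate",
        ],
    )
    return SimulatedPangenome(
        genomes=genomes, tree=tree, gene_orders=gene_orders,
        truth=truth, params=params,
    )


def simulate_ortholog_paralog_pool(
    n_genomes: int = 12,
    n_paralogs_per_genome: int = 2,
    ortholog_branch: tuple[float, float] = (0.3, 1.0),
    paralog_branch: tuple[float, float] = (0.02, 0.3),
    omega: float = 1.0,
    n_codons: int = 85,
    n_motifs: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """A duplication-rich cytochrome pool: weakly constrained orthologs
    plus recent within-genome paralog duplicates.

    Emulates small, fast-evolving periplasmic triheme carriers: each
    genome holds one "authentic" ortholog evolved far from the common
    ancestor (branch length drawn from ``ortholog_branch``), plus
    paralogs that are *recent duplicates* of that ortholog (short
    branches from ``paralog_branch``).  Because a recent duplicate is a
    near-identical sister of a training sequence, a profile trained on
    the orthologs cannot draw a bitscore threshold that excludes the
    paralogs.  Returns (ortholog proteins, paralog proteins); all
    sequences share length and carry exactly ``n_motifs`` heme motifs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor, locked = make_mhc_ancestor(n_codons, n_motifs, rng)
    orthologs: list[str] = []
    paralogs: list[str] = []
    for _ in range(n_genomes):
        b = rng.uniform(*ortholog_branch)
        orth_cds = evolve_cds(
            ancestor, b, omega, locked_positions=locked, rng=rng,
            preserve_motif_patterns=DEFAULT_PATTERNS,
        )
        orthologs.append(translate_cds(orth_cds))
        for _ in range(n_paralogs_per_genome):
            d = rng.uniform(*paralog_branch)
            dup_cds = evolve_cds(
                orth_cds, d, omega, locked_positions=locked, rng=rng,
                preserve_motif_patterns=DEFAULT_PATTERNS,
            )
            paralogs.append(translate_cds(dup_cds))
    return orthologs, paralogs


def simulate_divergent_families(
    n_families: int = 4,
    members_per_family: int = 6,
    split_branch: float = 0.8,
    member_branch: float = 0.05,
    omega_split: float = 0.5,
    omega_member: float = 0.1,
    n_codons: int = 130,
    n_motifs: int = 6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[str]]:
    """Anciently diverged cytochrome families with tight membership.

    Emulates hexaheme nanowire-like families: paralog lineages split
    long ago (``split_branch``) but members within each family are
    recent and strongly constrained (``member_branch``,
    ``omega_member``), so a profile trained on one family separates it
    cleanly from the others.  Returns one protein list per family.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor, locked = make_mhc_ancestor(n_codons, n_motifs, rng)
    families: list[list[str]] = []
    for _ in range(n_families):
        fam_cds = evolve_cds(
            ancestor, split_branch, omega_split, locked_positions=locked,
            rng=rng, preserve_motif_patterns=DEFAULT_PATTERNS,
        )
        members = [
            translate_cds(
                evolve_cds(
                    fam_cds, member_branch, omega_member,
                    locked_positions=locked, rng=rng,
                    preserve_motif_patterns=DEFAULT_PATTERNS,
                )
            )
            for _ in range(members_per_family)
        ]
        families.append(members)
    return families


def evolve_pair(
    n_codons: int,
    branch_length: float,
    omega: float,
    rng: np.random.Generator,
    kappa: float = 1.0,
) -> tuple[str, str]:
    """Convenience: one random ancestor, two independently evolved
    descendant lineages (each of ``branch_length``).  The workhorse of
    omega-recovery calibration."""
    ancestor = random_cds(n_codons, rng)
    a = evolve_cds(ancestor, branch_length, omega, kappa=kappa, rng=rng)
    b = evolve_cds(ancestor, branch_length, omega, kappa=kappa, rng=rng)
    return a, b
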