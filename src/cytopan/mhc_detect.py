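"""Multiheme cytochrome (MHC) detection by heme-binding motif counting.

c-Type cytochromes attach heme covalently through the canonical CXXCH
motif (two cysteines that form thioether bonds and the histidine axial
ligand), so counting non-overlapping CXXCH occurrences in a protein is a
direct census of its heme-binding sites.  A protein with two or more
motifs is treated as a multiheme cytochrome.  Rarer CX3CH/CX4CH variants
exist in nature and can be enabled through the pattern set, but are
excluded by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidSequenceError
from .genetic_code import translate_cds

#: the twenty standard amino acids
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: canonical heme-attachment motif; x = any residue
DEFAULT_PATTERNS: tuple[str, ...] = ("CxxCH",)

#: extended set admitting one or two extra spacer residues
EXTENDED_PATTERNS: tuple[str, ...] = ("CxxCH", "CxxxCH", "CxxxxCH")

#: localization labels used throughout (unknown = unannotated)
LOCALIZATIONS = ("IM", "ppc", "periplasm", "OM_ext", "unknown")


def _pattern_to_regex(pattern: str) -> re.Pattern:
    if not re.fullmatch(r"[A-Zx]+", pattern):
        raise InvalidSequenceError(f"bad motif pattern {pattern!r}")
    return re.compile(pattern.replace("x", "[A-Z]"))


@dataclass
class GeneRecord:
    """One coding gene: CDS, protein, provenance and heme annotation.

    ``protein`` must be the translation of ``cds`` (terminal stop
    stripped); ``heme_count`` the motif count under the configured
    pattern set.  Use :func:`make_gene_record` to build consistently.
    """

    gene_id: str
    genome_id: str
    cds: str
    protein: str
    heme_count: int = 0
    localization: str = "unknown"
    name: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.localization not in LOCALIZATIONS:
            raise InvalidSequenceError(
                f"unknown localization {self.localization!r} for {self.gene_id}"
            )


def make_gene_record(
    gene_id: str,
    genome_id: str,
    cds: str,
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    localization: str = "unknown",
    name: str | None = None,
) -> GeneRecord:
    """Translate a CDS and annotate its heme-motif count in one step."""
    protein = translate_cds(cds)
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        cds=cds.upper(),
        protein=protein,
        heme_count=count_heme_motifs(protein, patterns),
        localization=localization,
        name=name,
    )


def count_heme_motifs(
    protein: str, patterns: Sequence[str] = DEFAULT_PATTERNS
) -> int:
    """Count non-overlapping, leftmost-first heme-binding motifs.

    The scan walks the sequence left to right; at each position the
    patterns are tried in the order given, the first match is counted,
    and the scan resumes past it.  Overlapping motifs are never counted
    twice: overlapping CXXCH sites cannot both ligate a heme.

    Raises
    ------
    InvalidSequenceError
        if ``protein`` contains characters outside the 20-letter
        amino-acid alphabet.
    """
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"non-amino-acid characters {sorted(bad)} in protein"
        )
    regexes = [_pattern_to_regex(p) for p in patterns]
    count = 0
    pos = 0
    n = len(protein)
    while pos < n:
        for rx in regexes:
            m = rx.match(protein, pos)
            if m:
                count += 1
                pos = m.end()
                break
        else:
            pos += 1
    return count


def is_mhc(gene: GeneRecord, min_hemes: int = 2) -> bool:
    """A gene is called a multiheme cytochrome iff it carries at least
    ``min_hemes`` heme-binding motifs (default 2: "multi")."""
    return gene.heme_count >= min_hemes


def select_family(
    genes: Iterable[GeneRecord],
    heme_count: int,
    ref_length: int,
    length_tol: float = 0.10,
) -> list[GeneRecord]:
    """Select candidate members of a cytochrome family by exact heme
    count and protein length within ``length_tol`` of a reference length
    (e.g. all hexaheme proteins within 10% of the reference nanowire
    subunit length)."""
    if ref_length <= 0:
        raise InvalidSequenceError("ref_length must be positive")
    if not 0 <= length_tol < 1:
        raise InvalidSequenceError("length_tol must be in [0, 1)")
    out = []
    for g in genes:
        if g.heme_count != heme_count:
            continue
        if abs(len(g.protein) - ref_length) <= length_tol * ref_length:
            out.append(g)
    return out


def detect_table(
    genes: Iterable[GeneRecord],
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    min_hemes: int = 2,
) -> pd.DataFrame:
    """Tabulate per-gene heme counts and MHC calls (CLI `detect` output)."""
    rows = []
    for g in genes:
        hc = count_heme_motifs(g.protein, patterns)
        rows.append(
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "length_aa": len(g.protein),
                "heme_count": hc,
                "is_mhc": hc >= min_hemes,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "length_aa", "heme_count", "is_mhc"]
    )
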