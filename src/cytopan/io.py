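"""Readers and writers for the pipeline's plain-text formats, plus the
genome-metadata quality filter.

Formats: FASTA (nucleotide and protein, 60-column wrap on write),
Newick trees (branch lengths preserved at full precision), TSV tables,
and axt pairwise codon alignments in the KaKs-Calculator dialect (one
``idA-idB`` header line, the two aligned nucleotide lines, and a blank
separator line).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_dnds import CodonAlignmentPair
from .errors import InvalidParameterError, ParseError
from .mhc_detect import GeneRecord, make_gene_record

FASTA_WIDTH = 60


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs; sequences uppercased, line
    endings normalized."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike
) -> None:
    """Write (id, sequence) pairs wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(seqrecords)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(
        path=str(path), schema="newick", unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )


def write_axt(
    pairs: Iterable[CodonAlignmentPair], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}-{p.id_b}\n{p.nt_a}\n{p.nt_b}\n\n")


def read_axt(path: str | os.PathLike) -> list[CodonAlignmentPair]:
    pairs = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    lineno = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        if i + 2 >= len(lines):
            raise ParseError("truncated axt record", line=i + 1)
        header = lines[i].strip()
        if "-" not in header:
            raise ParseError(f"bad axt header {header!r}", line=i + 1)
        id_a, _, id_b = header.partition("-")
        nt_a = lines[i + 1].strip().upper()
        nt_b = lines[i + 2].strip().upper()
        try:
            pairs.append(
                CodonAlignmentPair(id_a=id_a, id_b=id_b, nt_a=nt_a, nt_b=nt_b)
            )
        except Exception as e:
            raise ParseError(str(e), line=i + 2) from e
        i += 3
        lineno = i
    return pairs


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomes on disk

def read_genome(
    ffn_path: str | os.PathLike,
    genome_id: str | None = None,
    patterns: Sequence[str] = ("CxxCH",),
) -> list[GeneRecord]:
    """Load one genome's CDS FASTA into GeneRecords (translating and
    counting heme motifs).  The genome id defaults to the file stem.
    Duplicate gene ids are rejected."""
    genome_id = genome_id or Path(ffn_path).stem
    genes = []
    seen = set()
    for gid, cds in read_fasta(ffn_path):
        if gid in seen:
            raise InvalidParameterError(f"duplicate gene id {gid!r}")
        seen.add(gid)
        genes.append(make_gene_record(gid, genome_id, cds, patterns=patterns))
    return genes


def read_genome_dir(
    ffn_dir: str | os.PathLike, patterns: Sequence[str] = ("CxxCH",)
) -> dict[str, list[GeneRecord]]:
    """Load every ``*.ffn`` in a directory, keyed by file stem."""
    genomes = {}
    for path in sorted(Path(ffn_dir).glob("*.ffn")):
        genomes[path.stem] = read_genome(path, patterns=patterns)
    if not genomes:
        raise InvalidParameterError(f"no .ffn files in {ffn_dir}")
    return genomes


def write_pangenome(sim, outdir: str | os.PathLike) -> None:
    """Write a simulated pangenome: per-genome .ffn/.faa, tree.nwk,
    gene_order.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome_id, genes in sim.genomes.items():
        write_fasta(
            [(g.gene_id, g.cds) for g in genes], outdir / f"{genome_id}.ffn"
        )
        write_fasta(
            [(g.gene_id, g.protein) for g in genes],
            outdir / f"{genome_id}.faa",
        )
    write_newick(sim.tree, outdir / "tree.nwk")
    order_rows = [
        {"genome": g, "position": i, "gene_id": gid}
        for g, order in sim.gene_orders.items()
        for i, gid in enumerate(order)
    ]
    write_tsv(pd.DataFrame(order_rows), outdir / "gene_order.tsv")
    write_tsv(sim.truth, outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# metadata filtering

@dataclass
class GenomeMetadata:
    genome_id: str
    coverage: float
    assembly_size: int
    is_mag: bool
    n_mhc: int | None = None


REQUIRED_METADATA = ("genome_id", "coverage", "assembly_size", "is_mag")


def filter_genomes(
    metadata: pd.DataFrame,
    min_coverage: float = 50.0,
    min_mag_size: int = 3_000_000,
    require_mhc: bool = True,
) -> tuple[list[str], dict[str, str]]:
    """Quality-filter genomes before analysis.

    Keep iff coverage >= min_coverage, AND (not a MAG OR assembly size
    >= min_mag_size), AND (when MHC counts are known) at least one MHC.
    Returns the kept genome ids and a reason per removed genome;
    genomes with missing required fields are removed as "incomplete
    metadata".
    """
    kept: list[str] = []
    reasons: dict[str, str] = {}
    for _, row in metadata.iterrows():
        gid = str(row.get("genome_id", "?"))
        if any(pd.isna(row.get(c)) for c in REQUIRED_METADATA):
            reasons[gid] = "incomplete metadata"
            continue
        if float(row["coverage"]) < min_coverage:
            reasons[gid] = "coverage"
            continue
        if bool(row["is_mag"]) and int(row["assembly_size"]) < min_mag_size:
            reasons[gid] = "mag_size"
            continue
        n_mhc = row.get("n_mhc")
        if require_mhc and n_mhc is not None and not pd.isna(n_mhc):
            if int(n_mhc) < 1:
                reasons[gid] = "no_mhc"
                continue
        kept.append(gid)
    return kept, reasons
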