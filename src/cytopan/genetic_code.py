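"""The standard bacterial genetic code and small codon utilities.

Translation uses NCBI table 11 (the bacterial/archaeal code), which maps
codons to amino acids identically to the standard code; only start-codon
conventions differ, and those play no role here.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .errors import InvalidSequenceError

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the three stop codons
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

BASES = "ACGT"

#: purine<->purine / pyrimidine<->pyrimidine partner (transitions)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons; length must be a multiple of three."""
    if len(cds) % 3 != 0:
        raise InvalidSequenceError(
            f"CDS length {len(cds)} is not a multiple of 3"
        )
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate_cds(cds: str, allow_terminal_stop: bool = True) -> str:
    """Translate a CDS to protein; internal stops are an error.

    A single terminal stop codon is stripped when ``allow_terminal_stop``.
    """
    cds = cds.upper()
    codons = codons_of(cds)
    if allow_terminal_stop and codons and is_stop(codons[-1]):
        codons = codons[:-1]
    aas = []
    for i, c in enumerate(codons):
        if is_stop(c):
            raise InvalidSequenceError(f"internal stop codon {c} at codon {i}")
        try:
            aas.append(CODON_TO_AA[c])
        except KeyError:
            raise InvalidSequenceError(f"unrecognized codon {c!r} at codon {i}")
    return "".join(aas)


def has_internal_stop(cds: str) -> bool:
    codons = codons_of(cds.upper())
    if codons and is_stop(codons[-1]):
        codons = codons[:-1]
    return any(is_stop(c) for c in codons)
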