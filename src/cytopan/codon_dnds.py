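"""Pairwise dN/dS estimation: protein-guided codon alignment, axt-style
pairs, and Nei-Gojobori (NG86) counting with Jukes-Cantor correction.

The NG86 estimator proceeds in three steps.  (1) *Sites*: each codon
position contributes fractionally to the synonymous site count according
to the fraction of its single-nucleotide changes that are synonymous;
changes to stop codons are excluded, with per-position renormalization
over the remaining (non-stop) neighbors, so every codon contributes
exactly 3 sites.  (2) *Differences*: for a pair of codons differing at k
positions, all k! minimal mutational pathways are enumerated, pathways
passing through a stop codon are discarded, and the synonymous /
nonsynonymous step counts are averaged over the remaining pathways.
(3) *Correction*: the proportions pS = Sd/S and pN = Nd/N are converted
to distances with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3); the
ratio dN/dS is the selection estimate omega (~1 neutral, <1 purifying).

Because every comparison in the pipeline is against a single reference
sequence, proteins are aligned pairwise to the reference directly rather
than through a multiple alignment; externally aligned sequences can be
supplied through the axt reader for exact replication of an MSA-based
workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    InconsistentInputError,
    InvalidParameterError,
    InvalidSequenceError,
)
from .genetic_code import CODON_TO_AA, STOP_CODONS, translate_cds

GAP_CODON = "---"
_NT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# protein alignment and codon-aware back-translation

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _protein_aligner()


def align_protein_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two proteins (BLOSUM62, affine gap open 11 /
    extend 1); returns the gapped pair.  The first optimal alignment in
    the aligner's deterministic enumeration order is used, so equal
    inputs always yield equal outputs."""
    for s in (a, b):
        if not s:
            raise InvalidSequenceError("empty protein sequence")
        bad = set(s) - set(_ALIGNER.substitution_matrix.alphabet)
        if bad:
            raise InvalidSequenceError(f"invalid residues {sorted(bad)}")
    aln = _ALIGNER.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gap-aligned nucleotide sequences in whole-codon units."""

    id_a: str
    id_b: str
    nt_a: str
    nt_b: str

    def __post_init__(self):
        if len(self.nt_a) != len(self.nt_b):
            raise InconsistentInputError("aligned sequences differ in length")
        if len(self.nt_a) % 3 != 0:
            raise InconsistentInputError("aligned length not a codon multiple")
        for seq in (self.nt_a, self.nt_b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise InconsistentInputError(
                        f"gap not in whole-codon units at column {i}"
                    )

    def codon_columns(self):
        for i in range(0, len(self.nt_a), 3):
            yield self.nt_a[i : i + 3], self.nt_b[i : i + 3]

    def ungapped(self) -> tuple[str, str]:
        return self.nt_a.replace("-", ""), self.nt_b.replace("-", "")


def back_translate(
    gapped_a: str,
    gapped_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignmentPair:
    """Thread source codons onto a gapped protein alignment.

    Each amino acid is replaced by the codon it came from; protein gaps
    become ``---``.  Trailing stop codons on the CDSs are tolerated.
    Raises :class:`InconsistentInputError` (naming the offending gene)
    if a CDS does not translate to its ungapped protein.
    """
    out = []
    for gapped, cds, gid in ((gapped_a, cds_a, id_a), (gapped_b, cds_b, id_b)):
        cds = cds.upper()
        protein = gapped.replace("-", "")
        try:
            translated = translate_cds(cds)
        except InvalidSequenceError as e:
            raise InconsistentInputError(f"{gid}: {e}") from e
        if translated != protein:
            raise InconsistentInputError(
                f"{gid}: CDS translation does not match aligned protein"
            )
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(protein))]
        it = iter(codons)
        out.append(
            "".join(GAP_CODON if ch == "-" else next(it) for ch in gapped)
        )
    return CodonAlignmentPair(id_a=id_a, id_b=id_b, nt_a=out[0], nt_b=out[1])


def align_codon_pair(
    cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> CodonAlignmentPair:
    """Protein-guided codon alignment of two CDSs in one call."""
    pa = translate_cds(cds_a)
    pb = translate_cds(cds_b)
    ga, gb = align_protein_pair(pa, pb)
    return back_translate(ga, gb, cds_a, cds_b, id_a=id_a, id_b=id_b)


# ---------------------------------------------------------------------------
# NG86 counting

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous site counts (s, n) of one codon.

    Per position, s gets the fraction of non-stop single-nucleotide
    neighbors that are synonymous; s + n = 3 exactly by renormalization.
    Stop or ambiguous codons return ``None`` (excluded-codon signal).
    """
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        return None
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TO_AA[neighbor] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Pathway-averaged synonymous/nonsynonymous differences (sd, nd).

    All minimal mutational pathways between the codons are enumerated;
    pathways passing through a stop codon are discarded and step
    classifications averaged over the survivors.  Returns ``None`` when
    either codon is not a sense codon or every pathway is blocked.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a not in CODON_TO_AA or codon_b not in CODON_TO_AA:
        return None
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN for p >= 3/4 (saturation: the correction diverges).
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"proportion {p} outside [0, 1]")
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DnDsResult:
    """NG86 counts and distances for one pairwise comparison.

    omega is NaN when undefined (dS zero or saturated); ``status``
    records why: ok | no_data | ds_zero | saturated.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    n_codons: int
    n_excluded: int
    status: str


_NO_DATA = DnDsResult(
    S=0.0, N=0.0, Sd=0.0, Nd=0.0, pS=math.nan, pN=math.nan,
    dS=math.nan, dN=math.nan, omega=math.nan, n_codons=0, n_excluded=0,
    status="no_data",
)


def estimate_dnds(pair: CodonAlignmentPair, method: str = "NG86") -> DnDsResult:
    """Estimate dN/dS for one codon-aligned pair.

    Codon columns containing gaps, stop codons or ambiguity characters
    in either sequence are excluded pairwise.  Site totals are averaged
    over the two sequences (making the estimate symmetric in sequence
    order); differences are summed over compared columns.
    """
    if method != "NG86":
        raise InvalidParameterError(
            f"method {method!r} not available; NG86 is the supported estimator"
        )
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    n_excluded = 0
    for ca, cb in pair.codon_columns():
        if ca == GAP_CODON or cb == GAP_CODON:
            n_excluded += 1
            continue
        if set(ca) - _NT or set(cb) - _NT:
            n_excluded += 1
            continue
        sites_a = ng86_sites(ca)
        sites_b = ng86_sites(cb)
        diffs = ng86_differences(ca, cb)
        if sites_a is None or sites_b is None or diffs is None:
            n_excluded += 1
            continue
        s_a += sites_a[0]
        s_b += sites_b[0]
        sd += diffs[0]
        nd += diffs[1]
        n_codons += 1
    if n_codons == 0:
        return _NO_DATA
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan
    dS = jukes_cantor(min(pS, 1.0)) if not math.isnan(pS) else math.nan
    dN = jukes_cantor(min(pN, 1.0)) if not math.isnan(pN) else math.nan
    if math.isnan(dS) or math.isnan(dN):
        status, omega = "saturated", math.nan
    elif dS == 0.0:
        status, omega = "ds_zero", math.nan
    else:
        status, omega = "ok", dN / dS
    return DnDsResult(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN,
        omega=omega, n_codons=n_codons, n_excluded=n_excluded, status=status,
    )


def estimate_dnds_cds(
    cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> DnDsResult:
    """Align two CDSs (protein-guided) and estimate dN/dS."""
    return estimate_dnds(align_codon_pair(cds_a, cds_b, id_a, id_b))
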