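"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own counting/alignment code
paths: translation goes through Bio.Seq, site counting enumerates all
single-nucleotide neighbors explicitly, pathway counting enumerates
permutations step by step, alignment scoring enumerates every possible
global alignment, and motif counting scans every position with explicit
non-overlap bookkeeping.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def aa_of(codon: str) -> str:
    """Translate one codon with Biopython ('*' for stops)."""
    return str(Seq(codon).translate())


def brute_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous sites by explicit neighbor enumeration
    with per-position renormalization over non-stop neighbors."""
    aa = aa_of(codon)
    assert aa != "*"
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbor_aa = aa_of(codon[:pos] + b + codon[pos + 1 :])
            if neighbor_aa == "*":
                continue
            outcomes.append(neighbor_aa == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def brute_differences(a: str, b: str) -> tuple[float, float] | None:
    """Pathway-averaged differences by stepping through every
    permutation of the differing positions."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in permutations(diffs):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa_of(nxt) == "*":
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    n = len(totals)
    return sum(t[0] for t in totals) / n, sum(t[1] for t in totals) / n


def brute_motif_count(protein: str, motif_len: int = 5) -> int:
    """Non-overlapping leftmost-first CxxCH count by explicit position
    scan."""
    count = 0
    i = 0
    while i + motif_len <= len(protein):
        w = protein[i : i + motif_len]
        if w[0] == "C" and w[3] == "C" and w[4] == "H":
            count += 1
            i += motif_len
        else:
            i += 1
    return count


def brute_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as gapped string pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in brute_global_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in brute_global_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in brute_global_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def score_gapped(ga: str, gb: str, matrix, open_pen=11.0, extend_pen=1.0):
    """Score one gapped alignment: substitution matrix + affine gaps
    (first gap residue costs open, subsequent cost extend)."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-":
            score -= extend_pen if prev_gap_a else open_pen
            prev_gap_a, prev_gap_b = True, False
        elif y == "-":
            score -= extend_pen if prev_gap_b else open_pen
            prev_gap_a, prev_gap_b = False, True
        else:
            score += matrix[x, y]
            prev_gap_a = prev_gap_b = False
    return score


def brute_best_alignment_score(a: str, b: str, matrix) -> float:
    return max(
        score_gapped(ga, gb, matrix)
        for ga, gb in brute_global_alignments(a, b)
    )


def brute_profile_scan(scores, encoded_seq) -> float:
    """Best ungapped local profile match by exhaustively scanning every
    (column range, sequence start) placement."""
    import numpy as np

    C = scores.shape[0]
    L = len(encoded_seq)
    best = -np.inf
    for j0 in range(C):
        for j1 in range(j0 + 1, C + 1):
            width = j1 - j0
            for start in range(0, L - width + 1):
                total = sum(
                    scores[j, encoded_seq[start + (j - j0)]]
                    for j in range(j0, j1)
                )
                if total > best:
                    best = total
    return best
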