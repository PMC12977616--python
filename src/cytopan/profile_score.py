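"""Position-specific log-odds profiles and bitscore separability.

A profile is built from an alignment of family members: per-column
residue frequencies with additive pseudocounts, scored in bits against
a background distribution (empirical by default).  Candidate sequences
are scored by the best ungapped placement of the profile along the
sequence.  This is deliberately *not* a profile-HMM implementation — no
insert/delete states, no E-values — because the question it answers is
whether any bitscore threshold separates true family members from
paralogs, which depends on score overlap, not on the HMM machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, InvalidSequenceError

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass
class Profile:
    """Per-column log-odds scores (bits) over the 20 residues."""

    scores: np.ndarray  # (n_columns, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    source_id: str = ""

    @property
    def n_columns(self) -> int:
        return int(self.scores.shape[0])

    def max_score(self) -> float:
        """The maximal achievable full-overlap score (column maxima)."""
        return float(self.scores.max(axis=1).sum())


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as e:
        raise InvalidSequenceError(f"invalid residue {e.args[0]!r}") from e


def build_profile(
    aligned_proteins: Sequence[str],
    pseudocount: float = 1.0,
    source_id: str = "",
    uniform_background: bool = False,
) -> Profile:
    """Build a log-odds profile from aligned (equal-length) proteins.

    Columns in which gaps form the majority are dropped.  Column
    probabilities use additive pseudocounts split evenly over the
    alphabet; the background is the empirical residue distribution of
    the whole alignment (with the same pseudocounts) unless
    ``uniform_background``.  A single-sequence alignment triggers a
    warning and a 5x heavier pseudocount to temper the resulting
    profile.
    """
    if not aligned_proteins:
        raise InvalidParameterError("empty alignment")
    lengths = {len(s) for s in aligned_proteins}
    if len(lengths) != 1:
        raise InvalidParameterError("aligned sequences must have equal length")
    if pseudocount <= 0:
        raise InvalidParameterError("pseudocount must be > 0")
    if len(aligned_proteins) == 1:
        warnings.warn(
            "building a profile from a single sequence; "
            "using a heavier pseudocount",
            stacklevel=2,
        )
        pseudocount *= 5.0
    ncols = lengths.pop()
    nseq = len(aligned_proteins)
    counts = np.zeros((ncols, 20))
    for seq in aligned_proteins:
        seq = seq.upper()
        for j, ch in enumerate(seq):
            if ch == "-":
                continue
            if ch not in _AA_INDEX:
                raise InvalidSequenceError(f"invalid residue {ch!r}")
            counts[j, _AA_INDEX[ch]] += 1

    keep = counts.sum(axis=1) > nseq / 2.0  # non-gap majority
    counts = counts[keep]
    if counts.shape[0] == 0:
        raise InvalidParameterError("no non-gap-majority columns")

    col_n = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount / 20.0) / (col_n + pseudocount)
    if uniform_background:
        background = np.full(20, 1.0 / 20.0)
    else:
        tot = counts.sum(axis=0)
        background = (tot + pseudocount) / (tot.sum() + 20.0 * pseudocount)
    scores = np.log2(probs / background)
    return Profile(
        scores=scores,
        background=background,
        pseudocount=pseudocount,
        source_id=source_id,
    )


def score_sequence(profile: Profile, protein: str) -> float:
    """Best ungapped local match of the profile along a sequence.

    For every placement offset, the contributions of the overlapping
    columns are computed and the best non-empty contiguous run of
    columns is taken (columns outside the sequence, or trimmed off the
    run, contribute 0) — ungapped local matching, the profile analogue
    of an ungapped Smith-Waterman hit.  This makes the score monotone
    under sequence extension: prepending or appending residues never
    lowers the maximum, because every previously available column run
    is still available.  A consensus sequence attains the profile's
    maximal achievable score (per-column maxima are always >= 0 for a
    log-odds profile).
    """
    if not protein:
        raise InvalidSequenceError("empty protein")
    enc = _encode(protein.upper())
    L = len(enc)
    C = profile.n_columns
    best = -np.inf
    for offset in range(-(C - 1), L):
        j0 = max(0, -offset)
        j1 = min(C, L - offset)
        if j1 <= j0:
            continue
        cols = np.arange(j0, j1)
        contrib = profile.scores[cols, enc[cols + offset]]
        # best non-empty contiguous subarray (Kadane)
        running = best_here = contrib[0]
        for x in contrib[1:]:
            running = max(x, running + x)
            best_here = max(best_here, running)
        if best_here > best:
            best = float(best_here)
    return best


@dataclass
class SeparabilityReport:
    """Can a single bitscore threshold separate family members from
    non-members?"""

    margin: float  # min(trained) - max(other); > 0 means separable
    overlap_fraction: float
    perfect_threshold_exists: bool
    n_trained: int
    n_other: int


def separability(
    trained_scores: Sequence[float],
    other_scores: Sequence[float],
) -> SeparabilityReport:
    """Score-overlap report between a profile's training family and all
    other sequences.

    The margin is min(trained) - max(other); a positive margin means
    some threshold classifies perfectly.  The overlap fraction is the
    proportion of all scores falling inside the other group's range
    crossing (trained scores <= max(other) plus other scores >=
    min(trained)).
    """
    if not len(trained_scores) or not len(other_scores):
        raise InvalidParameterError("both score sets must be non-empty")
    trained = np.asarray(trained_scores, dtype=float)
    other = np.asarray(other_scores, dtype=float)
    margin = float(trained.min() - other.max())
    n_overlap = int((trained <= other.max()).sum()) + int(
        (other >= trained.min()).sum()
    )
    return SeparabilityReport(
        margin=margin,
        overlap_fraction=n_overlap / (trained.size + other.size),
        perfect_threshold_exists=margin > 0,
        n_trained=int(trained.size),
        n_other=int(other.size),
    )
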