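"""PWM similarity and greedy redundancy removal.

Motif similarity follows the CompareACE approach: two PWMs are slid
against each other over every ungapped offset with at least six
overlapping columns, in both orientations (the second matrix also as its
reverse complement), and the similarity m is the maximum Pearson
correlation between the aligned 4×overlap probability blocks flattened to
vectors.  m is symmetric and invariant under reverse-complementing either
argument.  Zero-variance blocks (both matrices uniform over the overlap)
score 0 rather than leaving the correlation undefined.

Redundancy removal is greedy by score: motifs are sorted by MAP score
descending, the head is emitted and every remaining motif more similar
than the cutoff to it is discarded, repeating until the list is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refine import RefinedMotif, pwm_reverse_complement

__all__ = ["PwmAlignment", "compare_ace", "remove_redundant"]

MIN_OVERLAP = 6


@dataclass
class PwmAlignment:
    """Best ungapped alignment of two PWMs.

    ``offset`` is the column of B's start relative to A's start (negative
    when B hangs off A's left end); ``orientation`` records whether B was
    reverse-complemented.
    """

    m: float
    offset: int
    orientation: str  # "same" or "revcomp"
    overlap: int


def _as_pwm(x) -> np.ndarray:
    if isinstance(x, RefinedMotif):
        return x.pwm
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("PWM must have shape (width, 4)")
    return arr


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    av = a.ravel() - a.mean()
    bv = b.ravel() - b.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return 0.0
    return float((av @ bv) / denom)


def compare_ace(a, b, min_overlap: int = MIN_OVERLAP) -> PwmAlignment:
    """Maximal column-correlation similarity between two PWMs.

    Accepts :class:`RefinedMotif` or raw (w, 4) arrays.  Raises
    ``ValueError`` when either width is below ``min_overlap``.
    """
    A = _as_pwm(a)
    B = _as_pwm(b)
    wa, wb = len(A), len(B)
    if wa < min_overlap or wb < min_overlap:
        raise ValueError("PWM width below minimum overlap")
    best = None
    best_key = None
    for orientation, Bo in (("same", B), ("revcomp", pwm_reverse_complement(B))):
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a = max(0, offset)
            hi_a = min(wa, offset + wb)
            overlap = hi_a - lo_a
            if overlap < min_overlap:
                continue
            blk_a = A[lo_a:hi_a]
            blk_b = Bo[lo_a - offset : hi_a - offset]
            r = _pearson(blk_a, blk_b)
            # ties (e.g. periodic motifs) resolved toward the fullest,
            # most central, same-strand alignment
            key = (r, overlap, -abs(offset), orientation == "same")
            if best is None or key > best_key:
                best = PwmAlignment(r, offset, orientation, overlap)
                best_key = key
    if best is None:  # unreachable given the width check, kept defensive
        raise ValueError("no admissible alignment")
    return best


def remove_redundant(motifs: list, cutoff: float = 0.6) -> list:
    """Greedy removal of motifs similar to a better-scoring one.

    Sorts by MAP score descending (ties: lexicographically smaller
    consensus first), then repeatedly keeps the head and discards every
    remaining motif whose similarity to it exceeds ``cutoff``.  The output
    preserves emission order, is pairwise <= cutoff, and always contains
    the global max-MAP motif.
    """
    pool = sorted(motifs, key=lambda m: (-m.map_score, m.consensus))
    kept = []
    while pool:
        head = pool.pop(0)
        kept.append(head)
        pool = [
            m for m in pool if compare_ace(head, m).m <= cutoff
        ]
    return kept
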