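"""Gapped core-consensus space: enumeration, scanning and enrichment.

A core consensus is a pair of fully specified base triplets separated by a
fixed run of 0-14 unspecified (N) positions, ``UVW·N^g·XYZ``.  The full
space therefore holds 4^6 × 15 = 61,440 patterns of span 6-20 with exactly
six informative positions.  Each core is scored against a background by
fold enrichment F = C/E and a z-score of the observed foreground count C
against its length-proportional expectation E = N_bg · L_fg / L_bg.

Scanning is strand-symmetric: a pattern is matched on both strands, except
that a self-reverse-complementary pattern is scanned forward-only so that a
palindromic site is never counted twice.  The module exposes a direct
scanner (:func:`count_instances`) and a fast whole-space scorer built on
per-gap triplet-pair count matrices; the two agree exactly (the fast path
is property-tested against the scanner).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from math import inf, sqrt

import numpy as np

from . import iupac
from .seq_io import SequenceSet

__all__ = [
    "GappedConsensus",
    "EnrichmentStats",
    "MotifInstance",
    "enumerate_core_space",
    "count_instances",
    "enrichment_stats",
    "score_core_space",
    "select_primary_cores",
    "CoreCounter",
]

_TRIPLETS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
_TRIPLET_RC = np.array(
    [_TRIPLETS.index(iupac.reverse_complement(t)) for t in _TRIPLETS]
)


@dataclass(frozen=True)
class GappedConsensus:
    """An IUPAC consensus pattern, possibly with internal N gap positions."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(iupac.IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC codes in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)

    @classmethod
    def from_triplets(cls, left: str, gap: int, right: str) -> "GappedConsensus":
        return cls(left + "N" * gap + right)

    @property
    def span(self) -> int:
        return len(self.pattern)

    @cached_property
    def informative_positions(self) -> tuple:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")

    @property
    def n_informative(self) -> int:
        return len(self.informative_positions)

    @property
    def gap(self):
        """N-run length between the two triplets for core-shaped patterns.

        ``None`` when the pattern is not of the two-triplet core shape
        (e.g. after extension has specialized flank or gap positions).
        """
        s = self.span
        if s >= 6 and self.informative_positions == (0, 1, 2, s - 3, s - 2, s - 1):
            return s - 6
        return None

    @cached_property
    def is_palindromic(self) -> bool:
        return iupac.is_palindromic(self.pattern)

    def reverse_complement(self) -> "GappedConsensus":
        return GappedConsensus(iupac.reverse_complement(self.pattern))

    def __str__(self) -> str:
        return self.pattern


@dataclass
class EnrichmentStats:
    """Observed/expected foreground counts with fold enrichment and z-score."""

    C: int
    N_bg: int
    E: float
    F: float
    Z: float


@dataclass
class MotifInstance:
    """One occurrence of a motif in a sequence.

    ``site`` is the matched substring in motif (forward) orientation;
    ``offset`` is the 0-based start on the forward strand of the source
    sequence.  ``left_context`` holds up to three bases preceding the site
    on the instance's strand, used by the Markov background likelihood.
    """

    sequence_id: str
    offset: int
    strand: str
    site: str
    mismatches: int = 0
    left_context: str = ""


def enumerate_core_space(max_gap: int = 14) -> list:
    """Enumerate every two-triplet core ``UVW·N^g·XYZ`` for g in 0..max_gap.

    Deterministic order: by gap, then lexicographically by pattern.  The
    default gap range yields the full 61,440-pattern core space.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = []
    for gap in range(max_gap + 1):
        mid = "N" * gap
        for left in _TRIPLETS:
            for right in _TRIPLETS:
                out.append(GappedConsensus(left + mid + right))
    return out


def _forward_mismatch_counts(pattern: str, arr: np.ndarray) -> np.ndarray:
    """Mismatch count at informative positions for every window start."""
    span = len(pattern)
    n = len(arr) - span + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for p, code in enumerate(pattern):
        if code == "N":
            continue
        mm += ~iupac.MATCH[code][arr[p : p + n]]
    return mm


def forward_match_offsets(
    pattern: str, arr: np.ndarray, max_mismatch: int = 0
) -> np.ndarray:
    mm = _forward_mismatch_counts(pattern, arr)
    return np.nonzero(mm <= max_mismatch)[0]


def count_instances(
    motif: GappedConsensus, seqs: SequenceSet, max_mismatch: int = 0
):
    """Count occurrences of ``motif`` in ``seqs`` on both strands.

    Mismatches are counted at informative (non-N) positions only; pattern
    N positions match anything for free, and a sequence N never matches a
    specified position.  Overlapping occurrences are all counted.  If the
    pattern equals its own reverse complement only the forward strand is
    scanned, so palindromic sites are counted once.

    Returns ``(count, instances)``.
    """
    if motif.span == 0:
        raise ValueError("motif span must be positive")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    pattern = motif.pattern
    rc_pattern = iupac.reverse_complement(pattern)
    scan_reverse = rc_pattern != pattern
    span = motif.span
    instances = []
    for seq in seqs:
        arr = seq.encoded
        mm = _forward_mismatch_counts(pattern, arr)
        for off in np.nonzero(mm <= max_mismatch)[0]:
            instances.append(
                MotifInstance(
                    seq.identifier,
                    int(off),
                    "+",
                    seq.residues[off : off + span],
                    int(mm[off]),
                )
            )
        if scan_reverse:
            mm_r = _forward_mismatch_counts(rc_pattern, arr)
            for off in np.nonzero(mm_r <= max_mismatch)[0]:
                site = iupac.reverse_complement(seq.residues[off : off + span])
                instances.append(
                    MotifInstance(
                        seq.identifier, int(off), "-", site, int(mm_r[off])
                    )
                )
    return len(instances), instances


def enrichment_stats(C: int, N_bg: int, L_fg: int, L_bg: int) -> EnrichmentStats:
    """Fold enrichment and z-score of a foreground count vs background.

    E = N_bg·L_fg/L_bg; F = C/E; Z = (C−E)/sqrt(E·(1−L_fg/L_bg)), the
    binomial z-approximation with per-position hit probability proportional
    to length.  Degenerate cases: when E = 0, F is +inf for C > 0 and 1.0
    for C = 0, and Z = 0; when L_fg ≥ L_bg the variance term vanishes and
    Z is 0 for C = E, ±inf otherwise.
    """
    if min(C, N_bg) < 0 or L_fg <= 0 or L_bg <= 0:
        raise ValueError("counts must be non-negative, lengths positive")
    E = N_bg * L_fg / L_bg
    if E == 0:
        F = inf if C > 0 else 1.0
        Z = 0.0
    else:
        F = C / E
        p = L_fg / L_bg
        var = E * (1.0 - p)
        if var > 0:
            Z = (C - E) / sqrt(var)
        else:
            Z = 0.0 if C == E else inf * (1 if C > E else -1)
    return EnrichmentStats(C=C, N_bg=N_bg, E=E, F=F, Z=Z)


def _enrichment_arrays(C, N_bg, L_fg, L_bg):
    """Vectorized counterpart of :func:`enrichment_stats` (same contract)."""
    C = np.asarray(C, dtype=np.float64)
    E = np.asarray(N_bg, dtype=np.float64) * (L_fg / L_bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(E > 0, C / np.where(E > 0, E, 1.0), np.where(C > 0, np.inf, 1.0))
        var = E * (1.0 - L_fg / L_bg)
        Z = np.where(var > 0, (C - E) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        if L_fg >= L_bg:
            Z = np.where(
                (E == 0) | (C == E),
                0.0,
                np.where(C > E, np.inf, -np.inf),
            )
    return E, F, Z


class CoreCounter:
    """Per-gap triplet-pair occurrence matrices for a sequence set.

    ``pair_matrix(gap)[k1, k2]`` is the number of forward-strand text
    positions at which triplet ``k1`` occurs followed, ``gap`` positions
    later, by triplet ``k2`` (windows touching an N are excluded).  Forward
    counts for any core or degenerate consensus are sums over blocks of
    this matrix, which makes whole-space scoring and degeneration search
    cheap.  Matrices are cached per gap.
    """

    def __init__(self, seqs: SequenceSet):
        self.seqs = seqs
        self.total_length = seqs.total_length
        self._codes = []
        for seq in seqs:
            arr = seq.encoded.astype(np.int32)
            L = len(arr)
            if L < 3:
                self._codes.append((np.zeros(0, np.int32), np.zeros(0, bool)))
                continue
            t = arr[: L - 2] * 16 + arr[1 : L - 1] * 4 + arr[2:]
            valid = (arr[: L - 2] < 4) & (arr[1 : L - 1] < 4) & (arr[2:] < 4)
            t = np.where(valid, t, 0)
            self._codes.append((t, valid))
        self._cache: dict = {}

    def pair_matrix(self, gap: int, cache: bool = True) -> np.ndarray:
        if gap in self._cache:
            return self._cache[gap]
        d = 3 + gap
        ids = []
        for t, valid in self._codes:
            m = len(t) - d
            if m <= 0:
                continue
            ok = valid[:m] & valid[d:]
            ids.append((t[:m] * 64 + t[d:])[ok])
        if ids:
            flat = np.concatenate(ids)
            M = np.bincount(flat, minlength=64 * 64).astype(np.int64)
        else:
            M = np.zeros(64 * 64, dtype=np.int64)
        M = M.reshape(64, 64)
        if cache:
            self._cache[gap] = M
        return M

    def tensor(self, gap: int) -> np.ndarray:
        """pair_matrix reshaped to one 4-ary axis per informative position."""
        return self.pair_matrix(gap).reshape((4,) * 6)


def _core_count_matrices(counter: CoreCounter, gap: int, cache: bool = True):
    """Both-strand core counts for all 64×64 (left, right) triplet pairs."""
    M = counter.pair_matrix(gap, cache=cache)
    rc = _TRIPLET_RC
    # B[k1,k2] = forward matches of revcomp core = M[rc(k2), rc(k1)]
    B = M[np.ix_(rc, rc)].T
    pal = rc[np.newaxis, :] == np.arange(64)[:, np.newaxis]  # k1 == rc(k2)
    return np.where(pal, M, M + B)


def score_core_space(
    fg: SequenceSet | CoreCounter,
    bg: SequenceSet | CoreCounter,
    max_gap: int = 14,
):
    """Score the full core space; yields per-gap count/F/Z arrays.

    Returns an iterator of ``(gap, C, N_bg, F, Z)`` where each array has
    shape (64, 64) indexed by (left triplet, right triplet).
    """
    fgc = fg if isinstance(fg, CoreCounter) else CoreCounter(fg)
    bgc = bg if isinstance(bg, CoreCounter) else CoreCounter(bg)
    L_fg, L_bg = fgc.total_length, bgc.total_length
    for gap in range(max_gap + 1):
        C = _core_count_matrices(fgc, gap, cache=False)
        N = _core_count_matrices(bgc, gap, cache=False)
        _, F, Z = _enrichment_arrays(C, N, L_fg, L_bg)
        yield gap, C, N, F, Z


def select_primary_cores(
    fg: SequenceSet | CoreCounter,
    bg: SequenceSet | CoreCounter,
    min_fold: float = 1.2,
    top_k: int = 50,
    max_gap: int = 14,
):
    """Select the primary core motifs from the full gapped-core space.

    Every core with fold enrichment F >= ``min_fold`` survives; survivors
    are ranked by z-score descending (ties broken by lexicographically
    smaller pattern) and the first ``top_k`` are returned.  If fewer than
    ``top_k`` survive the fold filter all survivors are returned.

    Returns a list of ``(GappedConsensus, EnrichmentStats)``.
    """
    if isinstance(fg, SequenceSet) and len(fg) == 0:
        raise ValueError("empty foreground")
    if isinstance(bg, SequenceSet) and len(bg) == 0:
        raise ValueError("empty background")
    fgc = fg if isinstance(fg, CoreCounter) else CoreCounter(fg)
    bgc = bg if isinstance(bg, CoreCounter) else CoreCounter(bg)
    L_fg, L_bg = fgc.total_length, bgc.total_length
    survivors = []
    for gap, C, N, F, Z in score_core_space(fgc, bgc, max_gap=max_gap):
        k1s, k2s = np.nonzero(F >= min_fold)
        mid = "N" * gap
        for k1, k2, c, n, f, z in zip(
            k1s, k2s, C[k1s, k2s], N[k1s, k2s], F[k1s, k2s], Z[k1s, k2s]
        ):
            pat = _TRIPLETS[k1] + mid + _TRIPLETS[k2]
            survivors.append((float(z), pat, int(c), int(n), float(f)))
    survivors.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for z, pat, c, n, f in survivors[:top_k]:
        e = n * L_fg / L_bg
        out.append(
            (GappedConsensus(pat), EnrichmentStats(C=c, N_bg=n, E=e, F=f, Z=z))
        )
    return out
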