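"""Core-motif degeneration and extension.

Degeneration relaxes the six informative positions of a primary core to
IUPAC ambiguity codes: at up to four of the six positions the base may be
replaced by any *consistent* code (a code whose base set contains the
original base — 7 non-identity options per base, N included), and the
candidate that raises both the fold enrichment and the z-score the most
(max Z) replaces the core.

Extension pads the degenerate core with equal numbers of flanking N
positions to a fixed span — 20 when the core's internal gap is even, 19
when it is odd — and then specializes up to three non-informative
positions (flanks or gap interior) to any of the 15 non-N IUPAC codes,
keeping the variant with the largest z-score if it beats the unextended
form.  For foregrounds larger than 100 kb the extension round is run a
second time starting from the first winner.

Both searches are exhaustive and exact, made fast by counting candidate
occurrences from sufficient statistics instead of rescanning: degeneration
contracts the per-gap triplet-pair count tensor with per-position code
indicator matrices; extension histograms the parent consensus' match
sites at the positions being specialized (every occurrence of a variant is
an occurrence of its parent).  Strand symmetry uses the identity
count(V) = fwd(V) + fwd(revcomp(V)), with the second term dropped for
self-reverse-complementary variants.
"""

from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np

from . import iupac
from .consensus import (
    CoreCounter,
    EnrichmentStats,
    GappedConsensus,
    _enrichment_arrays,
    enrichment_stats,
    forward_match_offsets,
)
from .seq_io import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "enumerate_degenerations",
    "select_degenerate",
    "pad_core",
    "extend_core",
]

#: number of IUPAC codes consistent with each base (incl. itself and N)
N_CONSISTENT = 8


def _core_bases(core: GappedConsensus) -> str:
    if core.gap is None:
        raise ValueError("not a two-triplet core consensus")
    bases = core.pattern[:3] + core.pattern[-3:]
    if any(b not in "ACGT" for b in bases):
        raise ValueError("core informative positions must be concrete bases")
    return bases


def enumerate_degenerations(core: GappedConsensus, max_changed: int = 4):
    """Yield every consistent degeneration of a two-triplet core.

    At most ``max_changed`` of the six informative positions are replaced
    by a different IUPAC code whose base set contains the original base;
    the unmodified core is yielded first.  Total yield for the default is
    sum_{k<=4} C(6,k)*7^k = 43,653 consensuses.
    """
    bases = _core_bases(core)
    gap = core.gap
    mid = "N" * gap
    slots = range(6)
    options = [
        [c for c in iupac.CONSISTENT_CODES[b] if c != b] for b in bases
    ]
    for k in range(min(max_changed, 6) + 1):
        for pos in itertools.combinations(slots, k):
            for codes in itertools.product(*(options[p] for p in pos)):
                letters = list(bases)
                for p, c in zip(pos, codes):
                    letters[p] = c
                yield GappedConsensus(
                    "".join(letters[:3]) + mid + "".join(letters[3:])
                )


def _code_indicator(codes, complement: bool = False) -> np.ndarray:
    """len(codes) x 5 indicator of which sequence symbols satisfy a code.

    Column 4 (sequence N) is always 0: an N in the text never matches a
    specified pattern position.
    """
    M = np.zeros((len(codes), 5))
    for i, c in enumerate(codes):
        s = iupac.CODE_SETS[iupac.COMPLEMENT_CODE[c] if complement else c]
        for b in s:
            M[i, iupac.BASE_INDEX[b]] = 1.0
    return M


def select_degenerate(
    core: GappedConsensus,
    stats0: EnrichmentStats,
    fg: SequenceSet | CoreCounter,
    bg: SequenceSet | CoreCounter,
    max_changed: int = 4,
):
    """Pick the best consistent degeneration of a primary core.

    Candidates must strictly beat the core's fold enrichment AND z-score;
    among those the maximal-Z candidate wins (lexicographic pattern
    tie-break).  If no candidate qualifies the original core is returned
    with its original statistics.
    """
    bases = _core_bases(core)
    gap = core.gap
    fgc = fg if isinstance(fg, CoreCounter) else CoreCounter(fg)
    bgc = bg if isinstance(bg, CoreCounter) else CoreCounter(bg)
    L_fg, L_bg = fgc.total_length, bgc.total_length

    options = [list(iupac.CONSISTENT_CODES[b]) for b in bases]  # 8 each
    V = [_code_indicator(o)[:, :4] for o in options]
    Vc = [_code_indicator(o, complement=True)[:, :4] for o in options]

    def count_tensors(counter: CoreCounter) -> np.ndarray:
        R = counter.tensor(gap).astype(np.float64)
        A = R
        for i in range(6):
            A = np.tensordot(A, V[i].T, axes=([0], [0]))
        B = R
        for j in range(6):  # base axis j pairs with slot 5-j under revcomp
            B = np.tensordot(B, Vc[5 - j].T, axes=([0], [0]))
        B = B.transpose(5, 4, 3, 2, 1, 0)
        return A, B

    # palindromic-candidate mask: slot i code must equal the complement of
    # the slot 5-i code (gap Ns are self-complementary)
    pairs = []
    for i in range(3):
        P = np.zeros((N_CONSISTENT, N_CONSISTENT), dtype=bool)
        for a, ca in enumerate(options[i]):
            for b, cb in enumerate(options[5 - i]):
                P[a, b] = ca == iupac.COMPLEMENT_CODE[cb]
        pairs.append(P)
    pal = (
        pairs[0][:, None, None, None, None, :]
        & pairs[1][None, :, None, None, :, None]
        & pairs[2][None, None, :, :, None, None]
    )

    A_fg, B_fg = count_tensors(fgc)
    A_bg, B_bg = count_tensors(bgc)
    cnt_fg = np.where(pal, A_fg, A_fg + B_fg)
    cnt_bg = np.where(pal, A_bg, A_bg + B_bg)
    _, F, Z = _enrichment_arrays(cnt_fg, cnt_bg, L_fg, L_bg)

    orig_idx = [options[i].index(bases[i]) for i in range(6)]
    shape = (N_CONSISTENT,) * 6
    dist = np.zeros(shape, dtype=np.int8)
    for i in range(6):
        ax = np.ones((1,) * i + (N_CONSISTENT,) + (1,) * (5 - i), dtype=np.int8)
        sel = np.arange(N_CONSISTENT) != orig_idx[i]
        dist = dist + ax * sel.reshape(ax.shape)
    elig = (dist <= max_changed) & (F > stats0.F) & (Z > stats0.Z)
    if not elig.any():
        return core, stats0
    zmax = Z[elig].max()
    ties = np.argwhere(elig & (Z == zmax))
    mid = "N" * gap
    best = None
    for idx in ties:
        letters = [options[i][idx[i]] for i in range(6)]
        pat = "".join(letters[:3]) + mid + "".join(letters[3:])
        if best is None or pat < best:
            best = pat
    i6 = tuple(np.argwhere(elig & (Z == zmax))[0])  # stats identical on ties
    stats = enrichment_stats(
        int(round(cnt_fg[i6])), int(round(cnt_bg[i6])), L_fg, L_bg
    )
    return GappedConsensus(best), stats


def pad_core(core: GappedConsensus) -> GappedConsensus:
    """Pad a core with equal flanking Ns to span 20 (even gap) or 19 (odd).

    The gap parity is derived from the span (span = 6 + gap for every
    initial core, and degeneration never changes the span — it may only
    turn informative slots into N).
    """
    if core.span < 6 or core.span > 20:
        raise ValueError("core span must be between 6 and 20")
    gap = core.span - 6
    target = 20 if gap % 2 == 0 else 19
    if core.span > target:
        raise ValueError("core span exceeds padding target")
    side = (target - core.span) // 2
    return GappedConsensus("N" * side + core.pattern + "N" * side)


def _match_site_matrix(pattern: str, seqs: SequenceSet) -> np.ndarray:
    """Stacked int8 windows (rows) of forward-text exact matches."""
    w = len(pattern)
    rows = []
    for seq in seqs:
        arr = seq.encoded
        offs = forward_match_offsets(pattern, arr, 0)
        for off in offs:
            rows.append(arr[off : off + w])
    if not rows:
        return np.zeros((0, w), dtype=np.int8)
    return np.stack(rows)


def _pal_axis_masks(base: str, positions: tuple, codes: list):
    """Mask of self-reverse-complementary variants for one position combo.

    Returns either ``False`` (no variant over this combo can be
    palindromic) or a boolean tensor of shape (15,)*k over the code axes.
    A variant V is palindromic iff V[i] == complement(V[w-1-i]) for all i.
    """
    w = len(base)
    k = len(positions)
    pset = set(positions)
    # fixed positions must already satisfy the symmetry
    for i in range(w):
        j = w - 1 - i
        if i in pset or j in pset or i > j:
            continue
        if base[i] != iupac.COMPLEMENT_CODE[base[j]]:
            return False
    axis_masks = []
    pair_constraints = []  # (axis_a, axis_b) requiring comp codes
    for a, p in enumerate(positions):
        q = w - 1 - p
        if q == p:
            mask = np.array(
                [iupac.COMPLEMENT_CODE[c] == c for c in codes], dtype=bool
            )
            axis_masks.append((a, mask))
        elif q in pset:
            b = positions.index(q)
            if a < b:
                pair_constraints.append((a, b))
        else:
            if base[q] == "N":
                return False
            want = iupac.COMPLEMENT_CODE[base[q]]
            mask = np.array([c == want for c in codes], dtype=bool)
            axis_masks.append((a, mask))
    n = len(codes)
    out = np.ones((n,) * k, dtype=bool)
    for a, mask in axis_masks:
        shape = [1] * k
        shape[a] = n
        out &= mask.reshape(shape)
    comp_pair = np.array(
        [[ca == iupac.COMPLEMENT_CODE[cb] for cb in codes] for ca in codes],
        dtype=bool,
    )
    for a, b in pair_constraints:
        idx_shape = [1] * k
        idx_shape[a] = n
        ia = np.arange(n).reshape(idx_shape)
        idx_shape = [1] * k
        idx_shape[b] = n
        ib = np.arange(n).reshape(idx_shape)
        out &= comp_pair[ia, ib]
    return out


def _joint_hist(sites: np.ndarray, cols: list) -> np.ndarray:
    """Joint base histogram (5-ary axes) of site columns."""
    k = len(cols)
    if sites.shape[0] == 0:
        return np.zeros((5,) * k)
    idx = np.zeros(sites.shape[0], dtype=np.int64)
    for c in cols:
        idx = idx * 5 + sites[:, c]
    return np.bincount(idx, minlength=5**k).astype(np.float64).reshape((5,) * k)


class _ExtensionScorer:
    """Scores all <=k-position specializations of a consensus pattern."""

    def __init__(self, pattern: str, fg, bg):
        self.pattern = pattern
        self.w = len(pattern)
        self.rc = iupac.reverse_complement(pattern)
        self.is_pal = self.rc == pattern
        self.L_fg = fg.total_length
        self.L_bg = bg.total_length
        self.Mf_fg = _match_site_matrix(pattern, fg)
        self.Mf_bg = _match_site_matrix(pattern, bg)
        if self.is_pal:
            self.Mr_fg, self.Mr_bg = self.Mf_fg, self.Mf_bg
        else:
            self.Mr_fg = _match_site_matrix(self.rc, fg)
            self.Mr_bg = _match_site_matrix(self.rc, bg)
        self.codes = list(iupac.NON_N_CODES)  # 15, alphabetical
        self.Q = _code_indicator(self.codes)
        self.Qc = _code_indicator(self.codes, complement=True)

    def base_stats(self) -> EnrichmentStats:
        c0 = len(self.Mf_fg) + (0 if self.is_pal else len(self.Mr_fg))
        n0 = len(self.Mf_bg) + (0 if self.is_pal else len(self.Mr_bg))
        return enrichment_stats(c0, n0, self.L_fg, self.L_bg)

    def _counts(self, Mf, Mr, positions):
        k = len(positions)
        hf = _joint_hist(Mf, list(positions))
        mirror = [self.w - 1 - p for p in positions]
        hr = _joint_hist(Mr, mirror)
        A = hf
        for _ in range(k):
            A = np.tensordot(A, self.Q.T, axes=([0], [0]))
        B = hr
        for _ in range(k):
            B = np.tensordot(B, self.Qc.T, axes=([0], [0]))
        return A, B

    def score_combo(self, positions: tuple):
        """(cnt_fg, cnt_bg, F, Z) tensors over the (15,)*k code axes."""
        A_fg, B_fg = self._counts(self.Mf_fg, self.Mr_fg, positions)
        A_bg, B_bg = self._counts(self.Mf_bg, self.Mr_bg, positions)
        pal = _pal_axis_masks(self.pattern, positions, self.codes)
        if pal is False:
            cnt_fg = A_fg + B_fg
            cnt_bg = A_bg + B_bg
        else:
            cnt_fg = np.where(pal, A_fg, A_fg + B_fg)
            cnt_bg = np.where(pal, A_bg, A_bg + B_bg)
        _, F, Z = _enrichment_arrays(cnt_fg, cnt_bg, self.L_fg, self.L_bg)
        return cnt_fg, cnt_bg, F, Z

    def variant_pattern(self, positions, code_idx) -> str:
        letters = list(self.pattern)
        for p, ci in zip(positions, code_idx):
            letters[p] = self.codes[ci]
        return "".join(letters)


def _search_round(pattern: str, fg, bg, max_changed: int):
    """One exhaustive extension round; returns (best_pattern, best_stats).

    Falls back to the input pattern when no specialization strictly beats
    its z-score.
    """
    scorer = _ExtensionScorer(pattern, fg, bg)
    stats0 = scorer.base_stats()
    npos = [i for i, c in enumerate(pattern) if c == "N"]
    best_z = -np.inf
    best_pat = None
    best_counts = None
    for k in range(1, min(max_changed, len(npos)) + 1):
        for positions in itertools.combinations(npos, k):
            cnt_fg, cnt_bg, F, Z = scorer.score_combo(positions)
            zmax = Z.max()
            if zmax < best_z:
                continue
            ties = np.argwhere(Z == zmax)
            for idx in ties:
                pat = scorer.variant_pattern(positions, tuple(idx))
                if zmax > best_z or (zmax == best_z and pat < best_pat):
                    best_z = zmax
                    best_pat = pat
                    i = tuple(idx)
                    best_counts = (int(round(cnt_fg[i])), int(round(cnt_bg[i])))
    if best_pat is not None and best_z > stats0.Z:
        stats = enrichment_stats(
            best_counts[0], best_counts[1], scorer.L_fg, scorer.L_bg
        )
        return best_pat, stats
    return pattern, stats0


def _search_round_greedy(pattern: str, fg, bg, max_changed: int):
    """Greedy fallback: fix the best single-position change repeatedly."""
    stats = None
    for _ in range(max_changed):
        new_pattern, new_stats = _search_round(pattern, fg, bg, 1)
        if new_pattern == pattern:
            if stats is None:
                stats = new_stats
            break
        pattern, stats = new_pattern, new_stats
    if stats is None:
        stats = _ExtensionScorer(pattern, fg, bg).base_stats()
    return pattern, stats


def extend_core(
    core: GappedConsensus,
    fg: SequenceSet,
    bg: SequenceSet,
    max_changed: int = 3,
    large_threshold: int = 100_000,
    exact_limit: int = 5_000_000,
) -> GappedConsensus:
    """Pad a (degenerate) core and specialize non-informative positions.

    The padded consensus (span 19/20 by the parity of the core's gap) is
    searched exhaustively over all variants specializing at most
    ``max_changed`` N positions to non-N IUPAC codes; the max-Z variant is
    kept when it strictly beats the unextended padded core.  When the
    candidate count exceeds ``exact_limit`` a greedy one-change-at-a-time
    search is used instead.  The round is repeated once more when the
    foreground exceeds ``large_threshold`` nucleotides.
    """
    padded = pad_core(core)
    pattern = padded.pattern
    rounds = 2 if fg.total_length > large_threshold else 1
    for r in range(rounds):
        n_free = pattern.count("N")
        n_cand = sum(
            comb(n_free, k) * 15**k
            for k in range(1, min(max_changed, n_free) + 1)
        )
        if n_cand > exact_limit:
            pattern, stats = _search_round_greedy(pattern, fg, bg, max_changed)
        else:
            pattern, stats = _search_round(pattern, fg, bg, max_changed)
        logger.info(
            "extension round %d: %s (C=%d, F=%.3f, Z=%.3f)",
            r + 1, pattern, stats.C, stats.F, stats.Z,
        )
    return GappedConsensus(pattern)
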