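"""PWM refinement under a MAP objective with a Markov background.

Each extended consensus is turned into a position weight matrix by
scanning its occurrences in the foreground with one mismatch allowed and
keeping only the instances that raise a modified MAP (maximum a
posteriori) score.  The objective balances the information content of the
instance alignment against the likelihood of the instances under an
order-3 Markov model of the background:

    MAP = ln(w) * (ln(x_m)/w) * [ sum_ij p_ij ln p_ij
                                  - (1/x_m) sum_s ln p0(s) ]

where w is the motif width, x_m the instance count, p_ij the raw
per-position nucleotide frequencies of the instance sites and p0(s) the
background probability of site s given the three bases preceding it in
its source sequence.  The ln(w) factor compensates for the width
dependence of the inner score so that motifs of different lengths are
comparable.  Instance pruning is a single leave-one-out pass: an instance
is preserved iff the MAP score over all instances exceeds the MAP score
with that one instance removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .consensus import GappedConsensus, MotifInstance, count_instances
from .seq_io import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovBackground",
    "RefinedMotif",
    "fit_markov_background",
    "log_p0",
    "scan_instances",
    "map_score",
    "prune_instances",
    "refine_motif",
]

PWM_PSEUDOCOUNT = 0.25  # per cell, for the *reported* PWM only


@dataclass
class MarkovBackground:
    """Conditional nucleotide model of order k with start-of-sequence backoff.

    ``tables[k]`` has shape (4**k, 4): probability of each base given the
    k preceding bases (row-stochastic).  Lower-order tables serve
    positions closer than ``order`` bases to a sequence start.
    """

    order: int
    tables: list
    pseudocount: float = 1.0

    @classmethod
    def uniform(cls, order: int = 3) -> "MarkovBackground":
        tables = [np.full((4**k, 4), 0.25) for k in range(order + 1)]
        return cls(order=order, tables=tables, pseudocount=0.0)

    def cond_prob(self, context: str, base: str) -> float:
        k = min(len(context), self.order)
        ctx = context[len(context) - k :]
        idx = 0
        for ch in ctx:
            idx = idx * 4 + iupac.BASE_INDEX[ch]
        return float(self.tables[k][idx, iupac.BASE_INDEX[base]])


def fit_markov_background(
    bg: SequenceSet, order: int = 3, pseudocount: float = 1.0
) -> MarkovBackground:
    """Fit conditional base probabilities of orders 0..``order`` from ``bg``.

    Windows are counted on both strands; any window containing an N is
    skipped.  Each conditional distribution is smoothed with
    ``pseudocount`` per base.
    """
    # revcomp of encoded: A<->T (0<->3), C<->G (1<->2), N stays 4
    arrays = []
    for seq in bg:
        arr = seq.encoded.astype(np.int64)
        rc = np.where(arr[::-1] == 4, 4, 3 - arr[::-1])
        arrays.append(arr)
        arrays.append(rc)
    if not any((a < 4).any() for a in arrays):
        raise ValueError("background has no ACGT content")
    tables = []
    for k in range(order + 1):
        counts = np.zeros(4 ** (k + 1), dtype=np.int64)
        for arr in arrays:
            if len(arr) < k + 1:
                continue
            n = len(arr) - k
            idx = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for j in range(k + 1):
                win = arr[j : j + n]
                valid &= win < 4
                idx = idx * 4 + np.where(win < 4, win, 0)
            counts += np.bincount(idx[valid], minlength=4 ** (k + 1))
        counts = counts.reshape(4**k, 4).astype(np.float64)
        denom = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        tables.append((counts + pseudocount) / denom)
    return MarkovBackground(order=order, tables=tables, pseudocount=pseudocount)


def log_p0(bgm: MarkovBackground, site: str, left_context: str = "") -> float:
    """Natural-log background probability of ``site``.

    Each base is conditioned on the up-to-``order`` preceding bases, drawn
    first from ``left_context`` (the bases preceding the site in its
    source sequence, on the instance's strand) and then from the site
    itself; shorter contexts near a sequence start back off to the
    lower-order tables.
    """
    if any(ch not in "ACGT" for ch in site):
        raise ValueError("site must be over ACGT")
    if any(ch not in "ACGT" for ch in left_context):
        raise ValueError("left context must be over ACGT")
    lp = 0.0
    ctx = left_context
    for ch in site:
        lp += math.log(bgm.cond_prob(ctx, ch))
        ctx = (ctx + ch)[-bgm.order :] if bgm.order else ""
    return lp


def scan_instances(
    motif: GappedConsensus, fg: SequenceSet, max_mismatch: int = 1
) -> list:
    """Scan foreground occurrences of ``motif`` with mismatches allowed.

    Wraps :func:`count_instances` (both strands, palindrome dedup) and
    attaches the up-to-3-base left context on the instance's strand.
    Instances whose site or left context contains an N are dropped — they
    cannot be scored under the background model.
    """
    _, instances = count_instances(motif, fg, max_mismatch=max_mismatch)
    by_id = {s.identifier: s for s in fg}
    span = motif.span
    kept = []
    for inst in instances:
        seq = by_id[inst.sequence_id]
        if inst.strand == "+":
            ctx = seq.residues[max(0, inst.offset - 3) : inst.offset]
        else:
            tail = seq.residues[inst.offset + span : inst.offset + span + 3]
            ctx = iupac.reverse_complement(tail)
        if "N" in inst.site or "N" in ctx:
            continue
        inst.left_context = ctx
        kept.append(inst)
    return kept


def _site_counts(sites_idx: np.ndarray, w: int) -> np.ndarray:
    counts = np.zeros((w, 4))
    for i in range(w):
        counts[i] = np.bincount(sites_idx[:, i], minlength=4)
    return counts


def _map_from_stats(counts: np.ndarray, x: int, bg_sum: float, w: int) -> float:
    """Modified MAP from sufficient statistics (raw frequencies)."""
    if x <= 0:
        raise ValueError("MAP score needs at least one instance")
    p = counts / x
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0).sum()
    map_orig = (math.log(x) / w) * (ent - bg_sum / x)
    return math.log(w) * map_orig


def map_score(instances: list, bgm: MarkovBackground, w: int) -> float:
    """Modified MAP score of an instance set (natural logs throughout).

    ``p_ij`` uses raw frequencies with no pseudocount, so that identical
    sites on a uniform background give exactly ln(w)·ln(x_m)·ln(4).
    """
    if not instances:
        raise ValueError("MAP score needs at least one instance")
    if any(len(i.site) != w for i in instances):
        raise ValueError("all sites must have length w")
    sites_idx = np.stack([iupac.encode(i.site) for i in instances])
    counts = _site_counts(sites_idx, w)
    bg_sum = sum(log_p0(bgm, i.site, i.left_context) for i in instances)
    return _map_from_stats(counts, len(instances), bg_sum, w)


def prune_instances(instances: list, bgm: MarkovBackground, w: int):
    """Single leave-one-out pass of MAP-based instance pruning.

    Preserves instance i iff MAP(all) > MAP(all minus i), every test
    against the full set (no re-scanning, no iteration).  Returns
    ``(preserved, map_all)``.  The result is independent of instance
    order; a lone instance is always preserved.
    """
    x = len(instances)
    if x == 0:
        raise ValueError("no instances to prune")
    if x == 1:
        return list(instances), 0.0
    sites_idx = np.stack([iupac.encode(i.site) for i in instances])
    lp0 = np.array([log_p0(bgm, i.site, i.left_context) for i in instances])
    counts = _site_counts(sites_idx, w)
    bg_sum = float(lp0.sum())
    map_all = _map_from_stats(counts, x, bg_sum, w)
    preserved = []
    cache: dict = {}
    for inst, row, l in zip(instances, sites_idx, lp0):
        key = (inst.site, l)
        if key not in cache:
            cm = counts.copy()
            cm[np.arange(w), row] -= 1
            cache[key] = _map_from_stats(cm, x - 1, bg_sum - l, w)
        if map_all > cache[key]:
            preserved.append(inst)
    return preserved, map_all


@dataclass
class RefinedMotif:
    """A PWM with its preserved instance set and modified MAP score."""

    width: int
    pwm: np.ndarray
    instances: list
    x_m: int
    map_score: float
    source_consensus: GappedConsensus | None = None
    name: str | None = None
    fold: float | None = None
    zscore: float | None = None

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.shape != (self.width, 4):
            raise ValueError("PWM must have shape (width, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def consensus(self) -> str:
        if self.source_consensus is not None:
            return self.source_consensus.pattern
        return pwm_consensus(self.pwm)


def pwm_consensus(pwm: np.ndarray, threshold: float = 0.3) -> str:
    """IUPAC consensus of a PWM: code of the bases with freq >= threshold."""
    out = []
    for row in pwm:
        bases = frozenset(
            b for b, p in zip(iupac.BASES, row) if p >= threshold
        )
        if not bases:
            bases = frozenset([iupac.BASES[int(np.argmax(row))]])
        out.append(iupac._SET_TO_CODE[bases])
    return "".join(out)


def pwm_reverse_complement(pwm: np.ndarray) -> np.ndarray:
    return np.asarray(pwm)[::-1, ::-1]


def refine_motif(
    motif: GappedConsensus,
    fg: SequenceSet,
    bgm: MarkovBackground,
    max_mismatch: int = 1,
):
    """Refine an extended consensus into a :class:`RefinedMotif`.

    Flanking all-N columns are trimmed first (they carry no information
    and would dilute the MAP width term), then instances are scanned with
    ``max_mismatch`` and pruned by the leave-one-out MAP test.  The
    reported PWM adds a 0.25 pseudocount per cell to the preserved-site
    counts; the MAP score itself is computed on raw frequencies.  Returns
    ``None`` (with a logged warning) when the motif has no instances.
    """
    trimmed_pattern = motif.pattern.strip("N")
    if not trimmed_pattern:
        raise ValueError("motif has no informative positions")
    trimmed = GappedConsensus(trimmed_pattern)
    w = trimmed.span
    instances = scan_instances(trimmed, fg, max_mismatch=max_mismatch)
    if not instances:
        logger.warning("motif %s has no foreground instances; dropped", motif)
        return None
    preserved, _ = prune_instances(instances, bgm, w)
    if not preserved:
        logger.warning(
            "motif %s: no instance survived pruning; keeping all %d",
            motif, len(instances),
        )
        preserved = instances
    sites_idx = np.stack([iupac.encode(i.site) for i in preserved])
    counts = _site_counts(sites_idx, w)
    pwm = (counts + PWM_PSEUDOCOUNT) / (len(preserved) + 4 * PWM_PSEUDOCOUNT)
    score = map_score(preserved, bgm, w)
    return RefinedMotif(
        width=w,
        pwm=pwm,
        instances=preserved,
        x_m=len(preserved),
        map_score=score,
        source_consensus=trimmed,
    )
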