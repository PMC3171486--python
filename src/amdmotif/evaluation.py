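"""Motif-level accuracy measures for benchmarking discovery output.

Given an expected (reference) motif and an identified motif, the two PWMs
are aligned by the CompareACE similarity and the alignment is summarized
in column counts: TP — columns shared by both motifs in the alignment,
FP — identified-only columns, FN — expected-only columns.  The motif-level
sensitivity and specificity scale the similarity m by the covered
fraction of each motif:

    mSN = m * TP / (TP + FN)        mSP = m * TP / (TP + FP)

so a perfect match of equal widths gives mSN = mSP = m, and a short
identified motif inside a long expected one is penalized in mSN only.
Negative similarities are clamped to 0 (an accuracy cannot be negative).

The success rate of a tool on a collection of cases takes, per case, the
best CompareACE score of its top (at most three) reported motifs against
the expected motif and counts the fraction of cases at or above a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .redundancy import compare_ace

__all__ = ["AccuracyScores", "accuracy_scores", "success_rate"]


@dataclass
class AccuracyScores:
    m: float
    TP: int
    FP: int
    FN: int
    mSN: float
    mSP: float


def accuracy_scores(expected, identified, min_overlap: int = 6) -> AccuracyScores:
    """Motif-level accuracy of an identified PWM against an expected PWM."""
    try:
        aln = compare_ace(expected, identified, min_overlap=min_overlap)
    except ValueError:
        return AccuracyScores(m=0.0, TP=0, FP=0, FN=0, mSN=0.0, mSP=0.0)
    we = len(np.asarray(expected if not hasattr(expected, "pwm") else expected.pwm))
    wi = len(np.asarray(identified if not hasattr(identified, "pwm") else identified.pwm))
    tp = aln.overlap
    fp = wi - tp
    fn = we - tp
    m = max(aln.m, 0.0)
    msn = m * tp / (tp + fn)
    msp = m * tp / (tp + fp)
    return AccuracyScores(m=aln.m, TP=tp, FP=fp, FN=fn, mSN=msn, mSP=msp)


def success_rate(cases, cutoff: float):
    """Best-of-top-3 success rate over benchmark cases.

    ``cases`` is a sequence of ``(expected_pwm, identified_pwms)`` pairs
    with at most three identified motifs per case.  Per case the
    identified motif with the highest CompareACE score is selected; the
    case succeeds iff that score is at or above ``cutoff``.  Returns
    ``(rate, table)`` where ``table`` is a per-case DataFrame with the
    best score and its mSN/mSP (averaged by the caller across groups as
    needed).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("no cases supplied")
    rows = []
    for i, (expected, candidates) in enumerate(cases):
        candidates = list(candidates)[:3]
        best = None
        for cand in candidates:
            sc = accuracy_scores(expected, cand)
            if best is None or sc.m > best.m:
                best = sc
        if best is None:
            best = AccuracyScores(0.0, 0, 0, 0, 0.0, 0.0)
        rows.append(
            {
                "case": i,
                "m": best.m,
                "mSN": best.mSN,
                "mSP": best.mSP,
                "success": best.m >= cutoff,
            }
        )
    table = pd.DataFrame(rows)
    rate = float(table["success"].mean())
    return rate, table
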