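"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

import amdmotif as am
from amdmotif.iupac import CODE_SETS, reverse_complement


def random_set(rng, n, length, p_n=0.0, prefix="seq"):
    """Random A/C/G/T(/N) sequence set."""
    if p_n > 0:
        p = [(1 - p_n) / 4] * 4 + [p_n]
        mats = rng.choice(5, size=(n, length), p=p)
    else:
        mats = rng.choice(4, size=(n, length))
    return am.SequenceSet.from_strings(
        ["".join("ACGTN"[i] for i in row) for row in mats], prefix
    )


def brute_mismatches(pattern, window):
    """Mismatch count at informative positions, by direct definition."""
    mm = 0
    for pc, sc in zip(pattern, window):
        if pc == "N":
            continue
        if sc not in CODE_SETS[pc]:  # sequence N never matches a code
            mm += 1
    return mm


def brute_count(pattern, seqs, max_mismatch=0):
    """Naive both-strand scanner: every offset, both strands, palindrome
    scanned forward-only.  Independent of the package's scan code paths."""
    pats = [pattern]
    rc = reverse_complement(pattern)
    if rc != pattern:
        pats.append(rc)
    total = 0
    for seq in seqs:
        s = seq.residues
        for pat in pats:
            for off in range(len(s) - len(pat) + 1):
                if brute_mismatches(pat, s[off : off + len(pat)]) <= max_mismatch:
                    total += 1
    return total


def consensus_pwm(consensus, p=0.99):
    """Near-deterministic PWM for a concrete-base consensus."""
    M = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        M[i, "ACGT".index(b)] = p
    return M


@pytest.fixture(scope="session")
def uniform_bgm():
    return am.MarkovBackground.uniform(3)


@pytest.fixture(scope="session")
def ungapped_run():
    """Full pipeline on the contiguous planted-motif benchmark.

    TTGACGTCAA planted in 40% of 200x500 bp foreground sequences on a
    uniform background (4x foreground size), fixed seed.
    """
    spec = am.PlantSpec(motif="TTGACGTCAA", seed=42)
    fg, bg, truth = am.generate_dataset(spec)
    motifs = am.run_pipeline(fg, bg)
    return {
        "motifs": motifs,
        "truth": truth,
        "expected_pwm": consensus_pwm("TTGACGTCAA"),
        "fg": fg,
        "bg": bg,
    }


@pytest.fixture(scope="session")
def gapped_run():
    """Full pipeline on the gapped (GAL4-style) planted-motif benchmark."""
    planted = "CGG" + "N" * 11 + "CCG"
    spec = am.PlantSpec(motif=planted, seed=7)
    fg, bg, truth = am.generate_dataset(spec)
    motifs = am.run_pipeline(fg, bg)
    return {"motifs": motifs, "truth": truth, "planted": planted}
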