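"""IUPAC nucleotide alphabet tables shared across the package.

Sequences are stored internally as int8 arrays with A=0, C=1, G=2, T=3 and
N=4 (every non-ACGT input letter is folded to N).  Consensus patterns use
the 15 IUPAC ambiguity codes plus N; an N position in a *pattern* matches
any sequence base for free, whereas an N in a *sequence* never satisfies a
specified (non-N) pattern position.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_INDEX = 4

#: IUPAC code -> frozenset of concrete bases it allows
CODE_SETS: dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = sorted(CODE_SETS)  # deterministic (alphabetical) order
NON_N_CODES = [c for c in IUPAC_CODES if c != "N"]

_SET_TO_CODE = {v: k for k, v in CODE_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: code -> code whose base set is the complement set
COMPLEMENT_CODE = {
    c: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in s)]
    for c, s in CODE_SETS.items()
}

#: base -> the 8 IUPAC codes whose set contains that base (incl. base and N)
CONSISTENT_CODES = {
    b: tuple(sorted(c for c, s in CODE_SETS.items() if b in s)) for b in BASES
}

# match table: MATCH[code][symbol_index] for symbol in A,C,G,T,N.
# A pattern N matches everything (incl. sequence N); any other code never
# matches a sequence N.
MATCH = {}
for _c, _s in CODE_SETS.items():
    row = np.zeros(5, dtype=bool)
    for _b in _s:
        row[BASE_INDEX[_b]] = True
    if _c == "N":
        row[N_INDEX] = True
    MATCH[_c] = row
MATCH_BY_CODE_INDEX = np.stack([MATCH[c] for c in IUPAC_CODES])
CODE_INDEX = {c: i for i, c in enumerate(IUPAC_CODES)}

_ENCODE = np.full(256, N_INDEX, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGTN"))


def encode(residues: str) -> np.ndarray:
    """Encode a normalized A/C/G/T/N string as an int8 array."""
    return _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[arr])


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a nucleotide or IUPAC consensus string.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    Raises ``ValueError`` for characters outside the IUPAC alphabet.
    """
    out = []
    for ch in reversed(pattern):
        cu = ch.upper()
        if cu not in COMPLEMENT_CODE:
            raise ValueError(f"non-IUPAC character {ch!r}")
        out.append(COMPLEMENT_CODE[cu])
    return "".join(out)


def is_palindromic(pattern: str) -> bool:
    """True if the consensus equals its own reverse complement."""
    return pattern.upper() == reverse_complement(pattern)
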