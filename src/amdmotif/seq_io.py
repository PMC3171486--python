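"""Sequence containers, FASTA I/O and motif report writers.

Foreground and background sequence sets are the only inputs the discovery
pipeline needs.  Residues are normalized to uppercase A/C/G/T/N on ingest:
lowercase is folded to uppercase and every other IUPAC letter becomes N,
so that ambiguous input can never satisfy a specified consensus position.
Coordinates are 0-based half-open internally and in BED output.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TYPE_CHECKING

import numpy as np
from Bio import SeqIO

from . import iupac

if TYPE_CHECKING:  # pragma: no cover
    from .refine import RefinedMotif

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_IUPAC_LETTERS = set(iupac.IUPAC_CODES) | {"U"}


def normalize_residues(raw: str) -> str:
    """Uppercase and fold non-ACGT letters to N.

    Raises ``ValueError`` on characters that are not IUPAC nucleotide
    letters (catches accidentally passing protein or malformed input).
    """
    up = raw.upper()
    out = []
    for ch in up:
        if ch in _VALID:
            out.append(ch)
        elif ch in _IUPAC_LETTERS or ch == "-":
            out.append("N")
        else:
            raise ValueError(f"invalid residue {ch!r} in sequence")
    return "".join(out)


@dataclass
class Sequence:
    """A named DNA sequence over the A/C/G/T/N alphabet."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def encoded(self) -> np.ndarray:
        """int8 encoding (A=0..T=3, N=4); cached after first access."""
        enc = getattr(self, "_encoded", None)
        if enc is None:
            enc = iupac.encode(self.residues)
            object.__setattr__(self, "_encoded", enc)
        return enc


@dataclass
class SequenceSet:
    """Ordered collection of sequences with total-length accounting.

    ``total_length`` is the sum of all residue counts, N included — it is
    the L term of the length-proportional background expectation.
    """

    sequences: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.identifier for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence identifiers in set")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> Sequence:
        return self.sequences[i]

    def concat(self, other: "SequenceSet") -> "SequenceSet":
        return SequenceSet(list(self.sequences) + list(other.sequences))

    @classmethod
    def from_strings(
        cls, residues: Iterable[str], prefix: str = "seq"
    ) -> "SequenceSet":
        return cls(
            [Sequence(f"{prefix}{i}", r) for i, r in enumerate(residues)]
        )


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Record order is preserved; residues are normalized.  Empty records are
    retained with a warning (they contribute zero length).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path} does not look like FASTA")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            logger.warning("record with empty header in %s", path)
        if len(rec.seq) == 0:
            logger.warning("zero-length record %r in %s", rec.id, path)
        seqs.append(Sequence(rec.id, str(rec.seq)))
    return SequenceSet(seqs)


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n")
            for i in range(0, max(len(s), 1), width):
                fh.write(s.residues[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement of a nucleotide/IUPAC string (involution)."""
    return iupac.reverse_complement(s)


def write_meme_motifs(
    motifs: "list[RefinedMotif]", path: str | os.PathLike,
    background: tuple = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write PWMs in MEME minimal motif format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background)
        )
        for i, m in enumerate(motifs, start=1):
            name = m.name or f"motif_{i}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.x_m} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))
            fh.write("\n")


def write_motif_report(
    motifs: "list[RefinedMotif]", out_dir: str | os.PathLike
) -> dict:
    """Write the standard report triple for a ranked motif list.

    Produces ``motifs.meme`` (MEME minimal format), ``motifs.tsv``
    (rank, consensus, width, instance count, MAP score, fold, Z) and
    ``sites.bed`` (BED6 of preserved instances, 0-based half-open).
    Returns the mapping of report kind to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "meme": out_dir / "motifs.meme",
        "tsv": out_dir / "motifs.tsv",
        "bed": out_dir / "sites.bed",
    }
    write_meme_motifs(motifs, paths["meme"])
    with open(paths["tsv"], "w") as fh:
        fh.write("rank\tconsensus\twidth\tn_sites\tmap_score\tfold\tzscore\n")
        for rank, m in enumerate(motifs, start=1):
            fold = "" if m.fold is None else f"{m.fold:.4f}"
            z = "" if m.zscore is None else f"{m.zscore:.4f}"
            fh.write(
                f"{rank}\t{m.consensus}\t{m.width}\t{m.x_m}\t"
                f"{m.map_score:.6f}\t{fold}\t{z}\n"
            )
    with open(paths["bed"], "w") as fh:
        for rank, m in enumerate(motifs, start=1):
            name = m.name or f"motif_{rank}"
            for inst in m.instances:
                fh.write(
                    f"{inst.sequence_id}\t{inst.offset}\t"
                    f"{inst.offset + len(inst.site)}\t{name}\t0\t{inst.strand}\n"
                )
    return paths
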