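"""Seeded synthetic foreground/background datasets with planted motifs.

The generator emulates the discovery setting the pipeline is built for: a
background set drawn from a configurable sequence model (order-0 uniform
by default, or any fitted Markov background) and a foreground drawn from
the same model into which one motif instance is planted in a chosen
fraction of sequences — at a uniform random position, on a uniform random
strand, with an optional per-position mismatch rate.  IUPAC positions of
a consensus motif are sampled uniformly from their allowed bases; a PWM
motif is sampled per-column from its probabilities.  Every planted site
is recorded as ground truth.  Identical specs and seeds produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .consensus import GappedConsensus, MotifInstance
from .refine import MarkovBackground
from .seq_io import Sequence, SequenceSet

__all__ = ["PlantSpec", "generate_dataset"]


@dataclass
class PlantSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the planted-recovery benchmark used throughout the
    test suite: 200 foreground sequences of 500 bp, the motif planted in
    40% of them with no mismatches, and a uniform background four times
    the foreground size.  The enrichment z-score models the foreground as
    a length-proportional sample of the background, so the background set
    must be larger than the foreground for the variance term to be
    meaningful — hence the 4x default.
    """

    motif: object  # GappedConsensus | str | (w,4) PWM array
    planted_fraction: float = 0.4
    per_site_mismatch_rate: float = 0.0
    seed: int = 0
    n_seqs: int = 200
    seq_length: int = 500
    n_bg_seqs: int | None = None  # defaults to 4 * n_seqs
    background: MarkovBackground | None = None  # None = order-0 uniform
    instances_per_seq: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0.0 <= self.per_site_mismatch_rate <= 1.0:
            raise ValueError("per_site_mismatch_rate must be in [0, 1]")
        if isinstance(self.motif, str):
            self.motif = GappedConsensus(self.motif)


def _sample_background(
    rng: np.random.Generator, n: int, length: int, bgm: MarkovBackground | None
) -> list:
    if bgm is None:
        mat = rng.integers(0, 4, size=(n, length))
        return [iupac.decode(row) for row in mat]
    seqs = []
    for _ in range(n):
        out = []
        ctx = ""
        for _ in range(length):
            k = min(len(ctx), bgm.order)
            idx = 0
            for ch in ctx[len(ctx) - k :]:
                idx = idx * 4 + iupac.BASE_INDEX[ch]
            p = bgm.tables[k][idx]
            b = iupac.BASES[rng.choice(4, p=p)]
            out.append(b)
            ctx = (ctx + b)[-bgm.order :] if bgm.order else ""
        seqs.append("".join(out))
    return seqs


def _sample_site(rng: np.random.Generator, motif) -> str:
    if isinstance(motif, GappedConsensus):
        return "".join(
            sorted(iupac.CODE_SETS[c])[rng.integers(len(iupac.CODE_SETS[c]))]
            for c in motif.pattern
        )
    pwm = np.asarray(motif, dtype=np.float64)
    return "".join(iupac.BASES[rng.choice(4, p=row / row.sum())] for row in pwm)


def generate_dataset(spec: PlantSpec):
    """Generate ``(foreground, background, truth)`` for a plant spec.

    ``truth`` lists every planted site as a :class:`MotifInstance` with
    the site in motif orientation and the number of injected mismatches.
    """
    motif = spec.motif
    span = (
        motif.span if isinstance(motif, GappedConsensus) else len(np.asarray(motif))
    )
    if span > spec.seq_length:
        raise ValueError("motif span exceeds sequence length")
    rng = np.random.default_rng(spec.seed)
    n_bg = spec.n_bg_seqs if spec.n_bg_seqs is not None else 4 * spec.n_seqs
    bg_strings = _sample_background(rng, n_bg, spec.seq_length, spec.background)
    fg_strings = _sample_background(
        rng, spec.n_seqs, spec.seq_length, spec.background
    )
    n_planted = int(round(spec.planted_fraction * spec.n_seqs))
    planted_idx = rng.choice(spec.n_seqs, size=n_planted, replace=False)
    truth = []
    for si in sorted(int(i) for i in planted_idx):
        residues = fg_strings[si]
        for _ in range(spec.instances_per_seq):
            site = _sample_site(rng, motif)
            mism = 0
            if spec.per_site_mismatch_rate > 0:
                chars = list(site)
                for p in range(span):
                    if rng.random() < spec.per_site_mismatch_rate:
                        alt = [b for b in iupac.BASES if b != chars[p]]
                        chars[p] = alt[rng.integers(3)]
                        mism += 1
                site = "".join(chars)
            offset = int(rng.integers(0, spec.seq_length - span + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else iupac.reverse_complement(site)
            residues = residues[:offset] + inserted + residues[offset + span :]
            truth.append(
                MotifInstance(f"fg{si}", offset, strand, site, mismatches=mism)
            )
        fg_strings[si] = residues
    fg = SequenceSet([Sequence(f"fg{i}", s) for i, s in enumerate(fg_strings)])
    bg = SequenceSet([Sequence(f"bg{i}", s) for i, s in enumerate(bg_strings)])
    return fg, bg, truth
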