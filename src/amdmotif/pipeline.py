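"""End-to-end five-stage discovery workflow.

Order of stages: primary core filtering over the full gapped-consensus
space → degeneration of each primary core → extension → MAP refinement
against the order-3 background fitted from the background set →
redundancy removal.  Every stage runs on the full surviving list (near
duplicates are deduplicated only at the final redundancy step), and all
stages are deterministic given the inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from pathlib import Path

from .consensus import (
    CoreCounter,
    count_instances,
    enrichment_stats,
    select_primary_cores,
)
from .degenerate import extend_core, select_degenerate
from .redundancy import remove_redundant
from .refine import fit_markov_background, refine_motif
from .seq_io import SequenceSet, read_fasta, write_motif_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable thresholds of the workflow (defaults are the method's)."""

    min_fold: float = 1.2
    top_k_cores: int = 50
    max_gap: int = 14
    degeneration_max_changed: int = 4
    extension_max_changed: int = 3
    large_fg_threshold: int = 100_000
    scan_mismatch: int = 1
    redundancy_cutoff: float = 0.6
    markov_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_fold <= 0 or self.top_k_cores <= 0 or self.max_gap < 0:
            raise ValueError("invalid pipeline configuration")
        if self.scan_mismatch < 0 or self.markov_order < 0:
            raise ValueError("invalid pipeline configuration")
        if not 0 <= self.redundancy_cutoff <= 1:
            raise ValueError("redundancy cutoff must be in [0, 1]")


def _as_set(x) -> SequenceSet:
    if isinstance(x, SequenceSet):
        return x
    return read_fasta(x)


def run_pipeline(
    fg,
    bg,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> list:
    """Run discovery on a foreground/background pair.

    ``fg``/``bg`` may be :class:`SequenceSet` objects or FASTA paths.
    Returns the final motifs sorted by MAP score descending; when
    ``out_dir`` is given, also writes the MEME/TSV/BED report triple and a
    ``run_log.txt`` with the configuration and per-stage counts.
    """
    config = config or PipelineConfig()
    fg = _as_set(fg)
    bg = _as_set(bg)
    log_lines = [f"config: {dataclasses.asdict(config)}",
                 f"foreground: {len(fg)} sequences, {fg.total_length} nt",
                 f"background: {len(bg)} sequences, {bg.total_length} nt"]

    fgc, bgc = CoreCounter(fg), CoreCounter(bg)
    primaries = select_primary_cores(
        fgc, bgc,
        min_fold=config.min_fold,
        top_k=config.top_k_cores,
        max_gap=config.max_gap,
    )
    logger.info("stage 1: %d primary cores", len(primaries))
    log_lines.append(f"stage1_primary_cores: {len(primaries)}")
    if not primaries:
        log_lines.append("no core passed the fold-enrichment filter")
        _finish(out_dir, [], log_lines)
        return []

    bgm = fit_markov_background(bg, order=config.markov_order)

    refined = []
    for core, stats in primaries:
        deg, dstats = select_degenerate(
            core, stats, fgc, bgc, max_changed=config.degeneration_max_changed
        )
        ext = extend_core(
            deg, fg, bg,
            max_changed=config.extension_max_changed,
            large_threshold=config.large_fg_threshold,
        )
        motif = refine_motif(ext, fg, bgm, max_mismatch=config.scan_mismatch)
        logger.info(
            "core %s -> degenerate %s (Z=%.2f) -> extended %s -> %s",
            core, deg, dstats.Z, ext,
            "dropped" if motif is None else f"refined w={motif.width}",
        )
        if motif is None:
            continue
        c, _ = count_instances(motif.source_consensus, fg)
        n, _ = count_instances(motif.source_consensus, bg)
        es = enrichment_stats(c, n, fg.total_length, bg.total_length)
        motif.fold, motif.zscore = es.F, es.Z
        refined.append(motif)
    log_lines.append(f"stage4_refined_motifs: {len(refined)}")

    final = remove_redundant(refined, cutoff=config.redundancy_cutoff)
    for i, m in enumerate(final, start=1):
        m.name = f"motif_{i}"
        log_lines.append(
            f"motif_{i}: {m.consensus} w={m.width} x_m={m.x_m} "
            f"MAP={m.map_score:.4f} F={m.fold:.3f} Z={m.zscore:.3f}"
        )
    logger.info("stage 5: %d motifs after redundancy removal", len(final))
    log_lines.append(f"stage5_final_motifs: {len(final)}")
    _finish(out_dir, final, log_lines)
    return final


def _finish(out_dir, motifs, log_lines) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_motif_report(motifs, out_dir)
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
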