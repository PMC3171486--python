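"""scikit-learn style estimator facade over the discovery pipeline.

:class:`MotifDiscovery` fits on raw DNA sequences the way text
vectorizers fit on raw documents.  The foreground/background split can be
given either as a binary label vector ``y`` (1 = foreground) or by
passing the background to ``fit`` directly.  After fitting, ``motifs_``
holds the ranked :class:`~amdmotif.refine.RefinedMotif` list and
``transform`` maps sequences to per-motif occurrence counts, so the
estimator composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .consensus import count_instances
from .pipeline import PipelineConfig, run_pipeline
from .refine import fit_markov_background
from .seq_io import Sequence, SequenceSet

__all__ = ["MotifDiscovery"]


def _to_set(X, prefix: str = "seq") -> SequenceSet:
    if isinstance(X, SequenceSet):
        return X
    seqs = []
    for i, item in enumerate(X):
        if isinstance(item, Sequence):
            seqs.append(item)
        else:
            seqs.append(Sequence(f"{prefix}{i}", str(item)))
    return SequenceSet(seqs)


class MotifDiscovery(TransformerMixin, BaseEstimator):
    """De novo discovery of over-represented gapped/contiguous motifs.

    Parameters mirror the pipeline configuration: ``min_fold`` and
    ``top_k_cores`` control primary core filtering, ``max_gap`` the core
    space, ``degeneration_max_changed``/``extension_max_changed`` the
    stepwise consensus search, ``scan_mismatch`` the refinement scan,
    ``redundancy_cutoff`` the final similarity filter and ``markov_order``
    the background model.

    Examples
    --------
    >>> est = MotifDiscovery(max_gap=2)
    >>> est.fit(foreground_strings, background=background_strings)
    ... # doctest: +SKIP
    >>> est.motifs_[0].consensus  # doctest: +SKIP
    """

    def __init__(
        self,
        min_fold: float = 1.2,
        top_k_cores: int = 50,
        max_gap: int = 14,
        degeneration_max_changed: int = 4,
        extension_max_changed: int = 3,
        large_fg_threshold: int = 100_000,
        scan_mismatch: int = 1,
        redundancy_cutoff: float = 0.6,
        markov_order: int = 3,
    ):
        self.min_fold = min_fold
        self.top_k_cores = top_k_cores
        self.max_gap = max_gap
        self.degeneration_max_changed = degeneration_max_changed
        self.extension_max_changed = extension_max_changed
        self.large_fg_threshold = large_fg_threshold
        self.scan_mismatch = scan_mismatch
        self.redundancy_cutoff = redundancy_cutoff
        self.markov_order = markov_order

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            min_fold=self.min_fold,
            top_k_cores=self.top_k_cores,
            max_gap=self.max_gap,
            degeneration_max_changed=self.degeneration_max_changed,
            extension_max_changed=self.extension_max_changed,
            large_fg_threshold=self.large_fg_threshold,
            scan_mismatch=self.scan_mismatch,
            redundancy_cutoff=self.redundancy_cutoff,
            markov_order=self.markov_order,
        )

    def fit(self, X, y=None, background=None):
        """Discover motifs in a foreground against a background.

        Either pass ``background`` explicitly (then ``X`` is the
        foreground), or pass all sequences as ``X`` with binary labels
        ``y`` (nonzero/True = foreground).
        """
        if background is not None:
            fg = _to_set(X, "fg")
            bg = _to_set(background, "bg")
        elif y is not None:
            y = np.asarray(y).astype(bool)
            X = list(X)
            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            fg = _to_set([x for x, l in zip(X, y) if l], "fg")
            bg = _to_set([x for x, l in zip(X, y) if not l], "bg")
        else:
            raise ValueError("provide either y labels or background=")
        if len(fg) == 0 or len(bg) == 0:
            raise ValueError("foreground and background must be non-empty")
        self.motifs_ = run_pipeline(fg, bg, self._config())
        self.n_motifs_ = len(self.motifs_)
        self.background_model_ = fit_markov_background(
            bg, order=self.markov_order
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Per-sequence occurrence counts of each discovered motif."""
        if not hasattr(self, "motifs_"):
            raise ValueError("MotifDiscovery instance is not fitted yet")
        seqs = _to_set(X)
        out = np.zeros((len(seqs), self.n_motifs_), dtype=np.int64)
        for j, motif in enumerate(self.motifs_):
            for i, seq in enumerate(seqs):
                c, _ = count_instances(
                    motif.source_consensus,
                    SequenceSet([seq]),
                    max_mismatch=self.scan_mismatch,
                )
                out[i, j] = c
        return out

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "motifs_"):
            raise ValueError("MotifDiscovery instance is not fitted yet")
        return np.asarray([m.consensus for m in self.motifs_], dtype=object)
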