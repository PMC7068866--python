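"""Shared value types for the gene-network samplers.

A *genetic network* (or signature) is an ordered subset of genes evaluated as
one classifier input.  Many distinct networks can predict a binary phenotype
equally well; the samplers in this package draw large collections of them and
keep the high-accuracy ones.  The types below are the common currency those
samplers trade in.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "GeneticSignature",
    "AccuracyResult",
    "SamplerConfig",
    "SamplerResult",
    "FrequencyTable",
]


@dataclass(frozen=True)
class GeneticSignature:
    """An ordered set of distinct gene indices with its classification accuracy.

    Accuracy is a percentage in [0, 100]:
    ``100 * (n_evaluated - n_misclassified) / n_evaluated``.
    """

    genes: tuple[int, ...]
    accuracy: float
    iteration: int = -1

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("a signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene indices must be distinct")
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 100]")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AccuracyResult:
    """Outcome of one accuracy evaluation (LOOCV or blind validation)."""

    accuracy: float
    n_evaluated: int
    misclassified_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 100.0 * (self.n_evaluated - len(self.misclassified_sample_ids)) / self.n_evaluated
        if abs(expected - self.accuracy) > 1e-9:
            raise ValueError("accuracy inconsistent with misclassification count")


@dataclass
class SamplerConfig:
    """Tunable parameters shared by all samplers.

    Parameters
    ----------
    fold_change_threshold
        Minimum absolute difference of class means (log2 scale) for a gene to
        count as differentially expressed.
    fr_cutoff
        Fisher's-ratio cutoff; genes with FR strictly greater survive.  A gene
        passes FR > 0.8 exactly when its class centers are separated by more
        than sqrt(0.8) ~ 0.89 pooled standard deviations.
    fr_cutoff_relaxed
        Fallback cutoff applied automatically when fewer than ``relax_floor``
        genes survive the primary cutoff.
    fr_min_header
        Threshold splitting discriminatory genes into headers (FR above) and
        helpers (FR at or below).  ``"auto"`` uses the Fisher's ratio of the
        last gene of the minimum-scale signature.
    accuracy_threshold
        Percent accuracy above which a sampled network is retained.
    n_samples
        Number of networks drawn by the Fisher's-ratio and Random samplers.
    n_bags
        Number of train/validation bags drawn by the Holdout sampler.
    holdout_fraction
        Fraction of samples held out for validation in each bag.
    knn_k
        Neighbourhood size of the k-NN classifier (odd; 1 = nearest neighbour).
    prefix_cap
        Longest ranked-list prefix examined during recursive feature
        elimination (bounds runtime on very wide matrices).
    length_bounds
        Optional (min, max) network length; defaults to [1, minimum-scale
        signature length].
    pool_fr_cutoff
        Whether the Random sampler's gene pool applies the FR cutoff in
        addition to the fold-change filter.
    """

    fold_change_threshold: float = 1.0
    fr_cutoff: float = 0.8
    fr_cutoff_relaxed: float = 0.5
    relax_floor: int = 10
    fr_min_header: float | str = "auto"
    accuracy_threshold: float = 85.0
    n_samples: int = 100_000
    n_bags: int = 1000
    holdout_fraction: float = 0.25
    knn_k: int = 1
    rng_seed: int = 0
    prefix_cap: int = 200
    stratified: bool = True
    length_bounds: tuple[int, int] | None = None
    pool_fr_cutoff: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie strictly between 0 and 1")
        if not (0.0 <= self.accuracy_threshold <= 100.0):
            raise ValueError("accuracy_threshold must lie in [0, 100]")
        if self.fr_cutoff <= 0:
            raise ValueError("fr_cutoff must be positive")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")
        if self.n_samples < 1 or self.n_bags < 1:
            raise ValueError("n_samples and n_bags must be positive")
        if self.length_bounds is not None:
            lo, hi = self.length_bounds
            if not (1 <= lo <= hi):
                raise ValueError("length_bounds must satisfy 1 <= min <= max")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if d["length_bounds"] is not None:
            d["length_bounds"] = list(d["length_bounds"])
        return d


@dataclass
class SamplerResult:
    """Everything a sampler run produced.

    ``signatures`` holds only the retained networks (accuracy strictly above
    the configured threshold) — a sampled realisation of the uncertainty set
    of high-predictive networks.  ``draw_counts`` records how often each gene
    of the dataset was drawn *before* retention, which is what prior-
    correctness diagnostics look at.
    """

    sampler: str
    probe_ids: list[str]
    signatures: list[GeneticSignature]
    n_sampled: int
    draw_counts: np.ndarray
    accuracies: np.ndarray
    config: SamplerConfig
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.signatures)


@dataclass
class FrequencyTable:
    """Per-gene posterior sampling frequency over retained networks.

    Frequencies are shares of the total number of gene occurrences across all
    retained networks (the denominator is the sum of retained network
    lengths), so they sum to one.  Rows are ordered by descending frequency,
    ties broken by probe id.
    """

    probe_ids: list[str]
    counts: np.ndarray
    frequencies: np.ndarray
    sampler: str
    accuracy_threshold: float
    n_networks: int
    probe_space: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.probe_ids) != len(self.counts) or len(self.counts) != len(self.frequencies):
            raise ValueError("probe_ids, counts and frequencies must have equal length")
        if len(self.probe_ids) and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def top(self, n: int) -> list[str]:
        """The ``n`` highest-frequency probe ids, in rank order."""
        return list(self.probe_ids[:n])
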