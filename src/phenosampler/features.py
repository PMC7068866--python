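"""Feature selection: fold-change prefilter, Fisher's-ratio ranking and the
minimum-scale signature search.

For gene j with class centers mu_j1, mu_j2 and class dispersions s2_j1, s2_j2
the Fisher's ratio is

    FR_j = (mu_j1 - mu_j2)^2 / (s2_j1 + s2_j2)

High FR means large between-class separation relative to within-class spread.
Genes are first screened by absolute fold change (difference of class means on
the log2 scale), then by FR, and ranked by descending FR.  The *minimum-scale
signature* is the shortest prefix of that ranking attaining the maximum LOOCV
k-NN accuracy; it serves as a proxy for the complexity of the prediction
problem and bounds the length of the networks the samplers draw.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import loocv_prefix_profile
from .core import GeneticSignature, SamplerConfig
from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneStatistics",
    "RankedGeneList",
    "MinimumScaleSignature",
    "compute_gene_statistics",
    "filter_and_rank",
    "minimum_scale_signature",
]


@dataclass
class GeneStatistics:
    """Per-gene class means/variances, fold change and Fisher's ratio (arrays of length s)."""

    mu1: np.ndarray
    mu2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    fold_change: np.ndarray
    fisher_ratio: np.ndarray


@dataclass
class RankedGeneList:
    """Discriminatory genes ordered by descending Fisher's ratio.

    Ties are broken by descending absolute fold change, then probe id.  Every
    listed gene passes both the fold-change and the (possibly relaxed) FR
    threshold recorded here.
    """

    gene_indices: np.ndarray
    stats: GeneStatistics
    fold_change_threshold: float
    fr_cutoff: float
    relaxed: bool = False

    def __len__(self) -> int:
        return len(self.gene_indices)


@dataclass
class MinimumScaleSignature:
    """The shortest ranked prefix attaining maximal LOOCV accuracy.

    ``profile[i]`` is the LOOCV accuracy of the prefix of length i+1; the
    signature's length is the smallest argmax of this profile.
    """

    signature: GeneticSignature
    profile: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.signature)


def compute_gene_statistics(dataset: ExpressionDataset) -> GeneStatistics:
    """Class means, unbiased variances, log2 fold change and Fisher's ratio per gene.

    Degenerate genes (zero dispersion in both classes) get FR = +inf when the
    means differ — they separate perfectly — and FR = 0 when they coincide.
    """
    i1, i2 = dataset.class_indices(1), dataset.class_indices(2)
    if i1.size < 2 or i2.size < 2:
        raise ValueError("each class needs at least 2 samples for dispersion estimates")
    X1, X2 = dataset.values[:, i1], dataset.values[:, i2]
    mu1, mu2 = X1.mean(axis=1), X2.mean(axis=1)
    var1, var2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    denom = var1 + var2
    diff2 = (mu1 - mu2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(denom > 0, diff2 / np.where(denom > 0, denom, 1.0), np.where(diff2 > 0, np.inf, 0.0))
    return GeneStatistics(
        mu1=mu1, mu2=mu2, var1=var1, var2=var2,
        fold_change=mu1 - mu2, fisher_ratio=fr,
    )


def filter_and_rank(
    stats: GeneStatistics,
    config: SamplerConfig,
    probe_ids: list[str] | None = None,
) -> RankedGeneList:
    """Keep genes passing both screens and rank them by descending FR.

    A gene survives iff |fold_change| >= fold_change_threshold AND
    fisher_ratio > fr_cutoff (strict).  If fewer than ``config.relax_floor``
    genes survive, the FR cutoff is automatically relaxed to
    ``config.fr_cutoff_relaxed`` with a logged warning.
    """
    cutoff, relaxed = config.fr_cutoff, False
    fc_ok = np.abs(stats.fold_change) >= config.fold_change_threshold
    keep = fc_ok & (stats.fisher_ratio > cutoff)
    if keep.sum() < config.relax_floor and config.fr_cutoff_relaxed < cutoff:
        cutoff, relaxed = config.fr_cutoff_relaxed, True
        keep = fc_ok & (stats.fisher_ratio > cutoff)
        logger.warning(
            "only %d discriminatory genes at FR cutoff %.3g; relaxed to %.3g (%d genes)",
            (fc_ok & (stats.fisher_ratio > config.fr_cutoff)).sum(),
            config.fr_cutoff, cutoff, keep.sum(),
        )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            "no discriminatory genes survive the filters; "
            "lower fold_change_threshold or fr_cutoff"
        )
    if probe_ids is None:
        probe_ids = [str(i) for i in range(len(stats.fisher_ratio))]
    order = sorted(
        idx,
        key=lambda j: (-stats.fisher_ratio[j], -abs(stats.fold_change[j]), probe_ids[j]),
    )
    return RankedGeneList(
        gene_indices=np.asarray(order, dtype=np.int64),
        stats=stats,
        fold_change_threshold=config.fold_change_threshold,
        fr_cutoff=cutoff,
        relaxed=relaxed,
    )


def minimum_scale_signature(
    dataset: ExpressionDataset,
    ranked: RankedGeneList,
    config: SamplerConfig,
) -> MinimumScaleSignature:
    """Recursive backward feature elimination over the FR-ranked list.

    Evaluates the LOOCV k-NN accuracy of every nested prefix of the ranking
    (up to ``config.prefix_cap`` genes) — equivalent to repeatedly dropping
    the lowest-FR gene — and returns the shortest prefix attaining the global
    maximum accuracy.
    """
    if len(ranked) == 0:
        raise ValueError("ranked gene list is empty")
    L = min(len(ranked), config.prefix_cap)
    if L < len(ranked):
        logger.info("prefix search capped at %d of %d ranked genes", L, len(ranked))
    genes = ranked.gene_indices[:L]
    profile = loocv_prefix_profile(dataset.values, dataset.labels, genes, k=config.knn_k)
    best_len = int(np.argmax(profile)) + 1  # argmax returns the first (shortest) maximiser
    return MinimumScaleSignature(
        signature=GeneticSignature(
            genes=tuple(int(g) for g in genes[:best_len]),
            accuracy=float(profile[best_len - 1]),
        ),
        profile=profile,
    )
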