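"""Fisher's-ratio sampler (FRS).

Draws gene networks from a prior in which each gene's selection weight is
proportional to its Fisher's ratio.  The discriminatory genes are split into
*headers* (FR above a threshold FR_min — they carry the main discrimination)
and *helpers* (the rest — they add detail); every sampled network contains at
least one header, since helpers alone cannot reach high accuracy.  Each
network is scored by LOOCV k-NN accuracy and retained when that accuracy
exceeds the configured threshold, yielding a sampled realisation of the
uncertainty set of high-predictive networks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import loocv_accuracy
from .core import GeneticSignature, SamplerConfig, SamplerResult
from .datasets import ExpressionDataset
from .features import MinimumScaleSignature, RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["FisherPrior", "build_prior", "sample_network", "run_fisher_sampler"]


@dataclass
class FisherPrior:
    """FR-proportional sampling weights over the header and helper pools.

    Weights within each pool are positive and sum to one; ``header_cdf`` /
    ``helper_cdf`` are their cumulative sums, used for inverse-cdf draws.
    """

    header_indices: np.ndarray
    helper_indices: np.ndarray
    header_weights: np.ndarray
    helper_weights: np.ndarray
    fr_min: float

    @property
    def header_cdf(self) -> np.ndarray:
        return np.cumsum(self.header_weights)

    @property
    def helper_cdf(self) -> np.ndarray:
        return np.cumsum(self.helper_weights)

    @property
    def n_genes(self) -> int:
        return len(self.header_indices) + len(self.helper_indices)

    def draw(self, pool: str, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` distinct genes from one pool, probability ~ FR.

        Sampling without replacement; duplicates of earlier draws are
        effectively re-drawn (sequential renormalisation).
        """
        idx, w = (
            (self.header_indices, self.header_weights)
            if pool == "header"
            else (self.helper_indices, self.helper_weights)
        )
        return rng.choice(idx, size=size, replace=False, p=w)


def _fr_weights(fr: np.ndarray) -> np.ndarray:
    """Normalised FR-proportional weights; +inf sentinels dominate finitely."""
    fr = fr.astype(float).copy()
    if np.isinf(fr).any():
        finite = fr[np.isfinite(fr)]
        cap = 10.0 * finite.max() if finite.size else 1.0
        fr[np.isinf(fr)] = max(cap, 1.0)
    if fr.sum() <= 0:
        return np.full(fr.size, 1.0 / fr.size)
    return fr / fr.sum()


def build_prior(
    ranked: RankedGeneList,
    config: SamplerConfig,
    mss: MinimumScaleSignature | None = None,
) -> FisherPrior:
    """Split ranked genes into header/helper pools with FR-proportional weights.

    ``config.fr_min_header == "auto"`` resolves FR_min to the Fisher's ratio
    of the last (lowest-FR) gene of the minimum-scale signature, so headers
    coincide with the minimum-scale genes.
    """
    if len(ranked) == 0:
        raise ValueError("ranked gene list is empty")
    fr = ranked.stats.fisher_ratio[ranked.gene_indices]
    if config.fr_min_header == "auto":
        if mss is None:
            raise ValueError("fr_min_header='auto' requires a minimum-scale signature")
        fr_min = float(ranked.stats.fisher_ratio[mss.signature.genes[-1]])
        # headers = FR >= FR of the last minimum-scale gene (that gene included)
        is_header = fr >= fr_min
    else:
        fr_min = float(config.fr_min_header)
        is_header = fr > fr_min
    if not is_header.any():
        raise ValueError("header pool is empty; lower fr_min_header")
    headers = ranked.gene_indices[is_header]
    helpers = ranked.gene_indices[~is_header]
    return FisherPrior(
        header_indices=headers,
        helper_indices=helpers,
        header_weights=_fr_weights(fr[is_header]),
        helper_weights=_fr_weights(fr[~is_header]) if helpers.size else np.array([]),
        fr_min=fr_min,
    )


def sample_network(
    prior: FisherPrior,
    length_bounds: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one network: some headers and some helpers, weights ~ FR.

    The total length is uniform on the bounds; the header count is uniform on
    {1..min(length, #headers)}; the remainder is filled from the helper pool
    (capped at its size).  Headers come first in the returned index list.
    """
    lo, hi = length_bounds
    if not (1 <= lo <= hi <= prior.n_genes):
        raise ValueError(f"infeasible length bounds {length_bounds} for {prior.n_genes} genes")
    length = int(rng.integers(lo, hi + 1))
    n_head = int(rng.integers(1, min(length, len(prior.header_indices)) + 1))
    n_help = min(length - n_head, len(prior.helper_indices))
    parts = [prior.draw("header", n_head, rng)]
    if n_help > 0:
        parts.append(prior.draw("helper", n_help, rng))
    return np.concatenate(parts)


def run_fisher_sampler(
    dataset: ExpressionDataset,
    ranked: RankedGeneList,
    mss: MinimumScaleSignature,
    config: SamplerConfig,
) -> SamplerResult:
    """Draw ``config.n_samples`` networks from the Fisher prior and score each by LOOCV.

    Network lengths default to [1, len(minimum-scale signature)], floored at
    2 (when the pool allows) so that the header+helper mixing that defines
    this sampler stays realizable even when a single gene already attains the
    maximum accuracy.  Networks with accuracy strictly above
    ``config.accuracy_threshold`` are retained.  Fully reproducible from
    ``config.rng_seed``: each iteration gets its own spawned random substream.
    """
    prior = build_prior(ranked, config, mss)
    bounds = config.length_bounds or (1, min(max(len(mss), 2), prior.n_genes))
    streams = np.random.SeedSequence(config.rng_seed).spawn(config.n_samples)
    draw_counts = np.zeros(dataset.n_genes, dtype=np.int64)
    accuracies = np.empty(config.n_samples)
    retained: list[GeneticSignature] = []
    for i, ss in enumerate(streams):
        net = sample_network(prior, bounds, np.random.default_rng(ss))
        draw_counts[net] += 1
        acc = loocv_accuracy(dataset, net, k=config.knn_k).accuracy
        accuracies[i] = acc
        if acc > config.accuracy_threshold:
            retained.append(GeneticSignature(tuple(int(g) for g in net), acc, iteration=i))
    if not retained:
        logger.warning(
            "FRS retained no networks above %.1f%% accuracy", config.accuracy_threshold
        )
    return SamplerResult(
        sampler="FRS",
        probe_ids=dataset.probe_ids,
        signatures=retained,
        n_sampled=config.n_samples,
        draw_counts=draw_counts,
        accuracies=accuracies,
        config=config,
        extras={"fr_min": prior.fr_min, "length_bounds": bounds,
                "n_headers": len(prior.header_indices), "n_helpers": len(prior.helper_indices)},
    )
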