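"""Random sampler (RS).

The most explorative of the three samplers: gene networks of variable length
are drawn *uniformly* (without replacement) from the pool of differentially
expressed genes, with lengths bounded by the minimum-scale signature — the
problem's complexity proxy.  Each network is scored by LOOCV k-NN accuracy
and retained above the accuracy threshold, exactly as in the Fisher's-ratio
sampler; only the prior differs.
"""
from __future__ import annotations

import logging

import numpy as np

from .classify import loocv_accuracy
from .core import GeneticSignature, SamplerConfig, SamplerResult
from .datasets import ExpressionDataset
from .features import MinimumScaleSignature, RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["run_random_sampler"]


def run_random_sampler(
    dataset: ExpressionDataset,
    ranked: RankedGeneList,
    mss: MinimumScaleSignature,
    config: SamplerConfig,
) -> SamplerResult:
    """Draw ``config.n_samples`` uniform networks from the ranked pool and score by LOOCV.

    Length ~ Uniform{1..len(minimum-scale signature)} unless overridden by
    ``config.length_bounds``; genes uniform without replacement from the
    differentially-expressed pool.  Retains networks with accuracy strictly
    above ``config.accuracy_threshold``.  Seeded per-iteration substreams
    make the run reproducible.
    """
    if len(ranked) == 0:
        raise ValueError("ranked gene list is empty")
    if config.pool_fr_cutoff:
        pool = ranked.gene_indices
    else:
        # fold-change survivors only: drop the FR screen from the pool
        pool = np.flatnonzero(
            np.abs(ranked.stats.fold_change) >= ranked.fold_change_threshold
        )
    bounds = config.length_bounds or (1, max(1, min(len(mss), pool.size)))
    lo, hi = bounds
    if not (1 <= lo <= hi <= pool.size):
        raise ValueError(f"length bounds {bounds} exceed pool size {pool.size}")
    streams = np.random.SeedSequence(config.rng_seed).spawn(config.n_samples)
    draw_counts = np.zeros(dataset.n_genes, dtype=np.int64)
    accuracies = np.empty(config.n_samples)
    retained: list[GeneticSignature] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        length = int(rng.integers(lo, hi + 1))
        net = rng.choice(pool, size=length, replace=False)
        draw_counts[net] += 1
        acc = loocv_accuracy(dataset, net, k=config.knn_k).accuracy
        accuracies[i] = acc
        if acc > config.accuracy_threshold:
            retained.append(GeneticSignature(tuple(int(g) for g in net), acc, iteration=i))
    if not retained:
        logger.warning(
            "RS retained no networks above %.1f%% accuracy", config.accuracy_threshold
        )
    return SamplerResult(
        sampler="RS",
        probe_ids=dataset.probe_ids,
        signatures=retained,
        n_sampled=config.n_samples,
        draw_counts=draw_counts,
        accuracies=accuracies,
        config=config,
        extras={"length_bounds": bounds, "pool_size": int(pool.size)},
    )
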