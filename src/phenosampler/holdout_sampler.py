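"""Holdout sampler (HS).

Explores prediction uncertainty by perturbing the evidence: many random
75/25 train/validation partitions ("bags") of the samples.  In each bag the
full feature-selection pipeline — gene statistics, fold-change + FR filter,
minimum-scale signature search — runs on the training split alone, and the
resulting signature is scored by blind k-NN prediction of the validation
samples from the training samples.  Signatures whose validation accuracy
exceeds the threshold are retained.  Validation labels never influence
feature selection or the signature search.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import blind_validation_accuracy
from .core import AccuracyResult, GeneticSignature, SamplerConfig, SamplerResult
from .datasets import ExpressionDataset
from .features import (
    MinimumScaleSignature,
    compute_gene_statistics,
    filter_and_rank,
    minimum_scale_signature,
)

logger = logging.getLogger(__name__)

__all__ = ["HoldoutBag", "make_bags", "run_holdout_sampler"]


@dataclass
class HoldoutBag:
    """One random train/validation partition of the samples."""

    bag_id: int
    train_indices: np.ndarray
    valid_indices: np.ndarray
    signature: MinimumScaleSignature | None = None
    validation: AccuracyResult | None = None


def make_bags(
    dataset: ExpressionDataset,
    n_bags: int,
    fraction: float,
    rng: np.random.Generator,
    stratified: bool = True,
) -> list[HoldoutBag]:
    """Draw ``n_bags`` independent train/validation splits.

    Stratified mode (default) holds out ``floor(fraction * n_class)`` samples
    per class, at least one, so both splits always contain both classes.
    Training splits must keep >= 2 samples per class (variance estimates need
    them).  Bags are independent draws; samples never repeat within a bag.
    """
    if dataset.n_samples < 4:
        raise ValueError("need at least 4 samples to form holdout bags")
    bags: list[HoldoutBag] = []
    class_idx = {c: dataset.class_indices(c) for c in (1, 2)}
    if stratified:
        n_valid = {}
        for c, idx in class_idx.items():
            nv = max(1, int(np.floor(fraction * idx.size)))
            if idx.size - nv < 2:
                raise ValueError(
                    f"class {c} has {idx.size} samples; cannot keep 2 in training "
                    f"with {nv} held out"
                )
            n_valid[c] = nv
        for b in range(n_bags):
            tr, va = [], []
            for c, idx in class_idx.items():
                perm = rng.permutation(idx)
                va.append(perm[: n_valid[c]])
                tr.append(perm[n_valid[c]:])
            bags.append(
                HoldoutBag(b, np.sort(np.concatenate(tr)), np.sort(np.concatenate(va)))
            )
    else:
        nv = max(1, int(np.floor(fraction * dataset.n_samples)))
        for b in range(n_bags):
            perm = rng.permutation(dataset.n_samples)
            va, tr = perm[:nv], perm[nv:]
            labs_tr, labs_va = dataset.labels[tr], dataset.labels[va]
            if min((labs_tr == 1).sum(), (labs_tr == 2).sum()) < 2 or not (
                {1, 2} <= set(labs_va)
            ):
                raise ValueError(
                    "unstratified split left a class under-represented; "
                    "use stratified=True"
                )
            bags.append(HoldoutBag(b, np.sort(tr), np.sort(va)))
    return bags


def run_holdout_sampler(dataset: ExpressionDataset, config: SamplerConfig) -> SamplerResult:
    """Run the full holdout-bagging pipeline and retain high-accuracy signatures.

    Bags whose training split yields no discriminatory genes are skipped with
    a warning (recorded in ``extras['n_skipped']``), not treated as fatal.
    """
    rng = np.random.default_rng(config.rng_seed)
    bags = make_bags(
        dataset, config.n_bags, config.holdout_fraction, rng, stratified=config.stratified
    )
    draw_counts = np.zeros(dataset.n_genes, dtype=np.int64)
    accuracies: list[float] = []
    retained: list[GeneticSignature] = []
    n_skipped = 0
    for bag in bags:
        train = dataset.subset_samples(bag.train_indices)
        valid = dataset.subset_samples(bag.valid_indices)
        try:
            stats = compute_gene_statistics(train)
            ranked = filter_and_rank(stats, config, probe_ids=train.probe_ids)
        except ValueError as exc:
            logger.warning("bag %d skipped: %s", bag.bag_id, exc)
            n_skipped += 1
            continue
        bag.signature = minimum_scale_signature(train, ranked, config)
        genes = np.asarray(bag.signature.signature.genes)
        draw_counts[genes] += 1
        bag.validation = blind_validation_accuracy(train, valid, genes, k=config.knn_k)
        acc = bag.validation.accuracy
        accuracies.append(acc)
        if acc > config.accuracy_threshold:
            retained.append(
                GeneticSignature(tuple(int(g) for g in genes), acc, iteration=bag.bag_id)
            )
    if n_skipped:
        logger.warning("%d of %d bags skipped (no discriminatory genes)", n_skipped, len(bags))
    return SamplerResult(
        sampler="HS",
        probe_ids=dataset.probe_ids,
        signatures=retained,
        n_sampled=len(bags) - n_skipped,
        draw_counts=draw_counts,
        accuracies=np.asarray(accuracies),
        config=config,
        extras={"n_bags": len(bags), "n_skipped": n_skipped, "bags": bags},
    )
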