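"""Posterior gene-frequency analysis over retained high-accuracy networks.

Each sampler produces a collection of networks whose accuracy exceeds the
retention threshold.  A gene's posterior sampling frequency is its share of
all gene occurrences across those networks (denominator = sum of retained
network lengths).  Ranking genes by this frequency yields the discriminatory
gene list a user would submit to an ontology/pathway tool, and comparing the
top of the lists across samplers quantifies how sampler-independent — how
"biologically invariant" — the inferred signal is.
"""
from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .core import FrequencyTable, SamplerResult

logger = logging.getLogger(__name__)

__all__ = ["gene_frequencies", "apply_frequency_threshold", "sampler_concordance", "merge_results"]


def gene_frequencies(result: SamplerResult) -> FrequencyTable:
    """Per-gene occurrence frequency over the retained networks.

    Only genes appearing in at least one retained network are listed; rows
    are ordered by descending frequency, ties broken lexicographically by
    probe id.
    """
    if result.n_retained == 0:
        raise ValueError(
            "no retained networks; raise n_samples or lower the accuracy threshold"
        )
    counts: Counter[int] = Counter()
    total = 0
    for sig in result.signatures:
        counts.update(sig.genes)
        total += len(sig.genes)
    order = sorted(counts, key=lambda g: (-counts[g], result.probe_ids[g]))
    cnt = np.array([counts[g] for g in order], dtype=np.int64)
    return FrequencyTable(
        probe_ids=[result.probe_ids[g] for g in order],
        counts=cnt,
        frequencies=cnt / total,
        sampler=result.sampler,
        accuracy_threshold=result.config.accuracy_threshold,
        n_networks=result.n_retained,
        probe_space=frozenset(result.probe_ids),
    )


def apply_frequency_threshold(
    table: FrequencyTable, threshold: float | int | str = "top-30"
) -> list[str]:
    """Genes at/above a frequency threshold, or the top N, in rank order.

    ``threshold`` may be a float frequency, an integer N, or a string
    ``"top-N"``.  The returned list is what feeds external pathway analysis.
    """
    if len(table) == 0:
        raise ValueError("frequency table is empty")
    if isinstance(threshold, str):
        if not threshold.startswith("top-"):
            raise ValueError(f"unrecognised threshold {threshold!r}")
        n = int(threshold[4:])
        return table.top(n)
    if isinstance(threshold, (int, np.integer)) and not isinstance(threshold, bool):
        return table.top(int(threshold))
    keep = [p for p, f in zip(table.probe_ids, table.frequencies) if f >= threshold]
    if not keep:
        logger.warning("frequency threshold %.4g excludes every gene", threshold)
    return keep


def sampler_concordance(tables: list[FrequencyTable], n_top: int = 30) -> dict:
    """Pairwise top-N overlap/Jaccard between samplers plus the global intersection.

    All tables must come from the same probe space.  The all-sampler
    intersection of top-N lists is the package's quantitative handle on the
    sampler-independence of the inferred discriminatory genes.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 frequency tables")
    spaces = {t.probe_space for t in tables if t.probe_space is not None}
    if len(spaces) > 1:
        raise ValueError("frequency tables come from different probe spaces")
    tops = {t.sampler: set(t.top(n_top)) for t in tables}
    pairwise = {}
    names = [t.sampler for t in tables]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = tops[names[i]], tops[names[j]]
            inter, union = len(a & b), len(a | b)
            pairwise[f"{names[i]}|{names[j]}"] = {
                "overlap": inter,
                "jaccard": inter / union if union else 1.0,
            }
    common = set.intersection(*tops.values())
    return {
        "n_top": n_top,
        "pairwise": pairwise,
        "intersection": sorted(common),
        "intersection_size": len(common),
    }


def merge_results(a: SamplerResult, b: SamplerResult) -> SamplerResult:
    """Concatenate two runs over the same probe space into one result.

    Gene frequencies of the merged result equal the count-wise sum of the two
    tables before normalisation.
    """
    if a.probe_ids != b.probe_ids:
        raise ValueError("results cover different probe spaces")
    return SamplerResult(
        sampler=a.sampler if a.sampler == b.sampler else f"{a.sampler}+{b.sampler}",
        probe_ids=a.probe_ids,
        signatures=a.signatures + b.signatures,
        n_sampled=a.n_sampled + b.n_sampled,
        draw_counts=a.draw_counts + b.draw_counts,
        accuracies=np.concatenate([a.accuracies, b.accuracies]),
        config=a.config,
        extras={"merged_from": [a.sampler, b.sampler]},
    )
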