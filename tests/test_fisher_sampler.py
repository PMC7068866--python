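"""Fisher's-ratio sampler: prior construction, network draws, retention."""
import numpy as np
import pytest
from scipy import stats as sps

from phenosampler import (
    SamplerConfig,
    build_prior,
    compute_gene_statistics,
    filter_and_rank,
    minimum_scale_signature,
    run_fisher_sampler,
    sample_network,
)
from phenosampler.features import GeneStatistics, MinimumScaleSignature, RankedGeneList
from phenosampler.core import GeneticSignature


def _ranked(fr_values):
    fr = np.asarray(fr_values, float)
    fc = np.full_like(fr, 2.0)
    ones = np.ones_like(fc)
    stats = GeneStatistics(mu1=fc, mu2=np.zeros_like(fr), var1=ones, var2=ones,
                           fold_change=fc, fisher_ratio=fr)
    order = np.argsort(-fr, kind="stable")
    return RankedGeneList(gene_indices=order, stats=stats,
                          fold_change_threshold=1.0, fr_cutoff=0.8)


def _mss(genes, acc=100.0):
    return MinimumScaleSignature(signature=GeneticSignature(tuple(genes), acc))


def test_two_headers_weights_are_proportional():
    ranked = _ranked([3.0, 1.0])
    prior = build_prior(ranked, SamplerConfig(fr_min_header=0.5))
    np.testing.assert_allclose(prior.header_weights, [0.75, 0.25])
    assert len(prior.helper_indices) == 0


def test_equal_fr_gives_uniform_weights():
    ranked = _ranked([2.0] * 8)
    prior = build_prior(ranked, SamplerConfig(fr_min_header=0.5))
    np.testing.assert_allclose(prior.header_weights, np.full(8, 1 / 8))


def test_auto_fr_min_headers_are_minimum_scale_genes():
    ranked = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
    prior = build_prior(ranked, SamplerConfig(), mss=_mss([0, 1]))
    assert set(prior.header_indices) == {0, 1}
    assert set(prior.helper_indices) == {2, 3, 4}
    assert prior.header_cdf[-1] == pytest.approx(1.0)


def test_empty_header_pool_is_error():
    ranked = _ranked([1.0, 2.0])
    with pytest.raises(ValueError, match="header"):
        build_prior(ranked, SamplerConfig(fr_min_header=10.0))


def test_infinite_fr_dominates_but_stays_finite_weight():
    ranked = _ranked([np.inf, 4.0, 2.0])
    prior = build_prior(ranked, SamplerConfig(fr_min_header=1.0))
    assert np.isfinite(prior.header_weights).all()
    assert prior.header_weights[0] > prior.header_weights[1] > prior.header_weights[2]


def test_prior_draw_frequencies_match_weights():
    rng = np.random.default_rng(99)
    fr = rng.uniform(1.0, 6.0, size=50)
    ranked = _ranked(fr)
    prior = build_prior(ranked, SamplerConfig(fr_min_header=0.5))
    n = 20_000
    draws = rng.choice(prior.header_indices, size=n, p=prior.header_weights)
    counts = np.bincount(draws, minlength=50)[prior.header_indices]
    chi2, p = sps.chisquare(counts, f_exp=prior.header_weights * n)
    assert p > 0.01


def test_sample_network_forced_and_deterministic():
    ranked = _ranked([3.0, 1.0, 0.9])
    prior = build_prior(ranked, SamplerConfig(fr_min_header=2.0))
    net = sample_network(prior, (1, 1), np.random.default_rng(0))
    assert list(net) == [0]  # single-header pool, length 1 -> forced
    a = [sample_network(prior, (1, 3), np.random.default_rng(5)) for _ in range(20)]
    b = [sample_network(prior, (1, 3), np.random.default_rng(5)) for _ in range(20)]
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    for net in a:
        assert len(set(net.tolist())) == len(net)  # no duplicate genes
        assert net[0] in prior.header_indices  # at least one header, listed first


def test_infeasible_bounds_error():
    ranked = _ranked([3.0, 1.0])
    prior = build_prior(ranked, SamplerConfig(fr_min_header=0.5))
    with pytest.raises(ValueError, match="bounds"):
        sample_network(prior, (1, 5), np.random.default_rng(0))


def _pipeline(dataset, config):
    stats = compute_gene_statistics(dataset)
    ranked = filter_and_rank(stats, config, probe_ids=dataset.probe_ids)
    mss = minimum_scale_signature(dataset, ranked, config)
    return ranked, mss


def test_retained_networks_contain_planted_gene(planted, small_config):
    dataset, truth, _ = planted
    ranked, mss = _pipeline(dataset, small_config)
    result = run_fisher_sampler(dataset, ranked, mss, small_config)
    truth_set = set(truth.tolist())
    assert result.n_retained > 0
    for sig in result.signatures:
        assert truth_set & set(sig.genes)
        assert sig.accuracy > small_config.accuracy_threshold


def test_threshold_semantics(planted):
    dataset, _, _ = planted
    cfg0 = SamplerConfig(n_samples=200, rng_seed=3, accuracy_threshold=0.0)
    ranked, mss = _pipeline(dataset, cfg0)
    assert run_fisher_sampler(dataset, ranked, mss, cfg0).n_retained == 200

    cfg100 = SamplerConfig(n_samples=50, rng_seed=3, accuracy_threshold=100.0,
                           fold_change_threshold=0.0, fr_cutoff=1e-9, fr_cutoff_relaxed=1e-9)
    rng = np.random.default_rng(0)
    noise = dataset.values[rng.permutation(dataset.n_genes)][:, rng.permutation(dataset.n_samples)]
    # permuted labels make the data pure noise; threshold 100 retains nothing, no error
    from phenosampler import ExpressionDataset
    null = ExpressionDataset(dataset.probe_ids, dataset.sample_ids, noise,
                             rng.permutation(dataset.labels))
    ranked_n, mss_n = _pipeline(null, cfg100)
    result = run_fisher_sampler(null, ranked_n, mss_n, cfg100)
    assert result.n_retained == 0  # warning, not error


def test_same_seed_reproduces_run(planted, small_config):
    dataset, _, _ = planted
    ranked, mss = _pipeline(dataset, small_config)
    a = run_fisher_sampler(dataset, ranked, mss, small_config)
    b = run_fisher_sampler(dataset, ranked, mss, small_config)
    assert [s.genes for s in a.signatures] == [s.genes for s in b.signatures]
    np.testing.assert_array_equal(a.draw_counts, b.draw_counts)
    np.testing.assert_array_equal(a.accuracies, b.accuracies)


def test_header_frequency_dominates_helpers(planted):
    dataset, truth, _ = planted
    cfg = SamplerConfig(n_samples=2000, rng_seed=13, accuracy_threshold=0.0)
    ranked, mss = _pipeline(dataset, cfg)
    result = run_fisher_sampler(dataset, ranked, mss, cfg)
    from phenosampler import build_prior as bp, gene_frequencies

    prior = bp(ranked, cfg, mss)
    table = gene_frequencies(result)
    freq = dict(zip(table.probe_ids, table.frequencies))
    head = [freq.get(dataset.probe_ids[g], 0.0) for g in prior.header_indices]
    helpers = [freq.get(dataset.probe_ids[g], 0.0) for g in prior.helper_indices]
    if helpers:
        assert min(head) >= max(helpers) - 1e-12
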