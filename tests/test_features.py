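"""Fisher's-ratio statistics, the two-stage filter and the minimum-scale search."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenosampler import (
    ExpressionDataset,
    GeneStatistics,
    SamplerConfig,
    compute_gene_statistics,
    filter_and_rank,
    loocv_prefix_profile,
    minimum_scale_signature,
)
from conftest import oracle_fisher_ratio, oracle_loocv


def _ds(values, labels, probes=None):
    values = np.asarray(values, float)
    return ExpressionDataset(
        probe_ids=probes or [f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        values=values,
        labels=np.asarray(labels),
    )


def test_fisher_ratio_forced_arithmetic():
    # class means 1 and 3, both variances 1  ->  FR = (1-3)^2 / (1+1) = 2
    d = np.sqrt(0.5)
    ds = _ds([[1 - d, 1 + d, 3 - d, 3 + d]], [1, 1, 2, 2])
    stats = compute_gene_statistics(ds)
    assert stats.fisher_ratio[0] == pytest.approx(2.0, abs=1e-12)
    assert stats.fold_change[0] == pytest.approx(-2.0, abs=1e-12)


def test_degenerate_genes():
    ds = _ds(
        [
            [5.0, 5.0, 5.0, 5.0],  # identical everywhere -> FR 0
            [1.0, 1.0, 2.0, 2.0],  # zero variance, distinct means -> +inf sentinel
        ],
        [1, 1, 2, 2],
    )
    stats = compute_gene_statistics(ds)
    assert stats.fisher_ratio[0] == 0.0
    assert stats.fisher_ratio[1] == np.inf


def test_class_with_one_sample_rejected():
    ds = _ds([[0.0, 1.0, 2.0]], [1, 2, 2])
    with pytest.raises(ValueError, match="2 samples"):
        compute_gene_statistics(ds)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_fisher_ratio_label_swap_invariance(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(6, 9))
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2, 2])
    a = compute_gene_statistics(_ds(values, labels)).fisher_ratio
    b = compute_gene_statistics(_ds(values, 3 - labels)).fisher_ratio
    np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)


def test_fisher_ratio_matches_direct_oracle():
    rng = np.random.default_rng(11)
    values = rng.normal(size=(20, 10))
    labels = np.array([1] * 5 + [2] * 5)
    got = compute_gene_statistics(_ds(values, labels)).fisher_ratio
    np.testing.assert_allclose(got, oracle_fisher_ratio(values, labels), rtol=0, atol=1e-12)


def _stats(fr, fc=None):
    fr = np.asarray(fr, float)
    fc = np.full_like(fr, 2.0) if fc is None else np.asarray(fc, float)
    z = np.zeros_like(fr)
    return GeneStatistics(mu1=fc, mu2=z, var1=z + 1, var2=z + 1, fold_change=fc, fisher_ratio=fr)


def test_fr_cutoff_is_strict():
    # FR exactly 0.8 is excluded ("greater than")
    stats = _stats([0.8, 0.81, 3.0] + [0.79] * 12)
    cfg = SamplerConfig(relax_floor=1)
    ranked = filter_and_rank(stats, cfg)
    assert set(ranked.gene_indices) == {1, 2}
    assert ranked.gene_indices[0] == 2  # descending FR


def test_mean_separation_multiplier():
    # FR > 0.8 is the same condition as |mu1-mu2| > sqrt(0.8)*sqrt(var1+var2),
    # and sqrt(0.8) rounds to the 0.89 multiplier
    assert round(np.sqrt(0.8), 2) == 0.89
    rng = np.random.default_rng(5)
    mu_diff = rng.uniform(-3, 3, 500)
    var_sum = rng.uniform(0.5, 5, 500)
    fr = mu_diff**2 / var_sum
    accepted = fr > 0.8
    implied = np.abs(mu_diff) > np.sqrt(0.8) * np.sqrt(var_sum)
    np.testing.assert_array_equal(accepted, implied)


def test_relaxation_to_half(caplog):
    stats = _stats([0.6, 0.55, 0.7, 0.3])
    cfg = SamplerConfig()  # floor 10 > 0 survivors at 0.8
    with caplog.at_level("WARNING"):
        ranked = filter_and_rank(stats, cfg)
    assert ranked.relaxed and ranked.fr_cutoff == 0.5
    assert set(ranked.gene_indices) == {0, 1, 2}


def test_zero_survivors_is_error():
    stats = _stats([0.1, 0.2])
    with pytest.raises(ValueError, match="threshold|cutoff"):
        filter_and_rank(stats, SamplerConfig())


def test_fold_change_screen_applies():
    stats = _stats([5.0, 5.0], fc=[2.0, 0.1])
    ranked = filter_and_rank(stats, SamplerConfig(relax_floor=1))
    assert list(ranked.gene_indices) == [0]


def test_planted_genes_exactly_survive(planted, small_config):
    dataset, truth, _ = planted
    stats = compute_gene_statistics(dataset)
    ranked = filter_and_rank(stats, small_config, probe_ids=dataset.probe_ids)
    assert set(ranked.gene_indices) == set(truth)
    fr = stats.fisher_ratio[ranked.gene_indices]
    assert np.all(np.diff(fr) <= 1e-12)  # non-increasing


def test_minimum_scale_forced_single_gene(tiny_dataset, small_config):
    stats = compute_gene_statistics(tiny_dataset)
    ranked = filter_and_rank(stats, SamplerConfig(relax_floor=1))
    mss = minimum_scale_signature(tiny_dataset, ranked, small_config)
    assert len(mss) == 1
    assert mss.signature.accuracy == 100.0
    assert mss.signature.genes == (0,)


def test_prefix_profile_matches_exhaustive_oracle(planted, small_config):
    dataset, _, _ = planted
    stats = compute_gene_statistics(dataset)
    ranked = filter_and_rank(stats, small_config, probe_ids=dataset.probe_ids)
    profile = loocv_prefix_profile(dataset.values, dataset.labels, ranked.gene_indices, k=1)
    expected = [
        oracle_loocv(dataset.values, dataset.labels, ranked.gene_indices[: i + 1], 1)
        for i in range(len(ranked))
    ]
    np.testing.assert_allclose(profile, expected, rtol=0, atol=1e-12)
    mss = minimum_scale_signature(dataset, ranked, small_config)
    best = max(expected)
    assert mss.signature.accuracy == best
    assert len(mss) == 1 + min(i for i, a in enumerate(expected) if a == best)


def test_all_noise_accuracy_near_majority_rate():
    rng = np.random.default_rng(23)
    values = rng.normal(size=(30, 40))
    labels = np.array([1] * 25 + [2] * 15)
    ds = _ds(values, labels)
    stats = compute_gene_statistics(ds)
    cfg = SamplerConfig(fold_change_threshold=0.0, fr_cutoff=1e-9, fr_cutoff_relaxed=1e-9)
    ranked = filter_and_rank(stats, cfg)
    mss = minimum_scale_signature(ds, ranked, cfg)
    # selection bias inflates the best prefix, but it cannot approach perfect separation
    assert mss.signature.accuracy < 100.0
    # long prefixes of pure noise hover near chance for the majority class (62.5%)
    assert mss.profile[-1] < 85.0


def test_removing_non_signature_gene_preserves_signature(planted, small_config):
    dataset, truth, _ = planted
    stats = compute_gene_statistics(dataset)
    ranked = filter_and_rank(stats, small_config, probe_ids=dataset.probe_ids)
    mss = minimum_scale_signature(dataset, ranked, small_config)
    sig_probes = [dataset.probe_ids[g] for g in mss.signature.genes]

    drop = next(i for i in range(dataset.n_genes) if i not in set(mss.signature.genes))
    keep = [i for i in range(dataset.n_genes) if i != drop]
    reduced = ExpressionDataset(
        probe_ids=[dataset.probe_ids[i] for i in keep],
        sample_ids=dataset.sample_ids,
        values=dataset.values[keep],
        labels=dataset.labels,
    )
    stats2 = compute_gene_statistics(reduced)
    ranked2 = filter_and_rank(stats2, small_config, probe_ids=reduced.probe_ids)
    mss2 = minimum_scale_signature(reduced, ranked2, small_config)
    assert [reduced.probe_ids[g] for g in mss2.signature.genes] == sig_probes
    assert mss2.signature.accuracy == mss.signature.accuracy
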