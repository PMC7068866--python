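import numpy as np
import pytest

from phenosampler import ExpressionDataset, SamplerConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def planted():
    """Small planted dataset: 200 genes, 5 truly discriminatory, 20+20 samples."""
    spec = SyntheticSpec(
        n_genes=200, n_samples_per_class=(20, 20), n_planted=5, effect_size=3.0, rng_seed=42
    )
    dataset, truth = generate(spec)
    return dataset, truth, spec


@pytest.fixture
def small_config():
    return SamplerConfig(n_samples=500, n_bags=50, rng_seed=7)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, gene 0 separates the classes perfectly."""
    return ExpressionDataset(
        probe_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [0.0, 0.2, 5.0, 5.2],
                [1.0, 1.1, 1.0, 1.1],
                [3.0, 2.0, 2.5, 3.5],
            ]
        ),
        labels=np.array([1, 1, 2, 2]),
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive; never reuse package code)
# ---------------------------------------------------------------------------

def oracle_fisher_ratio(values, labels):
    """Direct per-gene evaluation of the Fisher's-ratio formula."""
    out = np.empty(values.shape[0])
    for j in range(values.shape[0]):
        x1 = values[j, labels == 1]
        x2 = values[j, labels == 2]
        num = (x1.mean() - x2.mean()) ** 2
        den = x1.var(ddof=1) + x2.var(ddof=1)
        if den == 0:
            out[j] = np.inf if num > 0 else 0.0
        else:
            out[j] = num / den
    return out


def oracle_knn_predict(train_X, train_labels, x, k):
    """Exhaustive k-NN prediction of one sample; ties to smallest train index / class 1."""
    d = [(float(np.sum((train_X[i] - x) ** 2)), i) for i in range(len(train_X))]
    d.sort()  # distance then index: smallest index wins on distance ties
    votes = [train_labels[i] for _, i in d[:k]]
    n1 = sum(1 for v in votes if v == 1)
    return 1 if n1 >= k - n1 else 2


def oracle_loocv(values, labels, signature, k):
    """O(n^2) exhaustive LOOCV accuracy over the signature's genes."""
    X = values[np.asarray(signature)].T
    n = len(labels)
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        pred = oracle_knn_predict(X[mask], labels[mask], X[i], k)
        if pred == labels[i]:
            correct += 1
    return 100.0 * correct / n


def oracle_blind(train_values, train_labels, valid_values, valid_labels, signature, k):
    sig = np.asarray(signature)
    Xt, Xv = train_values[sig].T, valid_values[sig].T
    correct = sum(
        1
        for i in range(len(valid_labels))
        if oracle_knn_predict(Xt, train_labels, Xv[i], k) == valid_labels[i]
    )
    return 100.0 * correct / len(valid_labels)
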