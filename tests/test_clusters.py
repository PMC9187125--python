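"""PCA reduction, k-means, cubic clustering criterion, k selection, ARI."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paintraj.clusters import (
    adjusted_rand_index,
    cubic_clustering_criterion,
    kmeans_fit,
    pca_reduce,
    select_k,
)


def naive_ccc(scores, labels):
    """Independent direct translation of the published CCC formulation.

    Written separately from the package implementation as a
    cross-implementation oracle: R^2 from within/total sums of squares,
    hypercube edges from the covariance eigenvalues, E(R^2) from the edge
    series, CCC from the variance-ratio statistic.
    """
    X = np.asarray(scores, float)
    labels = np.asarray(labels)
    n, p = X.shape
    k = len(set(labels.tolist()))

    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum()
    ssw = 0.0
    for lab in set(labels.tolist()):
        grp = X[labels == lab]
        ssw += ((grp - grp.mean(axis=0)) ** 2).sum()
    r2 = 1.0 - ssw / sst

    cov = np.cov(X, rowvar=False)
    if p == 1:
        eig = np.array([float(cov)])
    else:
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    s = np.sqrt(np.clip(eig, 0.0, None))

    # choose the hypercube dimensionality p* (largest feasible j < k with the
    # j-th standardized edge at least the unit edge)
    p_star, c_star = 1, max(s[0], 1e-300)
    for j in range(1, min(p, max(k - 1, 1)) + 1):
        prod = np.prod(s[:j])
        if prod <= 0:
            break
        c = (prod / k) ** (1.0 / j)
        if s[j - 1] / c >= 1.0:
            p_star, c_star = j, c
    u = s / c_star

    a = sum(1.0 / (n + u[j]) for j in range(p_star))
    b = sum(u[j] ** 2 / (n + u[j]) for j in range(p_star, p))
    e_r2 = 1.0 - (a + b) / (u ** 2).sum() * ((n - k) ** 2 / n) * (1.0 + 4.0 / n)
    e_r2 = min(max(e_r2, 0.0), 1.0 - 1e-12)
    r2 = min(r2, 1.0 - 1e-12)
    return (np.log((1.0 - e_r2) / (1.0 - r2))
            * np.sqrt(n * p_star / 2.0) / (0.001 + e_r2) ** 1.2)


@pytest.fixture(scope="module")
def two_blobs():
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-3.0, 1.0, size=(80, 2)),
                   rng.normal(3.0, 1.0, size=(80, 2))])
    return X


def test_ccc_matches_independent_implementation(two_blobs):
    for k in (2, 3, 4):
        a = kmeans_fit(two_blobs, k, seed=0, restarts=10)
        labels = a.label_array(list(range(len(two_blobs))))
        mine = cubic_clustering_criterion(two_blobs, labels)
        theirs = naive_ccc(two_blobs, labels)
        assert mine == pytest.approx(theirs, rel=1e-10), k


def test_ccc_peaks_at_two_for_two_blobs(two_blobs):
    k_star, table, _ = select_k(two_blobs, range(1, 4), seed=0, restarts=10)
    ccc = dict(zip(table["k"], table["ccc"]))
    assert ccc[2] > ccc[1] and ccc[2] > ccc[3]
    assert k_star == 2


def test_single_blob_flags_no_cluster_support():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(250, 3))
    _, table, _ = select_k(X, range(2, 8), seed=0, restarts=10)
    assert (table["ccc"] <= 0).all()
    assert table.attrs["no_cluster_support"] is True


def test_select_k_singleton_range(two_blobs):
    k_star, table, assign = select_k(two_blobs, [3], seed=0, restarts=5)
    assert k_star == 3 and len(table) == 1 and assign.k == 3


def test_select_k_range_validation(two_blobs):
    with pytest.raises(ValueError):
        select_k(two_blobs, [0, 2], seed=0)
    with pytest.raises(ValueError):
        select_k(two_blobs, [2, 10_000], seed=0)


def test_kmeans_optimal_on_small_instance():
    """Brute force over all 2-partitions of 8 one-dimensional points."""
    X = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 9.0])[:, None]
    best = np.inf
    for mask in itertools.product([0, 1], repeat=8):
        if len(set(mask)) < 2:
            continue
        w = 0.0
        for g in (0, 1):
            grp = X[np.array(mask) == g]
            w += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    a = kmeans_fit(X, 2, seed=0, restarts=20)
    assert a.within_ss == pytest.approx(best, rel=1e-12)


def test_kmeans_labels_sorted_by_size():
    X = np.vstack([np.random.default_rng(0).normal(0, 0.1, size=(30, 2)),
                   np.random.default_rng(1).normal(8, 0.1, size=(10, 2))])
    a = kmeans_fit(X, 2, seed=0, restarts=10)
    sizes = a.sizes
    assert sizes[1] == 30 and sizes[2] == 10


def test_kmeans_determinism(two_blobs):
    a = kmeans_fit(two_blobs, 3, seed=5, restarts=10)
    b = kmeans_fit(two_blobs, 3, seed=5, restarts=10)
    assert a.labels == b.labels and a.within_ss == b.within_ss


def test_kmeans_k_validation(two_blobs):
    with pytest.raises(ValueError):
        kmeans_fit(two_blobs, 0)
    with pytest.raises(ValueError):
        kmeans_fit(two_blobs, len(two_blobs) + 1)


def test_pca_oracle():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(200, 2))
    X = np.column_stack([base[:, 0], base[:, 0] + 0.1 * rng.normal(size=200),
                         base[:, 1], rng.normal(size=200)])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    res = pca_reduce(Z)
    # eigenvalues of the correlation matrix, non-increasing, summing to p
    expected = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    assert np.allclose(res.eigenvalues, expected, atol=1e-10)
    assert float(np.sum(res.eigenvalues)) == pytest.approx(4.0)
    # Kaiser retention and score variances equal to the eigenvalues
    assert res.q == int(np.sum(expected > 1.0))
    assert np.allclose(res.scores.var(axis=0, ddof=1), expected[:res.q], atol=1e-10)
    summary = res.summary()
    assert summary["n_components_retained"] == res.q
    assert 0 < summary["variance_explained_retained"] <= 1


def test_pca_sign_deterministic_and_validation():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(50, 3))
    a = pca_reduce(X)
    b = pca_reduce(X.copy())
    assert np.allclose(a.loadings, b.loadings)
    for j in range(a.loadings.shape[1]):
        i = np.argmax(np.abs(a.loadings[:, j]))
        assert a.loadings[i, j] > 0
    with pytest.raises(ValueError):
        pca_reduce(X[:1])


def test_ari_permutation_invariance():
    a = [1, 1, 2, 2, 3, 3]
    b = [3, 3, 1, 1, 2, 2]  # same partition, relabeled
    assert adjusted_rand_index(a, b) == pytest.approx(1.0)
    assert adjusted_rand_index(a, a) == pytest.approx(1.0)
    c = [1, 2, 1, 2, 1, 2]
    assert adjusted_rand_index(a, c) < 0.5


def test_planted_default_scenario_selects_four():
    """k* = 4 on planted 4-cluster synthetic features (default scenario)."""
    from paintraj import synthetic
    from paintraj.features import DEFAULT_WINSOR_PCT, feature_matrix, standardize

    series, _, labels = synthetic.generate_cohort(
        synthetic.default_scenario(n_patients=1000, seed=1))
    feats = feature_matrix(series)
    z, _, _ = standardize(feats[list(feats.columns[:24])],
                          winsor_pct=DEFAULT_WINSOR_PCT)
    pca = pca_reduce(z)
    k_star, _, assign = select_k(pca.scores, range(2, 8), seed=1, restarts=20,
                                 patient_ids=list(z.index))
    assert k_star == 4
    ids = list(z.index)
    ari = adjusted_rand_index([assign.labels[p] for p in ids],
                              [labels[p] for p in ids])
    assert ari > 0.75
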