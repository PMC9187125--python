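"""Latent trajectory classes: PCA reduction, k-means, cubic clustering criterion.

The 24 standardized change measures are reduced by principal component
analysis of their correlation matrix (Kaiser rule: eigenvalue > 1 retained),
patients are clustered by k-means on the retained component scores, and the
cluster count is selected by maximizing the cubic clustering criterion
(CCC). The CCC compares the observed proportion of variance explained by
the clustering (R^2) with its expectation under a uniform null on a
hypercube aligned with the data's principal axes:

    CCC = ln[(1 - E(R^2)) / (1 - R^2)] * sqrt(n p* / 2) / (0.001 + E(R^2))^1.2

with the hypercube edge and E(R^2) estimated from the eigenvalues of the
data covariance (the original technical-report formulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Correlation-matrix PCA of the standardized measures."""

    scores: np.ndarray      # n x q projections
    loadings: np.ndarray    # p x q eigenvectors
    eigenvalues: np.ndarray  # all p, non-increasing
    q: int
    patient_ids: Optional[list] = None

    def summary(self) -> dict:
        total = float(np.sum(self.eigenvalues))
        return {
            "n_components_retained": int(self.q),
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "variance_explained_retained": float(np.sum(self.eigenvalues[: self.q]) / total),
        }


@dataclass
class ClusterAssignment:
    """k-means labels (1..k, relabeled by descending cluster size)."""

    labels: dict            # patient_id -> label
    k: int
    centroids: np.ndarray
    within_ss: float
    seed: int
    restarts: int

    def label_array(self, patient_ids: Sequence) -> np.ndarray:
        return np.array([self.labels[p] for p in patient_ids])

    @property
    def sizes(self) -> dict:
        out: dict[int, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return dict(sorted(out.items()))


def pca_reduce(z, retention: str = "kaiser", patient_ids=None) -> PcaResult:
    """PCA of the correlation matrix of a standardized feature matrix.

    Components with eigenvalue > 1 are retained (``retention='kaiser'``,
    never fewer than one); scores are the projections of the standardized
    data onto the retained eigenvectors.
    """
    if isinstance(z, pd.DataFrame):
        patient_ids = list(z.index) if patient_ids is None else patient_ids
        z = z.to_numpy(dtype=float)
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 patients")
    if n <= p:
        logger.warning("PCA with n = %d <= p = %d features", n, p)
    corr = np.corrcoef(z, rowvar=False)
    if np.any(~np.isfinite(corr)):
        raise ValueError("correlation matrix not finite; remove zero-variance columns first")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    if retention == "kaiser":
        q = max(1, int(np.sum(eigvals > 1.0)))
    else:
        q = int(retention)
    # re-standardize columns so projections use the correlation metric even if
    # the caller passed unscaled data
    zc = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    scores = zc @ eigvecs[:, :q]
    return PcaResult(scores=scores, loadings=eigvecs, eigenvalues=eigvals, q=q,
                     patient_ids=patient_ids)


def kmeans_fit(scores, k: int, seed: int = 0, restarts: int = 50,
               patient_ids=None) -> ClusterAssignment:
    """k-means with ``restarts`` random initializations; best within-SS wins.

    Labels are 1..k sorted by descending cluster size (ties broken by the
    original k-means label) so reports are stable across runs.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k = {k} out of range for n = {n}")
    if patient_ids is None:
        patient_ids = list(range(n))
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(scores)
    counts = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-counts[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {pid: relabel[int(lab)] for pid, lab in zip(patient_ids, raw)}
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(labels=labels, k=k, centroids=centroids,
                             within_ss=float(km.inertia_), seed=seed, restarts=restarts)


def _r_squared(scores: np.ndarray, labels: np.ndarray) -> float:
    centered = scores - scores.mean(axis=0)
    total_ss = float(np.sum(centered**2))
    if total_ss == 0.0:
        raise ValueError("total sum of squares is zero; CCC undefined")
    within = 0.0
    for lab in np.unique(labels):
        grp = scores[labels == lab]
        within += float(np.sum((grp - grp.mean(axis=0)) ** 2))
    return 1.0 - within / total_ss


def cubic_clustering_criterion(scores, assignment) -> float:
    """Cubic clustering criterion of a k-means assignment.

    ``assignment`` may be a ClusterAssignment (with patient ids 0..n-1 or a
    matching id order is the caller's responsibility via ``label_array``) or
    a plain label array aligned with ``scores`` rows.
    """
    scores = np.asarray(scores, dtype=float)
    n, p = scores.shape
    if isinstance(assignment, ClusterAssignment):
        ids = list(assignment.labels)
        if len(ids) != n:
            raise ValueError("assignment size does not match scores")
        labels = np.array(list(assignment.labels.values()))
        k = assignment.k
    else:
        labels = np.asarray(assignment)
        k = len(np.unique(labels))
    r2 = _r_squared(scores, labels)
    return _ccc_from_r2(scores, r2, k)


def _ccc_from_r2(scores: np.ndarray, r2: float, k: int) -> float:
    n, p = scores.shape
    centered = scores - scores.mean(axis=0)
    eigvals = np.linalg.eigvalsh(centered.T @ centered / (n - 1))[::-1]
    eigvals = np.maximum(eigvals, 0.0)
    s = np.sqrt(eigvals)

    # hypercube dimensionality p*: largest j < k (at least 1) such that the
    # j-th standardized edge is >= the geometric-mean edge c = (v*/k)^(1/p*)
    p_star, c_star = 1, max(s[0], np.finfo(float).tiny)
    for cand in range(1, min(p, max(k - 1, 1)) + 1):
        v = float(np.prod(s[:cand]))
        if v <= 0:
            break
        c = (v / k) ** (1.0 / cand)
        u = s[:cand] / c
        if u[cand - 1] >= 1.0:
            p_star, c_star = cand, c
    u = s / c_star

    num = (np.sum(1.0 / (n + u[:p_star])) +
           np.sum(u[p_star:] ** 2 / (n + u[p_star:])))
    den = float(np.sum(u**2))
    e_r2 = 1.0 - num / den * ((n - k) ** 2 / n) * (1.0 + 4.0 / n)
    e_r2 = min(max(e_r2, 0.0), 1.0 - 1e-12)
    if r2 >= 1.0:
        r2 = 1.0 - 1e-12
    return float(np.log((1.0 - e_r2) / (1.0 - r2)) *
                 np.sqrt(n * p_star / 2.0) / (0.001 + e_r2) ** 1.2)


def select_k(scores, k_range=range(2, 8), seed: int = 0, restarts: int = 50,
             patient_ids=None):
    """Choose the cluster count maximizing the CCC over ``k_range``.

    Returns ``(k_star, table, assignment)`` where ``table`` lists CCC and
    within-SS per candidate k and carries a ``no_cluster_support`` attribute
    set when no candidate attains a positive CCC. Ties go to the smaller k.
    """
    scores = np.asarray(scores, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 1 or ks[-1] > scores.shape[0]:
        raise ValueError("k_range out of bounds")
    rows, fits = [], {}
    for k in ks:
        a = kmeans_fit(scores, k, seed=seed, restarts=restarts, patient_ids=patient_ids)
        labels = np.array(list(a.labels.values()))
        ccc = _ccc_from_r2(scores, _r_squared(scores, labels), k)
        rows.append({"k": k, "ccc": ccc, "within_ss": a.within_ss})
        fits[k] = a
    table = pd.DataFrame(rows)
    best = table.loc[table["ccc"].idxmax()]
    # ties -> smaller k
    k_star = int(table.loc[np.isclose(table["ccc"], best["ccc"]), "k"].min())
    table.attrs["no_cluster_support"] = bool((table["ccc"] <= 0).all())
    if table.attrs["no_cluster_support"]:
        logger.warning("CCC non-positive across the whole range: no cluster support")
    return k_star, table, fits[k_star]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(labels_a), list(labels_b)))
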