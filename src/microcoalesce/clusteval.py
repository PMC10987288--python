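"""Unsupervised and supervised evaluation of candidate grouping factors.

PAM (partitioning around medoids, BUILD + SWAP) clusters the gut samples on
an arbitrary dissimilarity matrix; the Calinski–Harabasz (CH) index — computed
on a classical principal-coordinate embedding of the dissimilarities —
selects the cluster number, with silhouette widths reported alongside. Each
candidate factor (habitat preference, species, family, trophic group) is then
scored two ways: its matching rate against the PAM partition (majority-level
mapping) and the macro one-vs-rest AUC of a random-forest classifier under
leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import calinski_harabasz_score, roc_auc_score, silhouette_samples

from .divstats import DistanceMatrix


class ClusterError(ValueError):
    """Raised for invalid clustering inputs."""


@dataclass
class ClusterEvaluation:
    """PAM scan across k with CH/silhouette and the selected partition."""

    k_values: list[int]
    ch_scores: list[float]
    silhouette_means: list[float]
    selected_k: int
    labels: np.ndarray
    medoids: list[str]
    matching_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class ClassifierEvaluation:
    """Cross-validated discrimination of one factor from the community table."""

    factor: str
    macro_auc: float
    per_class_auc: dict[str, float]
    cv_scheme: str
    seed: int


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam(dist: DistanceMatrix, k: int, seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Deterministic: ties break toward the lowest sample index. Returns integer
    cluster labels (0..k-1 by medoid order) and the medoid sample IDs.
    """
    n = dist.n
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} outside [1, {n}]")
    d = dist.data
    # BUILD: first medoid minimizes total distance; then greedily add the
    # point giving the largest cost reduction.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP: replace (medoid, non-medoid) pairs while total cost decreases.
    cost = _pam_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = _pam_cost(d, trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            improved = True
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    labels[medoids] = np.arange(len(medoids))  # a medoid belongs to its own cluster
    return labels, [dist.sample_ids[m] for m in medoids]


def pcoa_embedding(dist: DistanceMatrix) -> np.ndarray:
    """Classical principal-coordinate embedding, keeping positive eigenvalues."""
    d2 = dist.data**2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-10 * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def ch_index(dist: DistanceMatrix, labels) -> float:
    """Calinski–Harabasz index on the principal-coordinate embedding."""
    labels = np.asarray(labels)
    k = np.unique(labels).size
    if not 2 <= k <= dist.n - 1:
        raise ClusterError("CH requires 2 <= k <= n-1 non-empty clusters")
    return float(calinski_harabasz_score(pcoa_embedding(dist), labels))


def silhouette(dist: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths and their mean, on the raw dissimilarities."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ClusterError("silhouette requires at least 2 clusters")
    s = silhouette_samples(dist.data, labels, metric="precomputed")
    return s, float(s.mean())


def select_k(
    dist: DistanceMatrix, k_range=range(2, 9), seed: int = 0
) -> ClusterEvaluation:
    """Scan k with PAM and pick the CH-maximizing cluster number."""
    k_values = [k for k in k_range if 2 <= k <= dist.n - 1]
    if not k_values:
        raise ClusterError("empty k range")
    ch_scores, sil_means, partitions = [], [], []
    for k in k_values:
        labels, medoids = pam(dist, k, seed=seed)
        ch_scores.append(ch_index(dist, labels))
        sil_means.append(silhouette(dist, labels)[1])
        partitions.append((labels, medoids))
    best = int(np.argmax(ch_scores))
    labels, medoids = partitions[best]
    return ClusterEvaluation(
        k_values=k_values,
        ch_scores=ch_scores,
        silhouette_means=sil_means,
        selected_k=k_values[best],
        labels=labels,
        medoids=medoids,
    )


def matching_rate(cluster_labels, factor_labels) -> float:
    """Fraction of samples whose factor level matches their cluster's majority level."""
    cluster_labels = np.asarray(cluster_labels)
    factor_labels = np.asarray(factor_labels)
    if cluster_labels.size == 0 or cluster_labels.size != factor_labels.size:
        raise ClusterError("label vectors must be non-empty and equal-length")
    matched = 0
    for c in np.unique(cluster_labels):
        members = factor_labels[cluster_labels == c]
        levels, counts = np.unique(members, return_counts=True)
        majority = levels[np.lexsort((levels, -counts))][0]  # tie -> smallest level
        matched += int((members == majority).sum())
    return matched / cluster_labels.size


def supervised_auc(
    features: np.ndarray,
    factor_labels,
    factor_name: str = "factor",
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierEvaluation:
    """Random-forest discrimination of a factor under leave-one-out CV.

    ``features`` is samples x taxa (e.g. relative abundances). Out-of-fold
    class probabilities are pooled and scored as macro one-vs-rest AUC.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(factor_labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ClusterError("factor has a single class")
    if np.any(counts < 2):
        raise ClusterError("every class needs at least 2 members for LOO-CV")
    n = x.shape[0]
    proba = np.zeros((n, classes.size))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        clf.fit(x[mask], y[mask])
        p = clf.predict_proba(x[i : i + 1])[0]
        for cls, pc in zip(clf.classes_, p):
            proba[i, list(classes).index(cls)] = pc
    per_class: dict[str, float] = {}
    for ci, cls in enumerate(classes):
        per_class[str(cls)] = float(roc_auc_score((y == cls).astype(int), proba[:, ci]))
    if classes.size == 2:
        macro = float(roc_auc_score((y == classes[1]).astype(int), proba[:, 1]))
    else:
        macro = float(np.mean(list(per_class.values())))
    return ClassifierEvaluation(
        factor=factor_name,
        macro_auc=macro,
        per_class_auc=per_class,
        cv_scheme="leave-one-out",
        seed=seed,
    )
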