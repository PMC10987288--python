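"""Diversity, dissimilarity, ordination and group-difference statistics.

Shannon entropy (natural log), Bray–Curtis dissimilarity on raw counts,
nonmetric multidimensional scaling (NMDS), the ANOSIM rank permutation test
with Benjamini–Hochberg FDR adjustment across factors, shared-taxon fractions
between habitats and guts, and a rank-sum test on a single ordination axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, rankdata
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample identifiers."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise StatsError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise StatsError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise StatsError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)])


@dataclass
class AnosimResult:
    """ANOSIM R with its permutation p-value (and optional BH q-value)."""

    r: float
    p: float
    n_permutations: int
    q: float | None = None


@dataclass
class OrdinationResult:
    """NMDS coordinates plus the final Kruskal stress-1."""

    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    seed: int


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p over positive proportions (nats)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise StatsError("negative counts")
    total = counts.sum()
    if total == 0:
        raise StatsError("all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y) between two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("vectors differ in length")
    if x.sum() == 0 or y.sum() == 0:
        raise StatsError("zero-total vector")
    return float(np.abs(x - y).sum() / (x + y).sum())


def bray_curtis_matrix(counts: np.ndarray, sample_ids: list[str]) -> DistanceMatrix:
    """Pairwise Bray–Curtis over sample columns of a taxon-by-sample count matrix."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0):
        raise StatsError("sample with zero total reads")
    d = squareform(pdist(counts.T, metric="braycurtis"))
    return DistanceMatrix(sample_ids, d)


def nmds(
    dist: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric MDS (SMACOF with monotone regression), best of ``n_starts``.

    Stress is Kruskal's stress-1; seeded for reproducibility.
    """
    if dist.n < 4:
        raise StatsError("NMDS needs at least 4 samples")
    off = dist.condensed()
    if np.allclose(off, off[0]):
        raise StatsError("degenerate distance matrix: all off-diagonal distances equal")
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=1e-9,
        normalized_stress=True,
        random_state=seed,
        n_jobs=1,
    )
    coords = model.fit_transform(dist.data)
    return OrdinationResult(dist.sample_ids, coords, float(model.stress_), n_starts, seed)


def anosim_r(dist: DistanceMatrix | np.ndarray, labels: np.ndarray) -> float:
    """The ANOSIM R statistic on ranked pairwise dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with ranks taken over all n(n-1)/2 pairs (average ranks on ties).
    """
    data = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    n = data.shape[0]
    ranks = rankdata(squareform(data, checks=False))
    ii, jj = np.triu_indices(n, k=1)
    within = labels[ii] == labels[jj]
    return float((ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4))


def _perm_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return (ranks[~within].mean() - ranks[within].mean()) / denom


def anosim(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM permutation test of group separation on a dissimilarity matrix.

    The p-value uses the add-one convention p = (1 + #{R_perm >= R_obs}) /
    (1 + n_permutations), so the smallest attainable p is 1/(n_permutations+1).
    """
    labels = np.asarray(labels)
    if labels.size != dist.n:
        raise StatsError("labels length does not match distance matrix")
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise StatsError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        raise StatsError("every group needs at least 2 members")
    n = dist.n
    ranks = rankdata(dist.condensed())
    ii, jj = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4
    observed = _perm_r(ranks, labels[ii] == labels[jj], denom)
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _perm_r(ranks, lab[ii] == lab[jj], denom) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r=float(observed), p=float(p), n_permutations=n_permutations)


def anosim_exact(dist: DistanceMatrix, labels) -> AnosimResult:
    """Exact ANOSIM over all distinct label arrangements (small n only).

    p = fraction of arrangements (including the observed identity) with
    R >= R_observed.
    """
    labels = np.asarray(labels)
    n = dist.n
    if n > 10:
        raise StatsError("exact enumeration is limited to n <= 10")
    ranks = rankdata(dist.condensed())
    ii, jj = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4
    observed = _perm_r(ranks, labels[ii] == labels[jj], denom)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        lab = labels[list(perm)]
        total += 1
        if _perm_r(ranks, lab[ii] == lab[jj], denom) >= observed - 1e-12:
            hits += 1
    return AnosimResult(r=float(observed), p=hits / total, n_permutations=total)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise StatsError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise StatsError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def shared_fraction(source_presence: set, gut_presence: set) -> float:
    """Fraction of source taxa also present in guts: |source & gut| / |source|."""
    if not source_presence:
        raise StatsError("empty source presence set")
    return len(source_presence & gut_presence) / len(source_presence)


def axis_group_test(axis_coords, binary_labels) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a binary factor on one axis."""
    coords = np.asarray(axis_coords, dtype=float)
    labels = np.asarray(binary_labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise StatsError("axis_group_test needs exactly 2 groups")
    a = coords[labels == levels[0]]
    b = coords[labels == levels[1]]
    if a.size == 0 or b.size == 0:
        raise StatsError("empty group")
    # exact null distribution when it is well-defined (no tied values)
    method = "exact" if np.unique(coords).size == coords.size else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
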