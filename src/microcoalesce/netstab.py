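"""Co-occurrence networks and natural-connectivity robustness.

Networks are built per sample group from Spearman rank correlations between
taxa: taxa present in more than a prevalence fraction of the group's samples
are candidate nodes, and an undirected, unweighted edge joins two taxa when
|rho| meets the threshold (default 0.8) and the BH-adjusted p-value is below
the cutoff. Stability is probed by deleting random node subsets at a grid of
fractions, recomputing the natural connectivity

    NC(G) = ln( (1/n) * sum_i exp(lambda_i) )

over the adjacency eigenvalues lambda_i of the induced subgraph, averaging
over iterations, and regressing the mean connectivity on the removal
fraction: a steeper (more negative) slope means a less robust network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .divstats import bh_fdr


class NetworkError(ValueError):
    """Raised for invalid network inputs."""


@dataclass
class CooccurrenceNetwork:
    """Undirected, unweighted co-occurrence graph with edge-level correlation metadata."""

    graph: nx.Graph
    rho_threshold: float
    q_threshold: float
    prevalence: float
    group: str = ""

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.node_ids, weight=None)


@dataclass
class RobustnessResult:
    """Natural-connectivity decline curve under random node removal."""

    fractions: np.ndarray
    mean_connectivity: np.ndarray
    sd_connectivity: np.ndarray
    n_iterations: int
    slope: float
    intercept: float
    seed: int


def spearman_matrix(relabund: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p for taxa (rows) across samples (columns)."""
    m = np.asarray(relabund, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise NetworkError("need a 2-D matrix with at least 2 taxa")
    if m.shape[1] < 5:
        raise NetworkError("need at least 5 samples for rank correlations")
    rho, p = spearmanr(m, axis=1)
    if m.shape[0] == 2:  # spearmanr collapses the 2x2 case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    return rho, p


def build_network(
    table,
    group_sample_ids: list[str],
    rho_threshold: float = 0.8,
    q_threshold: float = 0.05,
    prevalence: float = 0.5,
    group: str = "",
) -> CooccurrenceNetwork:
    """Spearman co-occurrence network for one sample group.

    Candidate nodes are taxa with count > 0 in more than ``prevalence`` of the
    group's samples (constant taxa are excluded: their rank correlation is
    undefined). Edges use |rho| >= rho_threshold and BH-adjusted p <
    q_threshold over all candidate pairs. Isolated candidates stay as
    degree-0 nodes.
    """
    if not group_sample_ids:
        raise NetworkError("empty sample group")
    sub = table.subset_samples(group_sample_ids, drop_empty_taxa=False)
    counts = sub.counts.astype(float)
    n_samp = counts.shape[1]
    if n_samp < 5:
        raise NetworkError("group needs at least 5 samples")
    present = (counts > 0).sum(axis=1) / n_samp > prevalence
    non_constant = np.array([np.unique(row).size > 1 for row in counts])
    keep = present & non_constant
    taxa = [t for t, k in zip(sub.taxon_ids, keep) if k]
    g = nx.Graph()
    g.add_nodes_from(taxa)
    if len(taxa) >= 2:
        rho, p = spearman_matrix(counts[keep])
        iu, ju = np.triu_indices(len(taxa), k=1)
        q = bh_fdr(np.clip(p[iu, ju], np.finfo(float).tiny, 1.0))
        for i, j, r, qv in zip(iu, ju, rho[iu, ju], q):
            if abs(r) >= rho_threshold and qv < q_threshold:
                g.add_edge(taxa[i], taxa[j], rho=float(r), q=float(qv))
    return CooccurrenceNetwork(g, rho_threshold, q_threshold, prevalence, group)


def node_metrics(net: CooccurrenceNetwork) -> dict[str, dict[str, float]]:
    """Degree, unnormalized betweenness, and neighborhood connectivity per node."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise NetworkError("empty node set")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    neigh = {
        n: (float(np.mean([degree[v] for v in g.neighbors(n)])) if degree[n] > 0 else 0.0)
        for n in g.nodes
    }
    return {
        "degree": {n: float(d) for n, d in degree.items()},
        "betweenness": {n: float(b) for n, b in betweenness.items()},
        "neighborhood_connectivity": neigh,
    }


def detect_modules(net: CooccurrenceNetwork, seed: int = 0) -> dict[str, int]:
    """Greedy modularity-maximizing module assignment (singletons if edgeless)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}
    communities = nx.community.greedy_modularity_communities(g)
    out: dict[str, int] = {}
    for i, comm in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for n in comm:
            out[n] = i
    return out


def natural_connectivity(adjacency: np.ndarray) -> float:
    """NC = ln(mean(exp(eigenvalues))) of a symmetric 0/1 adjacency matrix."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NetworkError("adjacency must be square")
    n = a.shape[0]
    if n == 0:
        raise NetworkError("empty adjacency matrix")
    if not np.allclose(a, a.T):
        raise NetworkError("adjacency must be symmetric")
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def robustness_slope(
    net: CooccurrenceNetwork,
    fractions: np.ndarray | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> RobustnessResult:
    """Natural-connectivity decline under random node removal, with OLS slope.

    For each fraction f, round(f*n) uniformly chosen nodes are deleted and the
    natural connectivity of the induced subgraph is recorded; means over
    ``n_iterations`` draws are regressed on f by ordinary least squares.
    """
    if fractions is None:
        fractions = np.arange(0.05, 0.501, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions >= 1) or np.any(fractions < 0):
        raise NetworkError("removal fractions must lie in [0, 1)")
    a = net.adjacency()
    n = a.shape[0]
    if n < 4:
        raise NetworkError("need at least 4 nodes")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for f in fractions:
        m = int(round(f * n))
        if n - m == 0:
            raise NetworkError(f"fraction {f} removes every node")
        vals = np.empty(n_iterations)
        for it in range(n_iterations):
            keep = rng.permutation(n)[m:]
            vals[it] = natural_connectivity(a[np.ix_(keep, keep)])
        means.append(vals.mean())
        sds.append(vals.std(ddof=0))
    slope, intercept = np.polyfit(fractions, means, 1)
    return RobustnessResult(
        fractions=fractions,
        mean_connectivity=np.asarray(means),
        sd_connectivity=np.asarray(sds),
        n_iterations=n_iterations,
        slope=float(slope),
        intercept=float(intercept),
        seed=seed,
    )


def edge_list(net: CooccurrenceNetwork) -> list[tuple[str, str, float, float]]:
    """(node1, node2, rho, q) rows for TSV export."""
    return [
        (u, v, d.get("rho", float("nan")), d.get("q", float("nan")))
        for u, v, d in net.graph.edges(data=True)
    ]
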