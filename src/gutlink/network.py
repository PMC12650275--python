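"""Whole-community molecular ecological network analysis.

Correlation networks thresholded at an RMT-style similarity cutoff
(default 0.995, with an optional eigenvalue-spacing scan), the standard
topology panel (node/edge counts, edge-sign percentages, average degree,
average clustering coefficient, modularity, average path distance),
degree-preserving random-network nulls, and cross-group module
preservation by one-sided Fisher's exact tests with transitive-closure
clustering of similar module pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphs import SignedNetwork, from_correlation
from .linking import UNASSIGNED, detect_modules

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def _spacing_poisson_pvalue(eigvals: np.ndarray, n_bins: int = 8) -> float:
    """Chi-square consistency of nearest-neighbour spacings with Poisson.

    Eigenvalues are unfolded by rank (empirical CDF), so under independent
    (Poisson) statistics the normalized spacings are exponential(1); the
    observed spacing histogram is tested against that form.
    """
    ev = np.sort(np.unique(np.round(eigvals, 10)))
    if len(ev) < n_bins * 3:
        return 0.0
    raw = np.diff(ev)
    s = raw / raw.mean()  # mean-unfolded nearest-neighbour spacings
    edges = np.linspace(0.0, 3.0, n_bins)
    edges = np.append(edges, np.inf)
    obs, _ = np.histogram(s, bins=edges)
    cdf = 1.0 - np.exp(-edges)
    expected = np.diff(cdf) * len(s)
    mask = expected > 1e-9
    chi2 = float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    dof = int(mask.sum()) - 1
    return float(sps.chi2.sf(chi2, dof)) if dof > 0 else 0.0


def rmt_threshold(
    corr: pd.DataFrame,
    candidate_grid: np.ndarray | None = None,
    scan: bool = False,
    fixed: float = 0.995,
) -> float:
    """Similarity threshold for network construction.

    With ``scan=False`` (default) the configured fixed value is returned.
    The scan walks the candidate grid upward and returns the smallest
    threshold whose thresholded matrix has Poisson-consistent eigenvalue
    spacings (chi-square p > 0.05); if none passes, the grid maximum is
    returned with a warning.
    """
    mat = corr.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation matrix must be square symmetric")
    if not scan:
        return float(fixed)
    if candidate_grid is None:
        candidate_grid = np.arange(0.3, 0.96, 0.05)
    off = mat - np.diag(np.diag(mat))
    if np.abs(off).max() < 1e-12:
        log.warning("degenerate (identity-like) correlation matrix; returning fixed threshold")
        return float(fixed)
    for t in np.sort(np.asarray(candidate_grid, dtype=float)):
        a = np.where(np.abs(mat) >= t, mat, 0.0)
        np.fill_diagonal(a, 1.0)
        p = _spacing_poisson_pvalue(np.linalg.eigvalsh(a))
        if p > 0.05:
            return float(t)
    log.warning("no candidate threshold reached Poisson spacings; returning grid maximum")
    return float(np.max(candidate_grid))


def build_network(abundances: pd.DataFrame, threshold: float = 0.995) -> SignedNetwork:
    """Spearman correlation network over feature columns at ``threshold``."""
    variable = abundances.columns[abundances.nunique() > 1]
    sub = abundances[variable]
    rho = sps.spearmanr(sub.to_numpy()).statistic
    if np.ndim(rho) == 0:
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=variable, columns=variable)
    return from_correlation(corr, threshold)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    """Table-3-style metric panel of one network."""

    n_nodes: int
    n_edges: int
    positive_pct: float
    negative_pct: float
    avg_degree: float
    avg_clustering: float
    modularity: float
    n_modules: int
    avg_path_distance: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Node number (N)": self.n_nodes,
                "Edge number": self.n_edges,
                "Positive edges (%)": self.positive_pct,
                "Negative edges (%)": self.negative_pct,
                "Average degree (avgK)": self.avg_degree,
                "Module number": self.n_modules,
                "Average clustering coefficient (avgCC)": self.avg_clustering,
                "Modularity (M)": self.modularity,
                "Average path distance (GD)": self.avg_path_distance,
            }
        )


def edge_sign_summary(net: SignedNetwork) -> tuple[float, float]:
    """(positive %, negative %) of edges, 2 decimals, summing to 100."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    pos = sum(1 for _, _, d in net.graph.edges(data=True) if d["sign"] > 0)
    pct = round(100.0 * pos / net.n_edges, 2)
    return pct, round(100.0 - pct, 2)


def _avg_path_distance(g: nx.Graph) -> float:
    """Mean shortest-path length over connected (unordered) node pairs."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # excludes self
    if pairs == 0:
        return float("nan")
    return total / pairs  # each unordered pair counted twice in both terms


def topology(net: SignedNetwork, min_module_size: int = 1) -> NetworkTopology:
    """Compute the full topology panel.

    Clustering is the unweighted local coefficient averaged over all nodes
    (degree < 2 contributes 0); modularity scores the greedy partition on
    absolute weights; path distance averages over connected pairs only.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("topology undefined for an edgeless network")
    pos_pct, neg_pct = edge_sign_summary(net)
    labels = detect_modules(net, min_size=min_module_size)
    module_ids = sorted({m for m in labels.values() if m != UNASSIGNED})
    communities = [
        {n for n, m in labels.items() if m == mid} for mid in module_ids
    ]
    unassigned = {n for n, m in labels.items() if m == UNASSIGNED}
    mod_comms = communities + [{n} for n in unassigned]
    modularity = float(nx.community.modularity(g, mod_comms, weight="abs_weight"))
    return NetworkTopology(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        positive_pct=pos_pct,
        negative_pct=neg_pct,
        avg_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        avg_clustering=float(nx.average_clustering(g)),
        modularity=modularity,
        n_modules=len(module_ids),
        avg_path_distance=_avg_path_distance(g),
    )


# ---------------------------------------------------------------------------
# random nulls
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Mean +/- sd of topology metrics over degree-preserving randomizations."""

    stats: dict  # metric -> (mean, sd)
    n_randomizations: int


def random_null(
    net: SignedNetwork, n_rand: int = 100, seed: int = 0, min_module_size: int = 1
) -> NullDistribution:
    """Degree-preserving rewiring null (double-edge swaps, 10x edges attempts).

    Graphs too small to rewire fall back to Erdos-Renyi with the same node
    and edge counts (logged). avgCC, modularity and GD are recomputed per
    randomization.
    """
    g = net.graph
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    metrics = {"avg_clustering": [], "modularity": [], "avg_path_distance": []}
    nswap = 10 * g.number_of_edges()
    for k in range(n_rand):
        r = g.copy()
        try:
            nx.double_edge_swap(
                r, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31 - 1))
            )
        except nx.NetworkXException:
            log.info("graph not rewireable; Erdos-Renyi fallback")
            r = nx.gnm_random_graph(
                g.number_of_nodes(), g.number_of_edges(), seed=int(rng.integers(2**31 - 1))
            )
            for _, _, d in r.edges(data=True):
                d["weight"] = 1.0
        for _, _, d in r.edges(data=True):
            d.setdefault("weight", 1.0)
            d["abs_weight"] = abs(d["weight"])
            d["sign"] = 1 if d["weight"] >= 0 else -1
        rnet = SignedNetwork(r, 0.0)
        top = topology(rnet, min_module_size=min_module_size)
        metrics["avg_clustering"].append(top.avg_clustering)
        metrics["modularity"].append(top.modularity)
        metrics["avg_path_distance"].append(top.avg_path_distance)
    out = {
        name: (float(np.mean(vals)), float(np.std(vals, ddof=0)))
        for name, vals in metrics.items()
    }
    return NullDistribution(stats=out, n_randomizations=n_rand)


# ---------------------------------------------------------------------------
# module preservation across group networks
# ---------------------------------------------------------------------------

@dataclass
class ModulePairReport:
    """Cross-group module similarity by one-sided Fisher's exact test."""

    pairs: pd.DataFrame        # group_a, module_a, group_b, module_b, overlap, p, similar
    clusters: list[set]        # transitive closure of similar pairs
    total_pairs: int
    retained_pairs: int
    retained_pct: float


def fisher_module_overlap(a: set, b: set, universe: set) -> tuple[int, float]:
    """One-sided (enrichment) Fisher p for the overlap of two modules."""
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - len(a | b)
    _, p = sps.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return n11, float(p)


def module_similarity(
    partitions: dict[str, dict], alpha: float = 0.05
) -> ModulePairReport:
    """Score every cross-group module pair and cluster the similar ones.

    ``partitions`` maps group -> {node -> module id} (use the labels from
    :func:`gutlink.linking.detect_modules`; unassigned nodes are ignored).
    Pairs with Fisher p < alpha are 'similar' ('retained'); similar pairs
    merge into clusters by transitive closure; the retained percentage is
    100 * retained / total pairs, 2 decimals.
    """
    if len(partitions) < 2:
        raise ValueError("need partitions from at least two group networks")
    modules: dict[tuple[str, object], set] = {}
    universe: set = set()
    for grp, labels in partitions.items():
        universe.update(labels)
        for node, mid in labels.items():
            if mid != UNASSIGNED:
                modules.setdefault((grp, mid), set()).add(node)
    keys = sorted(modules, key=str)
    rows = []
    similar_edges = []
    overlap_any = False
    for (ka, kb) in itertools.combinations(keys, 2):
        if ka[0] == kb[0]:
            continue  # only cross-group pairs
        overlap, p = fisher_module_overlap(modules[ka], modules[kb], universe)
        overlap_any = overlap_any or overlap > 0
        similar = p < alpha
        if similar:
            similar_edges.append((ka, kb))
        rows.append(
            {
                "group_a": ka[0], "module_a": ka[1],
                "group_b": kb[0], "module_b": kb[1],
                "overlap": overlap, "p": p, "similar": similar,
            }
        )
    if rows and not overlap_any:
        log.warning("module universes are disjoint; no pair can be similar")
    pairs = pd.DataFrame(
        rows,
        columns=["group_a", "module_a", "group_b", "module_b", "overlap", "p", "similar"],
    )
    closure = nx.Graph()
    closure.add_edges_from(similar_edges)
    clusters = [set(c) for c in nx.connected_components(closure)]
    total = len(rows)
    retained = int(pairs["similar"].sum()) if total else 0
    pct = round(100.0 * retained / total, 2) if total else 0.0
    return ModulePairReport(
        pairs=pairs,
        clusters=clusters,
        total_pairs=total,
        retained_pairs=retained,
        retained_pct=pct,
    )


def retained_percentage(retained: int, total: int) -> float:
    """100 * retained / total, 2 decimals (the printed-arithmetic helper)."""
    if retained > total:
        raise ValueError("retained cannot exceed total")
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * retained / total, 2)
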