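"""Module-eigenvector mining and Mantel-based phenotype linking.

The biomarker-mining chain: a Spearman-thresholded network on the
differential ASVs, greedy-modularity module detection, one eigenvector
(first principal component, WGCNA-style) per module, hierarchical
clustering of phenotype traits into blocks with one eigengene each, Mantel
tests between module and block eigenvector distance matrices, link calls at
r > 0.3 and p < 0.05, biomarker ASVs ranked by module membership, and a
sensitivity re-run at a stricter correlation threshold.

Eigenvector distance matrices use |score_i - score_j|, which is invariant
to the eigenvector's sign; a negatively linked block therefore still
produces a positive Mantel r, and the one-sided (greater) permutation p
tests both link signs. The signed direct Spearman correlation is reported
alongside.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
import networkx as nx

from .containers import PhenotypeMatrix
from .graphs import SignedNetwork, from_correlation

log = logging.getLogger(__name__)

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# network construction and module detection
# ---------------------------------------------------------------------------

def spearman_adjacency(abundances: pd.DataFrame, threshold: float = 0.7) -> SignedNetwork:
    """Signed network with an edge wherever |Spearman rho| >= threshold.

    ``abundances`` is samples x features. Constant columns (rho undefined)
    are excluded with a warning.
    """
    if abundances.shape[0] < 4:
        raise ValueError("need at least 4 samples for a rank-correlation network")
    variable = abundances.columns[abundances.nunique() > 1]
    dropped = abundances.columns.difference(variable)
    for col in dropped:
        log.warning("excluding constant column %s from the correlation network", col)
    sub = abundances[variable]
    if len(variable) < 2:
        g = nx.Graph()
        g.add_nodes_from(variable)
        return SignedNetwork(g, threshold)
    rho = sps.spearmanr(sub.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=variable, columns=variable)
    return from_correlation(corr, threshold)


def detect_modules(
    net: SignedNetwork, min_size: int = 3, method: str = "greedy", seed: int = 0
) -> dict:
    """Partition nodes into modules by modularity maximization on |weight|.

    Modules smaller than ``min_size`` (and isolated nodes) are pooled under
    the ``UNASSIGNED`` (-1) label. Deterministic: greedy agglomeration with
    communities ordered by (size desc, smallest member name).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        return {n: UNASSIGNED for n in g.nodes}
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g, weight="abs_weight")
    elif method == "louvain":
        comms = nx.community.louvain_communities(g, weight="abs_weight", seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    comms = sorted((sorted(c, key=str) for c in comms), key=lambda c: (-len(c), str(c[0])))
    labels = {n: UNASSIGNED for n in g.nodes}
    mid = 0
    for comm in comms:
        if len(comm) >= min_size:
            for n in comm:
                labels[n] = mid
            mid += 1
    return labels


# ---------------------------------------------------------------------------
# eigenvectors
# ---------------------------------------------------------------------------

@dataclass
class ModuleEigenvector:
    """First principal component of a module's standardized member columns."""

    module_id: object
    members: list[str]
    score: pd.Series          # per-sample eigenvector (unit norm)
    loadings: pd.Series       # per-member loadings (unit norm)
    variance_explained: float


@dataclass
class PhenotypeEigengene:
    """One phenotype trait block's eigengene."""

    block_id: int
    label: str
    traits: list[str]
    score: pd.Series
    category: str
    variance_explained: float


def module_eigenvector(abundances: pd.DataFrame, members: list[str], module_id=0) -> ModuleEigenvector:
    """PC1 of the column-standardized member submatrix.

    Sign convention: the score is oriented so its mean correlation with the
    member columns is >= 0 (this makes the output invariant to flipping the
    sign of every member column).
    """
    if len(members) < 2:
        raise ValueError("module must have at least 2 members")
    sub = abundances[list(members)].astype(float)
    keep = [c for c in sub.columns if sub[c].std(ddof=0) > 0]
    for c in sub.columns.difference(keep):
        log.warning("dropping zero-variance member %s from eigenvector", c)
    if not keep:
        raise ValueError("all module members have zero variance")
    z = (sub[keep] - sub[keep].mean()) / sub[keep].std(ddof=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    score = u[:, 0]
    loadings = vt[0]
    var_exp = float(s[0] ** 2 / (s**2).sum()) if s.size else 0.0
    corr_mean = float(np.mean([np.corrcoef(score, z[c])[0, 1] for c in keep]))
    if corr_mean < 0:
        score, loadings = -score, -loadings
    return ModuleEigenvector(
        module_id=module_id,
        members=list(members),
        score=pd.Series(score, index=sub.index),
        loadings=pd.Series(loadings, index=keep),
        variance_explained=var_exp,
    )


def merge_correlated_modules(
    abundances: pd.DataFrame, labels: dict, r_merge: float = 0.75
) -> dict:
    """Merge modules whose eigenvectors correlate at |r| >= ``r_merge``.

    The WGCNA-style clean-up for over-fragmented partitions: threshold
    graphs can split one correlated block into near-duplicate communities;
    merging highly correlated module eigenvectors restores the block.
    Iterates until no pair of module eigenvectors exceeds the cutoff.
    """
    labels = dict(labels)
    while True:
        mids = sorted({m for m in labels.values() if m != UNASSIGNED})
        if len(mids) < 2:
            break
        mes = {
            mid: module_eigenvector(
                abundances, sorted([n for n, m in labels.items() if m == mid], key=str), mid
            )
            for mid in mids
        }
        best, best_r = None, r_merge
        for a, b in itertools.combinations(mids, 2):
            r = abs(float(np.corrcoef(mes[a].score, mes[b].score)[0, 1]))
            if r >= best_r:
                best, best_r = (a, b), r
        if best is None:
            break
        keep, absorb = best
        for n, m in labels.items():
            if m == absorb:
                labels[n] = keep
    # relabel compactly by (size desc, smallest member)
    groups: dict = {}
    for n, m in labels.items():
        if m != UNASSIGNED:
            groups.setdefault(m, []).append(n)
    order = sorted(groups, key=lambda m: (-len(groups[m]), str(min(groups[m], key=str))))
    remap = {old: new for new, old in enumerate(order)}
    return {n: (remap[m] if m != UNASSIGNED else UNASSIGNED) for n, m in labels.items()}


def eigenvectors_from_partition(
    abundances: pd.DataFrame, labels: dict
) -> list[ModuleEigenvector]:
    """One eigenvector per detected module (unassigned pool skipped)."""
    out = []
    for mid in sorted({m for m in labels.values() if m != UNASSIGNED}):
        members = sorted([n for n, m in labels.items() if m == mid], key=str)
        out.append(module_eigenvector(abundances, members, module_id=mid))
    return out


def phenotype_modules(phen: PhenotypeMatrix, n_blocks: int) -> list[PhenotypeEigengene]:
    """Cluster traits into blocks and extract one eigengene per block.

    Average-linkage hierarchical clustering on 1 - |Spearman rho| between
    traits, cut at ``n_blocks``; the block category is the majority of its
    member traits' category tags.
    """
    traits = phen.trait_ids
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    if n_blocks > len(traits):
        raise ValueError(f"n_blocks={n_blocks} exceeds trait count {len(traits)}")
    if n_blocks == 1:
        assign = np.ones(len(traits), dtype=int)
    else:
        rho = sps.spearmanr(phen.values.to_numpy()).statistic
        if np.ndim(rho) == 0:
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        dist = 1.0 - np.abs(rho)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        assign = fcluster(average(squareform(dist, checks=False)), n_blocks, criterion="maxclust")
    blocks: list[PhenotypeEigengene] = []
    for b in sorted(set(assign)):
        members = [t for t, a in zip(traits, assign) if a == b]
        cats = phen.categories.loc[members]
        category = cats.mode().iloc[0]
        if len(members) == 1:
            x = phen.values[members[0]].astype(float)
            z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
            score = z / np.linalg.norm(z)
            ev = 1.0
        else:
            me = module_eigenvector(phen.values, members, module_id=b)
            score, ev = me.score, me.variance_explained
        blocks.append(
            PhenotypeEigengene(
                block_id=int(b),
                label=f"block{b}_{category.replace(' ', '_').lower()}",
                traits=members,
                score=pd.Series(score, index=phen.values.index),
                category=category,
                variance_explained=ev,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _pair_index(n: int) -> np.ndarray:
    """Matrix mapping an (i, j) pair to its condensed upper-triangle index."""
    idx = np.zeros((n, n), dtype=int)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            idx[i, j] = idx[j, i] = k
            k += 1
    return idx


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Spearman Mantel test between two distance matrices.

    r is the Spearman correlation of the condensed (upper-triangle)
    entries; p is the permutation tail probability with rows/columns of
    ``d2`` permuted jointly:  p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    With ``exact=True`` all n! label permutations are enumerated (n <= 7)
    and p is the exact fraction #{r_perm >= r_obs} / n!.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share the same labels in the same order")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, 1)
    x = sps.rankdata(np.asarray(d1.data)[iu])
    y = sps.rankdata(np.asarray(d2.data)[iu])
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    m = len(x)
    r_obs = float(xz @ yz / m)

    pair = _pair_index(n)
    y_by_pair = yz  # permutation rearranges the same rank multiset

    def perm_r(sigma: np.ndarray) -> float:
        idx = y_by_pair[pair[sigma[iu[0]], sigma[iu[1]]]]
        return float(xz @ idx / m)

    stat = r_obs if alternative == "greater" else abs(r_obs)

    if exact:
        if n > 7:
            raise ValueError("exact enumeration limited to n <= 7")
        hits = 0
        total = 0
        for sigma in itertools.permutations(range(n)):
            rp = perm_r(np.asarray(sigma))
            rp = rp if alternative == "greater" else abs(rp)
            hits += rp >= stat - 1e-12
            total += 1
        return r_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        sigma = rng.permutation(n)
        rp = perm_r(sigma)
        rp = rp if alternative == "greater" else abs(rp)
        hits += rp >= stat - 1e-12
    return r_obs, (1 + hits) / (1 + n_perm)


def score_distance(score: pd.Series) -> DistanceMatrix:
    """Euclidean distances of a per-sample eigenvector: |s_i - s_j|."""
    v = score.to_numpy(dtype=float)
    return DistanceMatrix(np.abs(v[:, None] - v[None, :]), ids=list(score.index))


# ---------------------------------------------------------------------------
# linking and sensitivity
# ---------------------------------------------------------------------------

@dataclass
class LinkReport:
    """Mantel + Spearman correlations between module and phenotype eigenvectors."""

    pairs: pd.DataFrame  # module, block, mantel_r, mantel_p, spearman_r, spearman_p, significant
    biomarkers: dict = field(default_factory=dict)  # module id -> ranked (asv, |membership|)

    @property
    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def link_modules(
    mes: list[ModuleEigenvector],
    phen_eigens: list[PhenotypeEigengene],
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    abundances: pd.DataFrame | None = None,
) -> LinkReport:
    """Test every (module, block) pair; call links at r > 0.3, p < 0.05.

    Biomarkers of each significantly linked module are its member ASVs
    ranked by |Spearman correlation with the module's own eigenvector|
    (module-membership score); requires ``abundances``.
    """
    rows = []
    linked_modules = set()
    for k, (me, pe) in enumerate(itertools.product(mes, phen_eigens)):
        if list(me.score.index) != list(pe.score.index):
            raise ValueError("eigenvectors must be on the same samples")
        r_m, p_m = mantel(
            score_distance(me.score), score_distance(pe.score),
            n_perm=n_perm, seed=seed + k,
        )
        sp = sps.spearmanr(me.score, pe.score)
        # consensus call: the Mantel and the direct Spearman statistics are
        # both reported; a link is only called when both clear the thresholds
        significant = (
            (r_m > r_threshold)
            and (p_m < p_threshold)
            and (abs(float(sp.statistic)) > r_threshold)
            and (float(sp.pvalue) < p_threshold)
        )
        if significant:
            linked_modules.add(me.module_id)
        rows.append(
            {
                "module": me.module_id,
                "block": pe.label,
                "mantel_r": r_m,
                "mantel_p": p_m,
                "spearman_r": float(sp.statistic),
                "spearman_p": float(sp.pvalue),
                "significant": significant,
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["module", "block", "mantel_r", "mantel_p", "spearman_r", "spearman_p", "significant"],
    )
    biomarkers: dict = {}
    if abundances is not None:
        for me in mes:
            if me.module_id not in linked_modules:
                continue
            scores = []
            for asv in me.members:
                rho = sps.spearmanr(abundances[asv], me.score).statistic
                scores.append((asv, abs(float(rho)) if not math.isnan(rho) else 0.0))
            scores.sort(key=lambda t: (-t[1], t[0]))
            biomarkers[me.module_id] = scores
    return LinkReport(pairs=pairs, biomarkers=biomarkers)


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


@dataclass
class SensitivityReport:
    """Base-vs-alternative threshold module recovery."""

    table: pd.DataFrame  # module, jaccard, recovered, links_persist
    alt_threshold: float

    @property
    def recovered_modules(self) -> list:
        return list(self.table.loc[self.table["recovered"], "module"])


def sensitivity_check(
    abundances: pd.DataFrame,
    base_threshold: float = 0.7,
    alt_threshold: float = 0.8,
    min_size: int = 3,
    phen_eigens: list[PhenotypeEigengene] | None = None,
    base_links: LinkReport | None = None,
    n_perm: int = 999,
    seed: int = 0,
    merge_r: float | None = 0.75,
) -> SensitivityReport:
    """Rebuild the network at a stricter threshold and score module recovery.

    A base module is recovered iff its best Jaccard overlap with any
    alternative-threshold module is >= 0.5 and (when a base LinkReport and
    the phenotype eigengenes are supplied) its significant links are also
    significant for the matched alternative module.
    """
    if not alt_threshold > base_threshold:
        raise ValueError("alt_threshold must exceed base_threshold")
    base_labels = detect_modules(spearman_adjacency(abundances, base_threshold), min_size)
    alt_labels = detect_modules(spearman_adjacency(abundances, alt_threshold), min_size)
    if merge_r is not None:
        base_labels = merge_correlated_modules(abundances, base_labels, merge_r)
        alt_labels = merge_correlated_modules(abundances, alt_labels, merge_r)

    def groups(labels: dict) -> dict:
        out: dict = {}
        for node, mid in labels.items():
            if mid != UNASSIGNED:
                out.setdefault(mid, set()).add(node)
        return out

    base_mods, alt_mods = groups(base_labels), groups(alt_labels)
    alt_mes = (
        eigenvectors_from_partition(abundances, alt_labels) if alt_mods else []
    )
    alt_me_by_id = {me.module_id: me for me in alt_mes}

    rows = []
    for mid, members in sorted(base_mods.items()):
        best_alt, best_j = None, 0.0
        for aid, alt_members in alt_mods.items():
            j = _jaccard(members, alt_members)
            if j > best_j:
                best_alt, best_j = aid, j
        links_persist = True
        if base_links is not None and phen_eigens is not None:
            sig = base_links.significant_pairs
            my_links = sig[sig["module"] == mid]
            if len(my_links) and best_alt is not None:
                alt_report = link_modules(
                    [alt_me_by_id[best_alt]], phen_eigens, n_perm=n_perm, seed=seed
                )
                persisted = set(alt_report.significant_pairs["block"])
                links_persist = set(my_links["block"]) <= persisted
            elif len(my_links):
                links_persist = False
        rows.append(
            {
                "module": mid,
                "best_alt_module": best_alt,
                "jaccard": best_j,
                "recovered": best_j >= 0.5 and links_persist,
                "links_persist": links_persist,
            }
        )
    if not rows:
        log.warning("no base modules to assess; sensitivity report is empty")
    table = pd.DataFrame(
        rows, columns=["module", "best_alt_module", "jaccard", "recovered", "links_persist"]
    )
    return SensitivityReport(table=table, alt_threshold=alt_threshold)
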