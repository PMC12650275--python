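"""ASV-table transformations and diversity profiling.

Rarefaction (multivariate hypergeometric, i.e. subsampling reads without
replacement), relative abundance, taxonomic aggregation, the per-group ASV
partition arithmetic behind UpSet-style summaries, alpha diversity
(richness, Shannon), Bray-Curtis dissimilarity and classical PCoA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import AsvTable, OrdinationResult, PartitionReport, TaxonomyTable, RANKS

log = logging.getLogger(__name__)


def rarefy(table: AsvTable, depth: int, seed: int = 0) -> AsvTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning rather than up-sampled.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    for sample in table.sample_ids:
        row = table.counts.loc[sample].to_numpy()
        total = int(row.sum())
        if total < depth:
            log.warning("dropping sample %s: %d reads < depth %d", sample, total, depth)
            continue
        if total == depth:
            kept_rows[sample] = row
        else:
            kept_rows[sample] = rng.multivariate_hypergeometric(row, depth)
    if not kept_rows:
        raise ValueError("no sample reaches the requested rarefaction depth")
    counts = pd.DataFrame.from_dict(kept_rows, orient="index", columns=table.asv_ids)
    return AsvTable(counts.astype(np.int64), table.groups.loc[counts.index])


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Row-normalize counts to proportions (each sample sums to 1)."""
    totals = table.counts.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        raise ValueError(f"all-zero sample(s): {list(empty)}")
    return table.counts.div(totals, axis=0)


def clr(proportions: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform of a proportion matrix.

    log(x + pc) minus each sample's mean log: removes the per-sample
    compositional offset (sequencing-depth / denominator variation) that
    otherwise loads as a shared factor on every taxon. ``pseudocount``
    defaults to half the smallest nonzero proportion.
    """
    arr = proportions.to_numpy(dtype=float)
    if pseudocount is None:
        nz = arr[arr > 0]
        if nz.size == 0:
            raise ValueError("no nonzero proportion in table")
        pseudocount = float(nz.min() / 2.0)
    logged = np.log(arr + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=proportions.index, columns=proportions.columns)


def aggregate_taxa(table: AsvTable, tax: TaxonomyTable, rank: str) -> AsvTable:
    """Collapse ASV counts to a taxonomic rank; per-sample totals are preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = pd.Series(
        {a: tax.rank_of(a, rank) for a in table.asv_ids}, name=rank
    )
    collapsed = table.counts.T.groupby(labels).sum().T
    return AsvTable(collapsed.astype(np.int64), table.groups)


def partition_shares(totals: dict[str, int]) -> dict[str, float]:
    """Percent share of each group's observed-ASV total, 2 decimals."""
    denom = float(sum(totals.values()))
    if denom == 0:
        raise ValueError("all group totals are zero")
    return {g: round(100.0 * t / denom, 2) for g, t in totals.items()}


def group_asv_partition(table: AsvTable) -> PartitionReport:
    """Per-group observed/unique/common ASV arithmetic.

    An ASV counts as observed in a group iff its pooled count over the
    group's samples is > 0.
    """
    groups = table.group_names
    if len(groups) < 2:
        raise ValueError("partition needs at least two groups")
    observed: dict[str, set[str]] = {}
    for g in groups:
        rows = table.samples_in(g)
        if not rows:
            raise ValueError(f"group {g!r} has no samples")
        pooled = table.counts.loc[rows].sum(axis=0)
        observed[g] = set(pooled.index[pooled > 0])
    totals = {g: len(s) for g, s in observed.items()}
    common = set.intersection(*observed.values())
    unique = {
        g: len(observed[g] - set.union(*(observed[h] for h in groups if h != g)))
        for g in groups
    }
    return PartitionReport(
        totals=totals,
        unique=unique,
        common_all=len(common),
        shares=partition_shares(totals),
    )


def alpha_diversity(table: AsvTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample richness and Shannon index.

    Shannon H = -sum p_i log p_i over nonzero proportions; natural log by
    default, ``base`` switches the logarithm.
    """
    rows = {}
    for sample in table.sample_ids:
        row = table.counts.loc[sample].to_numpy(dtype=float)
        nz = row[row > 0]
        p = nz / nz.sum() if nz.size else nz
        h = float(-(p * np.log(p)).sum()) if p.size else 0.0
        if base is not None:
            h /= np.log(base)
        rows[sample] = {"richness": int((row > 0).sum()), "shannon": h}
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(proportions: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y)."""
    mat = proportions.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(proportions.index))


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (PCoA): Gower double-centering + eigendecomposition.

    Negative eigenvalues (Bray-Curtis is a semi-metric) are dropped from the
    variance denominator with a logged note; proportions explained are over
    the retained positive eigenvalues.
    """
    mat = np.asarray(d.data, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("PCoA needs a square symmetric distance matrix")
    n = mat.shape[0]
    a = -0.5 * mat**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -1e-10).sum())
    if n_neg:
        log.info("PCoA: dropping %d negative eigenvalue(s) from the variance denominator", n_neg)
    pos = eigvals > 1e-10
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)[None, :]
    k = min(n_axes, coords.shape[1]) if coords.shape[1] else 0
    if k == 0:  # all points coincide
        coords = np.zeros((n, n_axes))
        props = np.zeros(n_axes)
        k = n_axes
    else:
        props = lam[:k] / lam.sum()
        coords = coords[:, :k]
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coordinates=frame, proportion_explained=np.asarray(props))
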