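"""Per-ASV differential abundance screening between diet groups.

For each ASV an ordinary linear model of log2(relative abundance +
pseudocount) on the group indicator; with two groups this is exactly the
equal-variance two-sample t-test, and the implementation uses that closed
form vectorized over ASVs. Thresholds follow the screen convention
p < 0.05 and |log2 fold change| > 1 (i.e. >2-fold); ``fc_scale='ratio'``
offers the literal fold-change-ratio reading instead. Raw p-values by
default (the screen's stated convention); ``correction='bh'`` applies
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AsvTable, DifferentialResult
from .profiles import relative_abundance

log = logging.getLogger(__name__)


def default_pseudocount(rel: pd.DataFrame) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    arr = rel.to_numpy()
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero abundance")
    return float(nz.min() / 2.0)


def fit_differential(
    table: AsvTable,
    contrast: tuple[str, str],
    pseudocount: float | None = None,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    fc_scale: str = "log2",
    correction: str | None = None,
) -> DifferentialResult:
    """Screen every ASV for differential abundance in ``contrast = (A, B)``.

    log2fc > 0 means enriched in A. ASVs with zero counts across both
    groups are excluded; ASVs whose transformed values are constant get
    p = 1 rather than an exception.
    """
    group_a, group_b = contrast
    sa, sb = table.samples_in(group_a), table.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both contrast groups need at least 2 samples")
    sub = table.subset_samples(sa + sb)
    rel = relative_abundance(sub)
    keep = rel.columns[(sub.counts.sum(axis=0) > 0)]
    rel = rel[keep]
    pc = default_pseudocount(rel) if pseudocount is None else float(pseudocount)
    y = np.log2(rel.to_numpy() + pc)

    na, nb = len(sa), len(sb)
    ya, yb = y[:na], y[na:]
    mean_a, mean_b = ya.mean(axis=0), yb.mean(axis=0)
    log2fc = mean_a - mean_b  # fitted group-difference of the linear model
    # pooled-variance slope t-test, identical to the OLS group-indicator model
    ss = ((ya - mean_a) ** 2).sum(axis=0) + ((yb - mean_b) ** 2).sum(axis=0)
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(se > 0, p, 1.0)  # degenerate variance: no evidence, p = 1

    if correction == "bh":
        p = _benjamini_hochberg(p)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    if fc_scale == "log2":
        effect_ok_up = log2fc > lfc_threshold
        effect_ok_down = log2fc < -lfc_threshold
    elif fc_scale == "ratio":
        ratio = 2.0**log2fc
        effect_ok_up = ratio > lfc_threshold
        effect_ok_down = ratio < 1.0 / lfc_threshold if lfc_threshold != 0 else ratio < 0
    else:
        raise ValueError(f"fc_scale must be 'log2' or 'ratio', got {fc_scale!r}")

    direction = np.full(len(keep), "ns", dtype=object)
    direction[(p < p_threshold) & effect_ok_up] = "up"
    direction[(p < p_threshold) & effect_ok_down] = "down"

    frame = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "direction": direction}, index=keep
    )
    return DifferentialResult(contrast=(group_a, group_b), table=frame, pseudocount=pc)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def classify_counts(result: DifferentialResult) -> tuple[int, int]:
    """(n_up, n_down) direction counts of one screen."""
    d = result.table["direction"]
    return int((d == "up").sum()), int((d == "down").sum())


def shared_differentials(results: list[DifferentialResult]) -> dict[str, set[str]]:
    """Union and intersection of significant ASVs across contrasts.

    The intersection is the 'core' set: ASVs significant in every supplied
    contrast.
    """
    if len(results) < 2:
        raise ValueError("need at least two contrasts")
    sets = [set(r.significant) for r in results]
    return {"union": set.union(*sets), "intersection": set.intersection(*sets)}
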