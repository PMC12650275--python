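"""Univariate group-comparison statistics and qPCR quantification.

The comparison gate mirrors the trial's convention: Shapiro-Wilk normality
per group and Levene variance homogeneity at alpha = 0.05 route a trait into
one-way ANOVA + Tukey HSD (parametric) or Kruskal-Wallis + Dunn with
Bonferroni adjustment (non-parametric); group differences are rendered as a
compact letter display. Relative gene expression uses the Livak 2^-ddCt
method with a 90-110% primer-efficiency gate.

Note the normality gate has negligible power at n = 3 per group; it is
applied verbatim because that is the stated procedure of the emulated trial.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CtTable

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """One trait's omnibus + pairwise comparison with letter display."""

    trait: str
    means: pd.Series
    sems: pd.Series
    omnibus_p: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    test_used: str  # "parametric" | "nonparametric"


def _dunn(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Dunn's rank-sum post hoc z-test p-values (two-sided, unadjusted).

    Uses average ranks with the standard tie correction
    T = sum(t^3 - t) over tie groups.
    """
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    base_var = n * (n + 1) / 12.0 - tie_term
    p = np.ones((n_groups, n_groups))
    mean_rank = np.array([ranks[codes == g].mean() for g in range(n_groups)])
    sizes = np.array([(codes == g).sum() for g in range(n_groups)])
    for i, j in itertools.combinations(range(n_groups), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_rank[i] - mean_rank[j]) / se if se > 0 else 0.0
        p[i, j] = p[j, i] = 2.0 * sps.norm.sf(abs(z))
    return p


def compact_letters(order: list[str], pairwise_p: pd.DataFrame, alpha: float = ALPHA) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups from highest to lowest mean; letters are assigned
    alphabetically so that two groups share a letter iff their pairwise p is
    >= alpha.
    """
    # columns of the letter matrix are letter-sets; start with one column of all groups
    cols: list[set[str]] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if pairwise_p.loc[a, b] < alpha:
            new_cols: list[set[str]] = []
            for col in cols:
                if a in col and b in col:
                    new_cols.append(col - {b})
                    new_cols.append(col - {a})
                else:
                    new_cols.append(col)
            # absorb: drop columns that are subsets of another
            cols = []
            for col in new_cols:
                if not any(col < other for other in new_cols if col is not other):
                    if col not in cols:
                        cols.append(col)
    # order columns by the highest-mean group they contain, letter them
    rank = {g: i for i, g in enumerate(order)}
    cols.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in order}
    for letter, col in zip(string.ascii_lowercase, cols):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def gate_and_compare(values: pd.Series, groups: pd.Series, trait: str = "trait") -> GroupComparison:
    """Normality/homogeneity-gated omnibus + post hoc comparison of one trait."""
    values = values.astype(float)
    groups = groups.loc[values.index]
    names = []
    for g in groups:
        if g not in names:
            names.append(g)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g].to_numpy() for g in names]
    for g, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    parametric = True
    try:
        for arr in arrays:
            if len(arr) < 3 or np.ptp(arr) == 0:
                raise ValueError("Shapiro-Wilk undefined")
            if sps.shapiro(arr).pvalue < ALPHA:
                parametric = False
                break
        if parametric and sps.levene(*arrays).pvalue < ALPHA:
            parametric = False
    except ValueError:
        parametric = False

    codes = np.concatenate([np.full(len(a), i) for i, a in enumerate(arrays)])
    flat = np.concatenate(arrays)
    k = len(names)
    pair = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    if np.ptp(flat) == 0:  # all observations identical: nothing to test
        omnibus = 1.0
        test_used = "parametric" if parametric else "nonparametric"
    elif parametric:
        omnibus = float(sps.f_oneway(*arrays).pvalue)
        tk = sps.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(k), 2):
            pair.iloc[i, j] = pair.iloc[j, i] = float(tk.pvalue[i, j])
        test_used = "parametric"
    else:
        try:
            omnibus = float(sps.kruskal(*arrays).pvalue)
        except ValueError:  # all numbers identical within scipy's check
            omnibus = 1.0
        raw = _dunn(flat, codes, k)
        m = k * (k - 1) // 2
        adj = np.minimum(raw * m, 1.0)  # Bonferroni over the pairwise family
        for i, j in itertools.combinations(range(k), 2):
            pair.iloc[i, j] = pair.iloc[j, i] = float(adj[i, j])
        test_used = "nonparametric"

    means = pd.Series({g: float(np.mean(a)) for g, a in zip(names, arrays)})
    sems = pd.Series({g: float(np.std(a, ddof=1) / np.sqrt(len(a))) for g, a in zip(names, arrays)})
    order = list(means.sort_values(ascending=False).index)
    letters = compact_letters(order, pair)
    return GroupComparison(
        trait=trait,
        means=means,
        sems=sems,
        omnibus_p=omnibus,
        pairwise_p=pair,
        letters=letters,
        test_used=test_used,
    )


def compare_all(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Tidy report (trait, group, mean, sem, letter, test_used, p) for a trait matrix."""
    rows = []
    for trait in values.columns:
        cmp = gate_and_compare(values[trait], groups, trait=trait)
        for g in cmp.means.index:
            rows.append(
                {
                    "trait": trait,
                    "group": g,
                    "mean": cmp.means[g],
                    "sem": cmp.sems[g],
                    "letter": cmp.letters[g],
                    "test_used": cmp.test_used,
                    "p": cmp.omnibus_p,
                }
            )
    return pd.DataFrame(rows)


def ddct_expression(ct: CtTable, target_gene: str) -> pd.Series:
    """Per-sample relative expression of ``target_gene`` by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the arithmetic
    mean dCt of the calibrator group; expression = 2^-ddCt, so the calibrator
    group's geometric-mean expression is 1 by construction.
    """
    if target_gene not in ct.ct.columns:
        raise KeyError(f"gene {target_gene!r} not in Ct table")
    dct = ct.ct[target_gene] - ct.ct[ct.reference_gene]
    calib = ct.groups.index[ct.groups == ct.calibrator_group]
    if not len(calib):
        raise ValueError(f"calibrator group {ct.calibrator_group!r} has no samples")
    ddct = dct - dct.loc[calib].mean()
    return np.power(2.0, -ddct)


def efficiency_gate(ct: CtTable, lo: float = 90.0, hi: float = 110.0) -> pd.Series:
    """Advisory primer-efficiency gate: pass iff lo <= E <= hi (inclusive)."""
    passed = (ct.efficiencies >= lo) & (ct.efficiencies <= hi)
    for gene in passed.index[~passed]:
        log.warning(
            "primer efficiency %.2f%% for %s outside [%g, %g]%%",
            ct.efficiencies[gene], gene, lo, hi,
        )
    return passed
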