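"""Taxon -> KEGG-ortholog functional projection.

A simplified Tax4Fun-style prediction: project taxon relative abundances
through a user-supplied taxon x KO3-pathway weight matrix, keep only
pathways whose KO1 ancestor is "Metabolism", and test per-pathway group
differences with the gated comparison machinery. The reference mapping is
an input (any rank's abundance table works); a synthetic fixture generator
is provided for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import compare_all, gate_and_compare

log = logging.getLogger(__name__)


@dataclass
class KoMapping:
    """Taxon -> KO3 pathway weights plus the KO3 -> KO2 -> KO1 hierarchy."""

    weights: pd.DataFrame    # taxa x KO3 pathways, non-negative
    hierarchy: pd.DataFrame  # index KO3, columns ko2, ko1

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() < 0).any():
            raise ValueError("mapping weights must be non-negative")
        missing = self.weights.columns.difference(self.hierarchy.index)
        if len(missing):
            raise ValueError(f"KO3 pathways without hierarchy entry: {list(missing)}")

    @classmethod
    def from_tsv(cls, mapping_path, hierarchy_path) -> "KoMapping":
        raw = pd.read_csv(mapping_path, sep="\t")
        weights = raw.pivot_table(
            index="taxon", columns="ko3", values="weight", fill_value=0.0
        )
        hier = pd.read_csv(hierarchy_path, sep="\t").set_index("ko3")
        return cls(weights, hier)


def project_ko(rel_abund: pd.DataFrame, mapping: KoMapping) -> pd.DataFrame:
    """Pathway abundance = abundance x mapping, renormalized per sample."""
    shared = rel_abund.columns.intersection(mapping.weights.index)
    if len(shared) == 0:
        raise ValueError("no taxa shared between abundance table and mapping")
    coverage = len(shared) / rel_abund.shape[1]
    if coverage < 1.0:
        log.info("mapping covers %.1f%% of taxa", 100 * coverage)
    raw = rel_abund[shared].to_numpy() @ mapping.weights.loc[shared].to_numpy()
    out = pd.DataFrame(raw, index=rel_abund.index, columns=mapping.weights.columns)
    totals = out.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a sample projects to zero total pathway abundance")
    return out.div(totals, axis=0)


def filter_metabolism(
    pathway_table: pd.DataFrame, mapping: KoMapping, ko1_label: str = "Metabolism"
) -> pd.DataFrame:
    """Retain KO3 pathways whose KO1 ancestor is ``ko1_label``."""
    ancestors = mapping.hierarchy["ko1"]
    keep = [c for c in pathway_table.columns if ancestors.get(c) == ko1_label]
    dropped = pathway_table.shape[1] - len(keep)
    if dropped:
        log.info("dropped %d non-%s pathway(s)", dropped, ko1_label)
    if not keep:
        log.warning("no pathway remains after the %s filter", ko1_label)
        return pathway_table.iloc[:, :0]
    return pathway_table[keep]


def significance_stars(p: float) -> str:
    """'***' p<=0.001, '**' p<=0.01, '*' p<=0.05, else 'ns'."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def differential_pathways(filtered: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-pathway gated group comparison with significance stars."""
    rows = []
    for pathway in filtered.columns:
        cmp = gate_and_compare(filtered[pathway], groups, trait=pathway)
        rows.append(
            {
                "pathway": pathway,
                "p": cmp.omnibus_p,
                "stars": significance_stars(cmp.omnibus_p),
                "test_used": cmp.test_used,
                **{f"mean_{g}": cmp.means[g] for g in cmp.means.index},
            }
        )
    return pd.DataFrame(rows)


def synthetic_mapping(
    taxa: list[str], n_metabolism: int = 6, n_other: int = 2, seed: int = 0
) -> KoMapping:
    """Small synthetic taxon->KO mapping fixture (sparse non-negative weights)."""
    rng = np.random.default_rng(seed)
    ko3 = [f"ko3_met_{i + 1}" for i in range(n_metabolism)] + [
        f"ko3_other_{i + 1}" for i in range(n_other)
    ]
    w = rng.random((len(taxa), len(ko3))) * (rng.random((len(taxa), len(ko3))) < 0.5)
    w[w.sum(axis=1) == 0, 0] = 1.0  # every taxon maps somewhere
    weights = pd.DataFrame(w, index=taxa, columns=ko3)
    hier = pd.DataFrame(
        {
            "ko2": ["Amino acid metabolism"] * n_metabolism + ["Membrane transport"] * n_other,
            "ko1": ["Metabolism"] * n_metabolism + ["Environmental Information Processing"] * n_other,
        },
        index=ko3,
    )
    hier.index.name = "ko3"
    return KoMapping(weights, hier)
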