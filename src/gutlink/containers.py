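"""Typed containers shared across the pipeline.

The central object is :class:`AsvTable`, an integer count matrix of
samples x amplicon sequence variants (ASVs) carrying the sample -> diet
group assignment. Everything downstream (diversity profiling, differential
screening, network construction, neutral-model fitting) consumes it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with a sample -> group map.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, rows are samples, columns are ASV ids.
    groups : pandas.Series
        Group label per sample; index must match ``counts.index``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValueError("sample and ASV ids must be unique")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group assignment: {list(missing)}")
        self.groups = self.groups.loc[self.counts.index]

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_counts(self, group: str) -> pd.DataFrame:
        return self.counts.loc[self.samples_in(group)]

    def subset_samples(self, samples: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(samples)].copy(), self.groups.loc[list(samples)].copy())

    def subset_asvs(self, asvs: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts[list(asvs)].copy(), self.groups.copy())

    # -- I/O: ASV rows x sample columns on disk, the usual QIIME-ish shape
    def to_tsv(self, path) -> None:
        out = self.counts.T
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, groups: Mapping[str, str] | pd.Series) -> "AsvTable":
        mat = pd.read_csv(path, sep="\t", index_col=0).T
        mat.index.name = None
        mat.columns.name = None
        return cls(mat.astype(np.int64), pd.Series(dict(groups)))


@dataclass
class TaxonomyTable:
    """ASV -> 7-rank lineage (kingdom..species); unassigned ranks hold 'Unassigned'."""

    lineage: pd.DataFrame  # index asv_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"taxonomy missing ranks: {missing}")
        self.lineage = self.lineage[list(RANKS)].fillna("Unassigned")

    def rank_of(self, asv: str, rank: str) -> str:
        return str(self.lineage.at[asv, rank]) if asv in self.lineage.index else "Unassigned"

    def to_tsv(self, path) -> None:
        joined = self.lineage.apply(lambda row: ";".join(row.astype(str)), axis=1)
        pd.DataFrame({"asv_id": joined.index, "lineage": joined.values}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        raw = pd.read_csv(path, sep="\t")
        parts = raw["lineage"].str.split(";", expand=True)
        parts.columns = list(RANKS)[: parts.shape[1]]
        parts.index = raw["asv_id"]
        return cls(parts)


@dataclass
class PhenotypeMatrix:
    """Samples x traits numeric matrix; every trait carries a category tag."""

    values: pd.DataFrame
    categories: pd.Series  # trait -> category label

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.categories.index)
        if len(missing):
            raise ValueError(f"traits without category tag: {list(missing)}")
        self.categories = self.categories.loc[self.values.columns]

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.loc["__category__"] = self.categories.values
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeMatrix":
        raw = pd.read_csv(path, index_col=0)
        cats = raw.loc["__category__"]
        vals = raw.drop(index="__category__").astype(float)
        return cls(vals, cats)


@dataclass
class CtTable:
    """qPCR cycle-threshold matrix with primer efficiencies.

    ``ct`` is samples x genes; ``efficiencies`` maps gene -> percent
    amplification efficiency; the reference gene and calibrator group anchor
    the 2^-ddCt quantification.
    """

    ct: pd.DataFrame
    efficiencies: pd.Series
    reference_gene: str
    calibrator_group: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} not in Ct table")
        if not np.isfinite(np.asarray(self.ct, dtype=float)).all():
            raise ValueError("Ct values must be finite")
        if (self.efficiencies <= 0).any():
            raise ValueError("efficiencies must be positive")

    def to_csv(self, path) -> None:
        self.ct.to_csv(path)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding: sample coordinates + variance shares."""

    coordinates: pd.DataFrame  # samples x axes
    proportion_explained: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportion_explained, dtype=float)
        if (np.diff(p) > 1e-12).any():
            raise ValueError("proportion_explained must be non-increasing")


@dataclass
class PartitionReport:
    """Per-group ASV partition arithmetic (UpSet-style summary).

    ``totals`` counts ASVs observed (pooled count > 0) per group, ``unique``
    the group-exclusive ones, ``shares`` each group's percent of the summed
    group totals (2 decimals), ``common_all`` the ASVs present in every group.
    """

    totals: dict[str, int]
    unique: dict[str, int]
    common_all: int
    shares: dict[str, float]

    def __post_init__(self) -> None:
        for g, u in self.unique.items():
            if u > self.totals[g]:
                raise ValueError("unique count cannot exceed group total")


@dataclass
class DifferentialResult:
    """Per-ASV differential screen for one contrast (groupA vs groupB).

    ``table`` holds columns log2fc, p, direction ('up' | 'down' | 'ns');
    log2fc > 0 means higher in groupA.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    pseudocount: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]
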