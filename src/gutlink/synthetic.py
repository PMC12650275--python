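"""Synthetic feeding-trial data with planted ground truth.

Emulates the statistical structure of a 4-diet x 3-replicate 16S amplicon
study: an overdispersed, sparse ASV count table dominated by a handful of
phyla, planted group-differential ASVs, planted correlated ASV modules whose
latent factors drive phenotype trait blocks, and a qPCR Ct table for
relative-expression quantification. Every generator takes an explicit seed
and returns a :class:`GroundTruth` record so downstream stages can be tested
for planted-effect recovery without any external data.

Count model: each ASV has a lognormal latent abundance (baseline +
group/module effects + lognormal noise), masked by a per-ASV occupancy
probability so most ASVs are absent from most samples; per-sample depths are
Poisson around ``depth_mean`` and counts are multinomial draws from the
latent relative abundances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import RANKS, AsvTable, CtTable, PhenotypeMatrix, TaxonomyTable

GROUP_POOL = ("CK", "HFD", "LSF", "HSF")

DEFAULT_PHYLUM_WEIGHTS: dict[str, float] = {
    "Proteobacteria": 0.35,
    "Actinobacteria": 0.20,
    "Chloroflexi": 0.15,
    "Firmicutes": 0.15,
    "Fusobacteria": 0.10,
    "Bacteroidota": 0.05,
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic study design.

    Defaults mirror the emulated trial: 4 diet groups x 3 replicates,
    ~1500 ASVs at ~33000 reads per sample.
    """

    n_groups: int = 4
    n_reps: int = 3
    n_asvs: int = 1500
    depth_mean: int = 33000
    n_diff_asvs: int = 30          # planted differential ASVs per contrast
    planted_log2fc: float = 3.0
    n_modules: int = 3             # planted correlated ASV modules
    module_size: int = 8
    module_strength: float = 1.0   # log-scale factor loading of module members
    module_noise_sd: float = 0.35  # member-specific log-noise; within-module
    #   log-scale correlation is strength^2 / (strength^2 + module_noise_sd^2),
    #   ~0.89 at the defaults, without letting the shared factor swing a
    #   module's total share enough to leak compositionally into other taxa
    module_phenotype_r: float = 0.9
    n_linked_modules: int | None = None  # None: every module drives a trait block
    noise_sd: float = 1.0          # lognormal dispersion (natural-log sd)
    phylum_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS)
    )
    traits_per_block: int = 3
    n_unlinked_blocks: int = 2
    trait_group_sd: float = 1.0    # group-effect sd of unlinked traits
    ct_genes: tuple[str, ...] = ("rpl17", "cat", "gpx1", "sod", "nfkb")
    ct_reference_gene: str = "rpl17"
    ct_noise_sd: float = 0.1
    ct_planted: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_reps", "n_asvs", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_diff_asvs < 0 or self.n_modules < 0 or self.module_size < 0:
            raise ValueError("planted-structure counts must be non-negative")
        planted = self.n_contrasts * self.n_diff_asvs + self.n_modules * self.module_size
        if planted > self.n_asvs:
            raise ValueError(
                f"infeasible config: {planted} planted ASVs "
                f"({self.n_contrasts} contrasts x {self.n_diff_asvs} differential + "
                f"{self.n_modules} modules x {self.module_size}) exceed n_asvs={self.n_asvs}"
            )
        total = float(sum(self.phylum_weights.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phylum_weights must sum to 1, got {total}")

    @property
    def n_contrasts(self) -> int:
        return self.n_groups - 1

    @property
    def group_names(self) -> list[str]:
        return [GROUP_POOL[i] if i < len(GROUP_POOL) else f"G{i + 1}" for i in range(self.n_groups)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.group_names for r in range(self.n_reps)]


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    group_assignment: pd.Series                      # sample -> group
    diff_asvs: dict[tuple[str, str], dict[str, float]]  # contrast -> asv -> signed log2fc
    module_membership: dict[str, int]                # asv -> module id
    module_trait_links: dict[int, str]               # module id -> trait-block label
    module_factors: pd.DataFrame                     # samples x module ids (latent scores)

    def to_json(self, path) -> None:
        payload = {
            "group_assignment": self.group_assignment.to_dict(),
            "diff_asvs": {f"{a}|{b}": d for (a, b), d in self.diff_asvs.items()},
            "module_membership": self.module_membership,
            "module_trait_links": {str(k): v for k, v in self.module_trait_links.items()},
            "module_factors": self.module_factors.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _taxonomy(asv_ids: list[str], config: SynthConfig, rng: np.random.Generator) -> TaxonomyTable:
    phyla = list(config.phylum_weights)
    probs = np.array([config.phylum_weights[p] for p in phyla], dtype=float)
    choice = rng.choice(len(phyla), size=len(asv_ids), p=probs)
    rows = []
    for i, asv in enumerate(asv_ids):
        ph = phyla[choice[i]]
        lineage = {"kingdom": "Bacteria", "phylum": ph}
        # lower ranks: nested synthetic labels, truncated to 'Unassigned'
        # with increasing probability toward species level
        code = rng.integers(1, 6, size=5)
        labels = [
            f"{ph[:4]}_c{code[0]}",
            f"{ph[:4]}_o{code[0]}{code[1]}",
            f"{ph[:4]}_f{code[0]}{code[1]}{code[2]}",
            f"{ph[:4]}_g{code[0]}{code[1]}{code[2]}{code[3]}",
            f"{ph[:4]}_s{code[0]}{code[1]}{code[2]}{code[3]}{code[4]}",
        ]
        cut = rng.choice([3, 4, 5, 5, 5])  # how many lower ranks are assigned
        for rank, lab, k in zip(RANKS[2:], labels, range(5)):
            lineage[rank] = lab if k < cut else "Unassigned"
        rows.append(lineage)
    return TaxonomyTable(pd.DataFrame(rows, index=asv_ids))


def generate_asv_table(config: SynthConfig) -> tuple[AsvTable, TaxonomyTable, GroundTruth]:
    """Draw one synthetic ASV table with planted differential and module structure.

    Returns the count table, its taxonomy and the :class:`GroundTruth`
    record. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    groups = config.group_names
    samples = config.sample_ids
    group_of = pd.Series(
        {s: g for g in groups for s in samples if s.rsplit("_", 1)[0] == g}, name="group"
    ).loc[samples]

    n = config.n_asvs
    width = len(str(n))
    asv_ids = [f"ASV{i + 1:0{width}d}" for i in range(n)]

    # planted index blocks: differential ASVs per contrast, then module ASVs
    cursor = 0
    diff_truth: dict[tuple[str, str], dict[str, float]] = {}
    contrasts = [(g, groups[0]) for g in groups[1:]]
    for contrast in contrasts:
        ids = asv_ids[cursor : cursor + config.n_diff_asvs]
        cursor += config.n_diff_asvs
        # alternate planted sign: half enriched, half depleted in the test group
        diff_truth[contrast] = {
            a: (config.planted_log2fc if k % 2 == 0 else -config.planted_log2fc)
            for k, a in enumerate(ids)
        }
    module_membership: dict[str, int] = {}
    for m in range(config.n_modules):
        for a in asv_ids[cursor : cursor + config.module_size]:
            module_membership[a] = m
        cursor += config.module_size
    planted = set(module_membership)
    for d in diff_truth.values():
        planted.update(d)

    # baseline log-abundance and occupancy
    mu = rng.normal(0.0, 2.0, size=n)
    occupancy = rng.beta(0.5, 1.0, size=n)
    diff_idx = np.array(
        sorted({col for d in diff_truth.values() for col in (asv_ids.index(a) for a in d)}),
        dtype=int,
    )
    module_idx = np.array(sorted(asv_ids.index(a) for a in module_membership), dtype=int)
    if diff_idx.size:
        # moderate baseline: detectable counts at typical depths, yet a small
        # enough share of reads that the planted shift does not feed back on
        # the compositional denominator
        mu[diff_idx] = rng.normal(1.0, 0.4, size=diff_idx.size)
        occupancy[diff_idx] = 1.0
    if module_idx.size:
        mu[module_idx] = rng.normal(1.0, 0.3, size=module_idx.size)
        occupancy[module_idx] = 1.0

    # per-(sample, asv) log effects
    log_eff = np.zeros((len(samples), n))
    sample_pos = {s: i for i, s in enumerate(samples)}
    col_pos = {a: j for j, a in enumerate(asv_ids)}
    ln2 = math.log(2.0)
    for (test_g, _ref), d in diff_truth.items():
        rows = [sample_pos[s] for s in samples if group_of[s] == test_g]
        for a, lfc in d.items():
            log_eff[np.ix_(rows, [col_pos[a]])] += lfc * ln2

    factors = rng.standard_normal((len(samples), config.n_modules))
    if config.n_modules:
        # standardize the realized factor so the planted within-module
        # correlation does not drift with an unlucky low-variance draw
        factors = (factors - factors.mean(axis=0)) / factors.std(axis=0)
    for a, m in module_membership.items():
        log_eff[:, col_pos[a]] += config.module_strength * factors[:, m]

    noise = rng.normal(0.0, config.noise_sd, size=(len(samples), n))
    if module_idx.size:  # module members get member-specific low noise instead
        noise[:, module_idx] = rng.normal(
            0.0, config.module_noise_sd, size=(len(samples), module_idx.size)
        )
    present = rng.random((len(samples), n)) < occupancy[None, :]
    latent = np.exp(mu[None, :] + log_eff + noise) * present
    # no sample may be entirely empty; keep the most abundant latent ASV
    for i in range(len(samples)):
        if latent[i].sum() == 0:
            latent[i, int(np.argmax(mu))] = 1.0

    depths = rng.poisson(config.depth_mean, size=len(samples))
    depths = np.maximum(depths, 1)
    counts = np.zeros((len(samples), n), dtype=np.int64)
    for i in range(len(samples)):
        counts[i] = rng.multinomial(depths[i], latent[i] / latent[i].sum())

    table = AsvTable(pd.DataFrame(counts, index=samples, columns=asv_ids), group_of)
    tax = _taxonomy(asv_ids, config, rng)
    n_linked = (
        config.n_modules if config.n_linked_modules is None else config.n_linked_modules
    )
    truth = GroundTruth(
        group_assignment=group_of,
        diff_asvs=diff_truth,
        module_membership=module_membership,
        module_trait_links={m: f"linked_block_{m}" for m in range(min(n_linked, config.n_modules))},
        module_factors=pd.DataFrame(
            factors, index=samples, columns=list(range(config.n_modules))
        ),
    )
    return table, tax, truth


def generate_phenotypes(truth: GroundTruth, config: SynthConfig) -> PhenotypeMatrix:
    """Trait panel driven by the planted module factors.

    Each planted module gets one linked trait block whose traits correlate
    with the module's latent factor at ``module_phenotype_r`` (alternating
    sign); ``n_unlinked_blocks`` additional blocks carry group effects but
    are independent of every module. Categories alternate between
    "Gut health" and "Gut development".
    """
    if truth is None:
        raise ValueError("ground truth required (run generate_asv_table first)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = list(truth.group_assignment.index)
    r = float(config.module_phenotype_r)
    cols: dict[str, np.ndarray] = {}
    cats: dict[str, str] = {}
    block_of_trait: dict[str, str] = {}

    for m, label in truth.module_trait_links.items():
        f = truth.module_factors[m].to_numpy()
        fz = (f - f.mean()) / (f.std() or 1.0)
        for t in range(config.traits_per_block):
            sign = 1.0 if t % 2 == 0 else -1.0
            eps = rng.standard_normal(len(samples))
            x = sign * (r * fz + math.sqrt(max(0.0, 1 - r * r)) * eps)
            name = f"{label}_trait{t + 1}"
            cols[name] = 10.0 + 2.0 * x
            cats[name] = "Gut health" if m % 2 == 0 else "Gut development"
            block_of_trait[name] = label

    group_codes = pd.Categorical(truth.group_assignment).codes
    for b in range(config.n_unlinked_blocks):
        shared = rng.standard_normal(len(samples))  # block-level latent, module-free
        offsets = rng.normal(0.0, config.trait_group_sd, size=group_codes.max() + 1)
        for t in range(config.traits_per_block):
            eps = rng.standard_normal(len(samples))
            x = 0.8 * shared + 0.4 * eps + offsets[group_codes]
            name = f"unlinked_block_{b}_trait{t + 1}"
            cols[name] = 5.0 + x
            cats[name] = "Gut development" if b % 2 == 0 else "Gut health"
            block_of_trait[name] = f"unlinked_block_{b}"

    values = pd.DataFrame(cols, index=samples)
    return PhenotypeMatrix(values, pd.Series(cats))


def generate_ct_table(config: SynthConfig) -> CtTable:
    """qPCR Ct matrix with a group-invariant reference gene.

    ``config.ct_planted`` maps gene -> group -> log2 fold-change of
    expression (a 2-fold up-regulation lowers Ct by one cycle). Per-sample
    template-amount shifts are added to every gene of a sample; they cancel
    in the ddCt computation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    groups = config.group_names
    samples = config.sample_ids
    group_of = pd.Series({s: s.rsplit("_", 1)[0] for s in samples}).loc[samples]

    base = {g: float(rng.uniform(18.0, 28.0)) for g in config.ct_genes}
    sample_shift = rng.normal(0.0, 0.5, size=len(samples))
    ct = np.zeros((len(samples), len(config.ct_genes)))
    for j, gene in enumerate(config.ct_genes):
        ct[:, j] = base[gene] + sample_shift
        planted = config.ct_planted.get(gene, {})
        for i, s in enumerate(samples):
            lfc = planted.get(group_of[s], 0.0)
            ct[i, j] -= lfc  # one cycle per planted doubling
    ct += rng.normal(0.0, config.ct_noise_sd, size=ct.shape)
    ct = np.clip(ct, 15.0, 35.0)

    eff = pd.Series(
        rng.uniform(85.0, 115.0, size=len(config.ct_genes)), index=list(config.ct_genes)
    )
    return CtTable(
        ct=pd.DataFrame(ct, index=samples, columns=list(config.ct_genes)),
        efficiencies=eff,
        reference_gene=config.ct_reference_gene,
        calibrator_group=groups[0],
        groups=group_of,
    )


def write_bundle(outdir, config: SynthConfig) -> dict[str, Path]:
    """Generate the full synthetic bundle and write it as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, tax, truth = generate_asv_table(config)
    phen = generate_phenotypes(truth, config)
    cts = generate_ct_table(config)
    paths = {
        "asv_table": outdir / "asv_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "ct_table": outdir / "ct_table.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    table.to_tsv(paths["asv_table"])
    tax.to_tsv(paths["taxonomy"])
    table.groups.rename("group").to_csv(paths["metadata"], index_label="sample_id")
    phen.to_csv(paths["phenotypes"])
    cts.to_csv(paths["ct_table"])
    truth.to_json(paths["ground_truth"])
    return paths
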