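"""End-to-end pipeline orchestration.

Runs the stages in order (profiles -> group stats -> differential screen ->
module linking -> ecological networks -> neutral model -> functional
projection) from a single :class:`RunConfig`, writes one results bundle per
run with a checksum manifest, and reproduces identical checksums when rerun
with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, function, linking, ncm, network, profiles, stats, synthetic
from .containers import AsvTable, CtTable, PhenotypeMatrix, TaxonomyTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and seeds of one pipeline run."""

    outdir: str = "results"
    seed: int = 0
    # input paths; when asv_table is None the synthetic bundle is generated
    asv_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    phenotypes: str | None = None
    ct_table: str | None = None
    # synthetic design (used when no input paths are given)
    synth: dict = field(default_factory=dict)
    # thresholds (the emulated study's printed parameters)
    rho_threshold: float = 0.7
    rho_alt_threshold: float = 0.8
    st_threshold: float = 0.995
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    mantel_r_threshold: float = 0.3
    mantel_perms: int = 999
    rarefy_depth: str | int = "auto"
    n_phenotype_blocks: int | None = None
    min_module_size: int = 3
    n_randomizations: int = 20
    network_top_asvs: int = 150
    reference_group: str | None = None

    def validate(self) -> None:
        for name in ("rho_threshold", "rho_alt_threshold", "st_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        for p in (self.asv_table, self.taxonomy, self.metadata, self.phenotypes, self.ct_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key != "synth":
                flat.update(val)
            else:
                flat[key] = val
        cfg = cls(**{k: v for k, v in flat.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_generate(config: RunConfig):
    if config.asv_table is None:
        synth_cfg = synthetic.SynthConfig(**{**config.synth, "seed": config.seed})
        table, tax, truth = synthetic.generate_asv_table(synth_cfg)
        phen = synthetic.generate_phenotypes(truth, synth_cfg)
        cts = synthetic.generate_ct_table(synth_cfg)
        return table, tax, phen, cts
    meta = pd.read_csv(config.metadata, index_col=0)["group"]
    table = AsvTable.from_tsv(config.asv_table, meta)
    tax = TaxonomyTable.from_tsv(config.taxonomy) if config.taxonomy else None
    phen = PhenotypeMatrix.from_csv(config.phenotypes) if config.phenotypes else None
    cts = None  # Ct tables need efficiencies/reference metadata; CLI passes them explicitly
    return table, tax, phen, cts


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("inputs")
        table, tax, phen, cts = _load_or_generate(config)

        stage("profiles")
        depth = (
            int(table.counts.sum(axis=1).min())
            if config.rarefy_depth == "auto"
            else int(config.rarefy_depth)
        )
        rarefied = profiles.rarefy(table, depth, seed=config.seed)
        part = profiles.group_asv_partition(rarefied)
        alpha = profiles.alpha_diversity(rarefied)
        rel = profiles.relative_abundance(rarefied)
        bc = profiles.bray_curtis(rel)
        ordn = profiles.pcoa(bc)
        alpha.to_csv(outdir / "alpha_diversity.csv")
        written["alpha_diversity"] = outdir / "alpha_diversity.csv"
        pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)).to_csv(
            outdir / "bray_curtis.tsv", sep="\t"
        )
        written["bray_curtis"] = outdir / "bray_curtis.tsv"
        ordn.coordinates.to_csv(outdir / "pcoa.csv")
        written["pcoa"] = outdir / "pcoa.csv"
        summary["partition"] = {
            "totals": part.totals,
            "unique": part.unique,
            "common_all": part.common_all,
            "shares": part.shares,
        }
        summary["pcoa_pct"] = [round(100 * p, 2) for p in ordn.proportion_explained[:2]]

        if phen is not None:
            stage("group_stats")
            report = stats.compare_all(phen.values, table.groups)
            report.to_csv(outdir / "phenotype_comparisons.csv", index=False)
            written["phenotype_comparisons"] = outdir / "phenotype_comparisons.csv"
        if cts is not None:
            gate = stats.efficiency_gate(cts)
            expr = pd.DataFrame(
                {
                    g: stats.ddct_expression(cts, g)
                    for g in cts.ct.columns
                    if g != cts.reference_gene
                }
            )
            expr.to_csv(outdir / "relative_expression.csv")
            written["relative_expression"] = outdir / "relative_expression.csv"
            summary["efficiency_pass"] = {k: bool(v) for k, v in gate.items()}

        stage("differential")
        groups = table.group_names
        ref = config.reference_group or groups[0]
        results = [
            differential.fit_differential(
                table, (g, ref),
                p_threshold=config.p_threshold, lfc_threshold=config.lfc_threshold,
            )
            for g in groups
            if g != ref
        ]
        diff_frames = []
        for res in results:
            frame = res.table.copy()
            frame.insert(0, "contrast", f"{res.contrast[0]}_vs_{res.contrast[1]}")
            diff_frames.append(frame)
        pd.concat(diff_frames).to_csv(outdir / "differential_asvs.csv", index_label="asv_id")
        written["differential_asvs"] = outdir / "differential_asvs.csv"
        shared = differential.shared_differentials(results)
        summary["differential"] = {
            f"{r.contrast[0]}_vs_{r.contrast[1]}": dict(
                zip(("n_up", "n_down"), differential.classify_counts(r))
            )
            for r in results
        }
        summary["differential"]["union"] = len(shared["union"])
        summary["differential"]["core"] = len(shared["intersection"])

        stage("linking")
        diff_asvs = sorted(shared["union"])
        link_summary: dict = {"n_differential_asvs": len(diff_asvs)}
        if len(diff_asvs) >= 4 and phen is not None:
            abund = profiles.clr(rel)[[a for a in diff_asvs if a in rel.columns]]
            net = linking.spearman_adjacency(abund, config.rho_threshold)
            labels = linking.detect_modules(net, min_size=config.min_module_size)
            mes = linking.eigenvectors_from_partition(abund, labels)
            n_blocks = config.n_phenotype_blocks or max(
                2, min(10, phen.values.shape[1] // 3)
            )
            blocks = linking.phenotype_modules(phen, n_blocks)
            links = linking.link_modules(
                mes, blocks,
                r_threshold=config.mantel_r_threshold, p_threshold=config.p_threshold,
                n_perm=config.mantel_perms, seed=config.seed, abundances=abund,
            )
            links.pairs.to_csv(outdir / "module_phenotype_links.csv", index=False)
            written["module_phenotype_links"] = outdir / "module_phenotype_links.csv"
            pd.Series(labels, name="module").to_csv(
                outdir / "module_membership.tsv", sep="\t", index_label="asv_id"
            )
            written["module_membership"] = outdir / "module_membership.tsv"
            sens = linking.sensitivity_check(
                abund, config.rho_threshold, config.rho_alt_threshold,
                min_size=config.min_module_size, phen_eigens=blocks,
                base_links=links, n_perm=config.mantel_perms, seed=config.seed,
            )
            sens.table.to_csv(outdir / "sensitivity.csv", index=False)
            written["sensitivity"] = outdir / "sensitivity.csv"
            link_summary.update(
                n_modules=len(mes),
                n_blocks=len(blocks),
                n_significant_links=int(links.pairs["significant"].sum()),
                biomarkers={
                    str(m): [a for a, _ in ranked[:5]] for m, ranked in links.biomarkers.items()
                },
                recovered_modules=[int(m) for m in sens.recovered_modules],
            )
        else:
            log.warning("linking skipped: too few differential ASVs or no phenotypes")
        summary["linking"] = link_summary

        stage("network")
        topo_cols = {}
        partitions = {}
        nulls = {}
        for g in groups:
            sub = table.group_counts(g)
            top = sub.sum(axis=0).sort_values(ascending=False).index[: config.network_top_asvs]
            gr_rel = sub[top].div(sub[top].sum(axis=1).replace(0, 1), axis=0)
            net_g = network.build_network(gr_rel, config.st_threshold)
            net_g.to_edge_tsv(outdir / f"network_{g}.tsv")
            written[f"network_{g}"] = outdir / f"network_{g}.tsv"
            if net_g.n_edges == 0:
                log.warning("group %s network has no edges at St=%s", g, config.st_threshold)
                continue
            topo = network.topology(net_g, min_module_size=config.min_module_size)
            topo_cols[g] = topo.as_series()
            partitions[g] = linking.detect_modules(net_g, min_size=config.min_module_size)
            null = network.random_null(
                net_g, n_rand=config.n_randomizations, seed=config.seed,
                min_module_size=config.min_module_size,
            )
            nulls[g] = {k: {"mean": v[0], "sd": v[1]} for k, v in null.stats.items()}
        if topo_cols:
            pd.DataFrame(topo_cols).to_csv(outdir / "network_topology.csv")
            written["network_topology"] = outdir / "network_topology.csv"
        summary["network_null"] = nulls
        if len(partitions) >= 2:
            pairs = network.module_similarity(partitions, alpha=config.p_threshold)
            pairs.pairs.to_csv(outdir / "module_pairs.csv", index=False)
            written["module_pairs"] = outdir / "module_pairs.csv"
            summary["module_pairs"] = {
                "total": pairs.total_pairs,
                "retained": pairs.retained_pairs,
                "retained_pct": pairs.retained_pct,
                "n_clusters": len(pairs.clusters),
            }

        stage("ncm")
        fit = ncm.fit_ncm(table)
        fit.table.to_csv(outdir / "ncm_fit.csv")
        written["ncm_fit"] = outdir / "ncm_fit.csv"
        summary["ncm"] = {"nm": fit.nm, "m": fit.m, "r_squared": fit.r_squared}

        stage("function")
        mapping = function.synthetic_mapping(table.asv_ids, seed=config.seed)
        pathways = function.filter_metabolism(function.project_ko(rel, mapping), mapping)
        fn_report = function.differential_pathways(pathways, rarefied.groups)
        fn_report.to_csv(outdir / "pathway_comparisons.csv", index=False)
        written["pathway_comparisons"] = outdir / "pathway_comparisons.csv"
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
    written["summary"] = outdir / "summary.json"
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "checksums": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
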