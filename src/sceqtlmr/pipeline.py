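"""End-to-end orchestration: instruments -> MR -> Q gate -> colocalization ->
aggregation -> enrichment -> (optional) single-cell DEG -> Tier scoring.

Every stage writes a plain tab-delimited table under the output directory so
any stage can be re-run and inspected in isolation, and a run manifest
records per-stage record counts (the Figure-2A-style survival summary),
the configuration snapshot and the seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg as deg_mod
from . import io as io_mod
from .aggregate import cross_trait_intersect, gate_candidates
from .coloc import ColocResult, run_coloc
from .config import PipelineConfig
from .enrichment import enrich_all
from .instruments import select_instruments
from .mr import bh_fdr_stratified, heterogeneity_gate, mr_results_frame, run_mr
from .simulate import (SimConfig, SimDataset, simulate_dataset, simulate_gmt,
                       simulate_sc_counts)
from .tier import build_scorecard, scheme_sensitivity, scorecards_frame

log = logging.getLogger("sceqtlmr")

__all__ = ["RunManifest", "run_all", "run_mr_stage", "run_tier_stage"]


@dataclass
class RunManifest:
    seed: int
    config: dict
    stage_counts: dict = field(default_factory=dict)
    stage_order: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stage_counts[stage] = {k: int(v) for k, v in counts.items()}
        self.stage_order.append(stage)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True))


def _binary_traits(ds: SimDataset) -> set[str]:
    return {t.name for t in ds.config.traits if t.binary}


def run_mr_stage(ds: SimDataset, config: PipelineConfig,
                 iv_pval: float | None = None) -> pd.DataFrame:
    """Instrument selection + MR for every (gene, cell type, trait).

    Returns the MR table with stratified FDR already applied. Instruments
    are selected per trait because the Steiger filter needs outcome
    statistics.
    """
    results = []
    kept_instruments = {}
    for gene_id, edf in ds.eqtl.groupby("gene_id", sort=True):
        ld = ds.ld_store[gene_id]
        snps = set(edf["snp_id"])
        for trait, gdf in ds.outcomes.items():
            gsub = gdf.loc[gdf["snp_id"].isin(snps)]
            inst = select_instruments(edf, gsub, ld, config, iv_pval=iv_pval)
            if inst.n_snp == 0:
                continue
            kept_instruments[(gene_id, trait)] = inst
            res = run_mr(inst, gsub, trait, config)
            if res is not None:
                results.append(res)
    results = bh_fdr_stratified(results)
    df = mr_results_frame(results)
    df.attrs["instruments"] = kept_instruments
    return df


def run_coloc_stage(ds: SimDataset, mr_df: pd.DataFrame,
                    config: PipelineConfig) -> pd.DataFrame:
    """Colocalization for MR signals passing FDR and the Q gate."""
    instruments = mr_df.attrs.get("instruments", {})
    binary = _binary_traits(ds)
    retained, _ = heterogeneity_gate(
        list(mr_df.itertuples(index=False)), config.q_alpha)
    rows = []
    for r in retained:
        if not (r.fdr_p < config.fdr_alpha):
            continue
        inst = instruments.get((r.gene_id, r.trait))
        if inst is None:
            continue
        edf = ds.eqtl.loc[(ds.eqtl["gene_id"] == r.gene_id)]
        gdf = ds.outcomes[r.trait]
        gdf = gdf.loc[gdf["snp_id"].isin(set(edf["snp_id"]))]
        res = run_coloc(inst.records, edf, gdf, ds.ld_store[r.gene_id],
                        config, r.gene_id, r.cell_type, r.trait,
                        binary_outcome=r.trait in binary)
        rows.append({k: v for k, v in res.__dict__.items()}
                    | {"evidence": res.evidence})
    if not rows:
        cols = [f.name for f in dataclasses.fields(ColocResult)]
        return pd.DataFrame(columns=cols + ["evidence"])
    return pd.DataFrame(rows)


def run_tier_stage(replicable: list[str],
                   mr_strict: pd.DataFrame,
                   coloc_df: pd.DataFrame,
                   pathway_counts: dict[str, int],
                   deg_evidence: dict[str, bool],
                   druggability: dict[str, str],
                   cell_types: dict[str, set[str]] | None = None,
                   ) -> pd.DataFrame:
    """Assemble evidence bundles for replicable genes and score them.

    ``mr_strict`` is the strict-instrument MR rerun; a trait counts toward
    the MR sensitivity score when its rerun p < 0.05. A trait counts toward
    the coloc sensitivity score when PP.H4 > 0.8.
    """
    cards = []
    for gene in sorted(replicable):
        sub = mr_strict.loc[(mr_strict["gene_id"] == gene)
                            & (mr_strict["pval"] < 0.05)] if len(mr_strict) else mr_strict
        mr_x = int(sub["trait"].nunique()) if len(sub) else 0
        if len(coloc_df):
            csub = coloc_df.loc[(coloc_df["gene_id"] == gene)
                                & (coloc_df["strict_pass"])]
            coloc_x = int(csub["trait"].nunique())
        else:
            coloc_x = 0
        cards.append(build_scorecard(
            gene=gene,
            mr_sens_x=min(mr_x, 3), coloc_sens_x=min(coloc_x, 3),
            enrich_x=int(pathway_counts.get(gene, 0)),
            deg_evidence=bool(deg_evidence.get(gene, False)),
            drug_class=druggability.get(gene, "none"),
            cell_types=";".join(sorted((cell_types or {}).get(gene, set()))),
        ))
    return scorecards_frame(cards), cards


def run_all(config: PipelineConfig | None = None,
            sim_config: SimConfig | None = None,
            outdir: str | Path = "results",
            with_deg: bool = True,
            druggability: dict[str, str] | None = None) -> RunManifest:
    """Run the whole pipeline on a simulated dataset and write every stage.

    Deterministic under a fixed ``sim_config.rng_seed``. When
    ``druggability`` is omitted, classes are drawn from a seeded stream at
    published-like proportions (most genes lack druggable evidence).
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimConfig(rng_seed=config.rng_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=sim_config.rng_seed, config=config.to_dict())

    ds = simulate_dataset(sim_config)
    io_mod.write_results_table(ds.eqtl, outdir / "eqtl.tsv")
    for name, gdf in ds.outcomes.items():
        io_mod.write_results_table(gdf, outdir / f"gwas_{name}.tsv")
    io_mod.write_results_table(ds.truth, outdir / "sim_truth.tsv")
    io_mod.write_ld_store(ds.ld_store, outdir / "ld")
    manifest.record("simulate", n_genes=sim_config.n_genes,
                    n_eqtl_rows=len(ds.eqtl),
                    n_gwas_rows=sum(len(v) for v in ds.outcomes.values()))

    mr_df = run_mr_stage(ds, config)
    io_mod.write_results_table(mr_df, outdir / "mr.tsv")
    n_inst = sum(i.n_snp for i in mr_df.attrs["instruments"].values())
    manifest.record("mr", n_instruments=n_inst, n_results=len(mr_df),
                    n_fdr_significant=int((mr_df["fdr_p"] < config.fdr_alpha).sum())
                    if len(mr_df) else 0)

    coloc_df = run_coloc_stage(ds, mr_df, config)
    io_mod.write_results_table(coloc_df, outdir / "coloc.tsv")
    manifest.record("coloc", n_tested=len(coloc_df),
                    n_evidence=int(coloc_df["evidence"].sum()) if len(coloc_df) else 0)

    trait_names = tuple(t.name for t in sim_config.traits)
    candidates = gate_candidates(mr_df, coloc_df if len(coloc_df) else
                                 pd.DataFrame(columns=["gene_id", "cell_type",
                                                       "trait", "rule_pass",
                                                       "ldcheck_pass"]),
                                 config)
    io_mod.write_results_table(candidates, outdir / "candidates.tsv")
    sets = cross_trait_intersect(candidates, traits=trait_names)
    pd.DataFrame({"gene_id": sorted(sets.replicable)}).to_csv(
        outdir / "replicable_genes.tsv", sep="\t", index=False)
    manifest.record("aggregate",
                    n_candidate_rows=int(candidates["candidate"].sum()),
                    n_one_trait=len(sets.one_trait),
                    n_two_plus=len(sets.two_plus),
                    n_replicable=len(sets.replicable))

    # enrichment over the union of per-trait candidate genes
    candidate_genes = set(
        candidates.loc[candidates["candidate"], "gene_id"])
    all_genes = sorted(ds.eqtl["gene_id"].unique())
    true_causal = sorted(set(
        ds.truth.loc[ds.truth["scenario"] == "H4", "gene_id"]))
    gmt = simulate_gmt(all_genes, enriched_genes=true_causal,
                       seed=sim_config.rng_seed + 1)
    io_mod.write_gmt(gmt, outdir / "genesets.gmt")
    enrich_df, pathway_counts = enrich_all(
        candidate_genes, gmt, universe=set(all_genes),
        p_cutoff=config.enrich_p)
    io_mod.write_results_table(enrich_df, outdir / "enrichment.tsv")
    manifest.record("enrich", n_terms=len(enrich_df),
                    n_significant=int(enrich_df["significant"].sum()))

    deg_evidence: dict[str, bool] = {}
    if with_deg:
        deg_targets = {g: (sim_config.sc_cell_types[0], sim_config.deg_lfc)
                       for g in true_causal[: sim_config.n_deg_genes]}
        adata = simulate_sc_counts(sim_config, deg_genes=deg_targets,
                                   gene_names=all_genes,
                                   seed=sim_config.rng_seed + 2)
        io_mod.write_sc_data(adata, outdir / "sc")
        adata = deg_mod.qc_filter(adata, config.qc_gene_min,
                                  config.qc_gene_max, config.qc_mito_max)
        adata = deg_mod.normalize(adata, config.norm_scale)
        test_genes = sorted(candidate_genes & set(adata.var_names))
        deg_rows = []
        for ct in sim_config.sc_cell_types:
            for res in deg_mod.deg_test(adata, ct, test_genes,
                                        config.deg_min_pct, config.deg_adj_p):
                deg_rows.append(res.__dict__)
                if res.significant:
                    deg_evidence[res.gene] = True
        deg_df = pd.DataFrame(deg_rows)
        io_mod.write_results_table(deg_df, outdir / "deg.tsv")
        manifest.record("deg", n_tested=len(deg_df),
                        n_significant=int(deg_df["significant"].sum())
                        if len(deg_df) else 0)

    if druggability is None:
        drug_rng = np.random.default_rng(
            np.random.SeedSequence(sim_config.rng_seed + 3))
        druggability = {
            g: str(drug_rng.choice(["available_drug", "druggable", "none"],
                                   p=[0.1, 0.3, 0.6]))
            for g in sorted(sets.replicable)}

    mr_strict = run_mr_stage(ds, config, iv_pval=config.iv_pval_strict)
    io_mod.write_results_table(mr_strict, outdir / "mr_strict.tsv")
    tier_df, cards = run_tier_stage(
        sorted(sets.replicable), mr_strict, coloc_df, pathway_counts,
        deg_evidence, druggability, cell_types=sets.gene_cell_types)
    io_mod.write_results_table(tier_df, outdir / "tier.tsv")
    if len(cards) >= 2:
        sens = scheme_sensitivity(cards)
        io_mod.write_results_table(sens, outdir / "tier_sensitivity.tsv")
    manifest.record("tier", n_scored=len(tier_df),
                    n_tier1=int((tier_df["tier"] == 1).sum()) if len(tier_df) else 0)
    manifest.to_json(outdir / "manifest.json")
    return manifest
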