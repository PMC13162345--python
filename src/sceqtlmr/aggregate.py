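"""Combine MR, heterogeneity and colocalization evidence into candidate gene
lists per trait, and intersect across traits to find replicable genes.

A (gene, cell type, trait) signal is a candidate iff its stratified FDR p is
below alpha, it was not excluded by the Cochran's Q gate, and colocalization
evidence (composite rule or LD check) is present. Replicable genes show
evidence for all three obesity-related traits; by default the cell type may
differ between traits (a strict same-cell-type mode is available).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig

log = logging.getLogger("sceqtlmr")

__all__ = ["CrossTraitSets", "gate_candidates", "cross_trait_intersect"]


@dataclass
class CrossTraitSets:
    one_trait: set[str]
    two_plus: set[str]
    replicable: set[str]
    per_cell_type: pd.DataFrame    # cell_type x n_candidate_pairs
    gene_traits: dict[str, set[str]] = field(default_factory=dict)
    gene_cell_types: dict[str, set[str]] = field(default_factory=dict)


def gate_candidates(mr: pd.DataFrame, coloc: pd.DataFrame,
                    config: PipelineConfig) -> pd.DataFrame:
    """Per-(gene, cell type, trait) candidate table.

    ``mr`` must carry ``fdr_p``, ``n_snp``, ``q_pval``; ``coloc`` must carry
    ``rule_pass`` and ``ldcheck_pass``. MR rows without a matching coloc row
    are treated as lacking colocalization evidence and logged.
    """
    key = ["gene_id", "cell_type", "trait"]
    cjoin = coloc[key + ["rule_pass", "ldcheck_pass"]].copy()
    merged = mr.merge(cjoin, on=key, how="left", validate="one_to_one")
    missing = merged["rule_pass"].isna().sum()
    if missing:
        log.info("gate_candidates: %d MR row(s) lack coloc rows; "
                 "treated as no coloc evidence", missing)
    for col in ("rule_pass", "ldcheck_pass"):
        merged[col] = merged[col].eq(True)   # NaN (no coloc row) -> False
    merged["coloc_evidence"] = merged["rule_pass"] | merged["ldcheck_pass"]
    het_excluded = (merged["n_snp"] >= 2) & (merged["q_pval"] < config.q_alpha)
    merged["het_excluded"] = het_excluded.fillna(False)
    merged["candidate"] = (
        (merged["fdr_p"] < config.fdr_alpha)
        & ~merged["het_excluded"]
        & merged["coloc_evidence"]
    )
    return merged


def cross_trait_intersect(candidates: pd.DataFrame,
                          traits: tuple[str, ...] = ("obesity", "bmi", "bodyfat"),
                          same_cell_type: bool = False) -> CrossTraitSets:
    """Partition candidate genes by how many traits show evidence.

    Gene-trait membership is the union over cell types unless
    ``same_cell_type`` is set, in which case a gene is replicable only if a
    single cell type carries evidence for every trait.
    """
    cand = candidates.loc[candidates["candidate"]]
    gene_traits: dict[str, set[str]] = {}
    gene_cells: dict[str, set[str]] = {}
    cell_trait: dict[tuple[str, str], set[str]] = {}
    for _, row in cand.iterrows():
        gene_traits.setdefault(row["gene_id"], set()).add(row["trait"])
        gene_cells.setdefault(row["gene_id"], set()).add(row["cell_type"])
        cell_trait.setdefault((row["gene_id"], row["cell_type"]), set()).add(row["trait"])
    one = {g for g, t in gene_traits.items() if len(t) == 1}
    two_plus = {g for g, t in gene_traits.items() if len(t) >= 2}
    if same_cell_type:
        replicable = {g for (g, _c), t in cell_trait.items() if set(traits) <= t}
    else:
        replicable = {g for g, t in gene_traits.items() if set(traits) <= t}
    per_ct = (
        cand.drop_duplicates(["gene_id", "cell_type"])
        .groupby("cell_type").size().rename("n_candidate_pairs")
        .reset_index()
    )
    return CrossTraitSets(one_trait=one, two_plus=two_plus,
                          replicable=replicable, per_cell_type=per_ct,
                          gene_traits=gene_traits, gene_cell_types=gene_cells)
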