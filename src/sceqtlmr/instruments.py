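"""Instrument selection for one (gene, cell type) exposure.

The filter chain follows the order: association p-value threshold, greedy LD
clumping, per-SNP F-statistic floor, then Steiger directionality against the
outcome. Each retained SNP therefore satisfies all four predicates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .records import LdMatrix

__all__ = [
    "InstrumentSet",
    "SteigerResult",
    "filter_by_pval",
    "ld_clump",
    "f_statistic",
    "steiger_filter",
    "select_instruments",
]


@dataclass
class SteigerResult:
    keep: bool
    r2_exposure: float
    r2_outcome: float
    steiger_p: float


@dataclass
class InstrumentSet:
    """Post-filter instruments for one (gene, cell type) and one outcome."""

    gene_id: str
    cell_type: str
    records: pd.DataFrame          # canonical eQTL rows surviving all filters
    provenance: pd.DataFrame = field(default=None)  # per-SNP filter outcomes

    @property
    def n_snp(self) -> int:
        return len(self.records)


def filter_by_pval(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep records with pval strictly below ``threshold``, order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0,1]")
    return records.loc[records["pval"] < threshold].copy()


def _clump_order(records: pd.DataFrame) -> pd.DataFrame:
    # greedy order: ascending p, ties broken by genomic position then id
    return records.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    )


def ld_clump(records: pd.DataFrame, ld: LdMatrix, r2_max: float) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly retain the most significant remaining SNP and remove every SNP
    with r^2 >= ``r2_max`` to it. The returned set has pairwise r^2 < r2_max.
    Ties in p are broken by (chrom, pos, snp_id) so the result is independent
    of input row order.
    """
    if records.empty:
        return records.copy()
    missing = [s for s in records["snp_id"] if s not in ld]
    if missing:
        raise KeyError(f"SNP(s) absent from LD matrix: {missing[:5]}")
    ordered = _clump_order(records)
    kept_ids: list[str] = []
    removed: set[str] = set()
    for snp in ordered["snp_id"]:
        if snp in removed:
            continue
        kept_ids.append(snp)
        for other in ordered["snp_id"]:
            if other != snp and other not in removed and ld.r2(snp, other) >= r2_max:
                removed.add(other)
    keep_mask = records["snp_id"].isin(kept_ids)
    return records.loc[keep_mask].copy()


def f_statistic(beta, se):
    """Single-SNP instrument strength, F = (beta/se)^2 = z^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def _z_to_r2(z: float, n: float) -> float:
    return z * z / (z * z + n - 2.0)


def steiger_filter(beta_exp: float, se_exp: float, n_exposure: float,
                   beta_out: float, se_out: float, n_outcome: float
                   ) -> SteigerResult:
    """Directionality check for one harmonized SNP.

    Variance explained on each side is inferred from the z-statistic,
    r^2 = z^2 / (z^2 + n - 2); the SNP is kept when it explains strictly
    more variance in the exposure than in the outcome. ``steiger_p`` is the
    two-sided p of the z-test on Fisher-transformed |r| with variances
    1/(n-3); it is reported, not thresholded.
    """
    if n_exposure <= 3 or n_outcome <= 3:
        raise ValueError("Steiger test requires n > 3 on both sides")
    r2_exp = _z_to_r2(beta_exp / se_exp, n_exposure)
    r2_out = _z_to_r2(beta_out / se_out, n_outcome)
    r_exp, r_out = math.sqrt(r2_exp), math.sqrt(r2_out)
    # Fisher transforms of |r| compared with independent sampling variances
    z_diff = (np.arctanh(r_exp) - np.arctanh(r_out)) / math.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z_diff))
    return SteigerResult(keep=r2_exp > r2_out, r2_exposure=r2_exp,
                         r2_outcome=r2_out, steiger_p=float(p))


def select_instruments(
    eqtl: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LdMatrix,
    config: PipelineConfig,
    iv_pval: float | None = None,
) -> InstrumentSet:
    """Run the full filter chain for one (gene, cell type, outcome).

    ``eqtl`` holds the canonical eQTL rows of a single gene/cell type;
    ``outcome`` the GWAS rows (indexed by snp_id match). SNPs missing from
    the outcome cannot be Steiger-tested and are dropped with provenance.
    """
    iv_pval = config.iv_pval if iv_pval is None else iv_pval
    gene_id = eqtl["gene_id"].iloc[0] if len(eqtl) else ""
    cell_type = eqtl["cell_type"].iloc[0] if len(eqtl) else ""

    prov = eqtl[["snp_id", "pval"]].copy()
    stage1 = filter_by_pval(eqtl, iv_pval)
    prov["pass_pval"] = prov["snp_id"].isin(stage1["snp_id"])

    stage2 = ld_clump(stage1, ld, config.clump_r2) if len(stage1) else stage1
    prov["pass_clump"] = prov["snp_id"].isin(stage2["snp_id"]) & prov["pass_pval"]

    if len(stage2):
        fvals = f_statistic(stage2["beta"].to_numpy(), stage2["se"].to_numpy())
        stage3 = stage2.loc[fvals > config.f_min].copy()
        stage3["f_stat"] = fvals[fvals > config.f_min]
    else:
        stage3 = stage2.copy()
        stage3["f_stat"] = pd.Series(dtype=float)
    prov["pass_f"] = prov["snp_id"].isin(stage3["snp_id"]) & prov["pass_clump"]

    out_by_snp = outcome.set_index("snp_id")
    keep_rows, r2e, r2o, sp = [], [], [], []
    for _, row in stage3.iterrows():
        if row["snp_id"] not in out_by_snp.index:
            continue
        orow = out_by_snp.loc[row["snp_id"]]
        res = steiger_filter(row["beta"], row["se"], row["n"],
                             orow["beta"], orow["se"], orow["n"])
        if res.keep:
            keep_rows.append(row)
            r2e.append(res.r2_exposure)
            r2o.append(res.r2_outcome)
            sp.append(res.steiger_p)
    final = pd.DataFrame(keep_rows).reset_index(drop=True)
    if len(final):
        final["steiger_r2_exp"] = r2e
        final["steiger_r2_out"] = r2o
        final["steiger_p"] = sp
    prov["pass_steiger"] = prov["snp_id"].isin(
        final["snp_id"] if len(final) else []
    ) & prov["pass_f"]
    return InstrumentSet(gene_id=gene_id, cell_type=cell_type,
                         records=final, provenance=prov)
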