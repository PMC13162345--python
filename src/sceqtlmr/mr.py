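"""Two-sample MR estimation: harmonization, Wald ratio, IVW, Cochran's Q,
and Benjamini-Hochberg FDR stratified by (cell type, trait).

Single-instrument genes are estimated by the Wald ratio; genes with two or
more instruments by inverse-variance weighting of the per-SNP ratios. The
default IVW mode is multiplicative random effects: the fixed-effect standard
error is inflated by max(1, sqrt(Q/df)), matching the behavior of the
standard two-sample MR toolchain. A fixed-effect mode is available by flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .instruments import InstrumentSet

__all__ = [
    "HarmonizedPair",
    "MRResult",
    "harmonize",
    "harmonize_tables",
    "wald_ratio",
    "ivw",
    "run_mr",
    "bh_fdr_stratified",
    "heterogeneity_gate",
]


@dataclass
class HarmonizedPair:
    """Exposure and outcome statistics for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    n_exp: float = np.nan
    n_out: float = np.nan
    eaf: float = np.nan
    flipped: bool = False
    palindromic_dropped: bool = False
    drop_reason: str = ""

    @property
    def dropped(self) -> bool:
        return bool(self.drop_reason)


@dataclass
class MRResult:
    gene_id: str
    cell_type: str
    trait: str
    method: str                   # "wald_ratio" | "ivw"
    n_snp: int
    beta: float
    se: float
    pval: float
    fdr_p: float = np.nan
    q_stat: float = np.nan
    q_df: float = np.nan
    q_pval: float = np.nan
    gene_symbol: str = ""
    snp_ids: str = ""


def _minor_af(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(exposure, outcome,
              palindromic_window: tuple[float, float] = (0.42, 0.58)
              ) -> HarmonizedPair:
    """Align one outcome record to the exposure effect allele.

    ``exposure`` and ``outcome`` are canonical rows (Series / dataclass-like
    with attribute or item access). Swapped allele coding negates the outcome
    beta and flips its EAF. Palindromic SNPs (A/T, C/G) whose EAF on either
    side lies inside ``palindromic_window`` are ambiguous and dropped.
    Incompatible allele sets are dropped with a reason code.
    """
    def get(rec, name):
        return rec[name] if not hasattr(rec, name) else getattr(rec, name)

    ea_x, oa_x = str(get(exposure, "effect_allele")).upper(), str(get(exposure, "other_allele")).upper()
    ea_y, oa_y = str(get(outcome, "effect_allele")).upper(), str(get(outcome, "other_allele")).upper()
    pair = HarmonizedPair(
        snp_id=str(get(exposure, "snp_id")),
        beta_exp=float(get(exposure, "beta")), se_exp=float(get(exposure, "se")),
        beta_out=float(get(outcome, "beta")), se_out=float(get(outcome, "se")),
        n_exp=float(get(exposure, "n")), n_out=float(get(outcome, "n")),
        eaf=float(get(exposure, "eaf")),
    )
    palindromic = {ea_x, oa_x} in ({"A", "T"}, {"C", "G"})
    lo, hi = palindromic_window
    if palindromic:
        for eaf in (float(get(exposure, "eaf")), float(get(outcome, "eaf"))):
            if lo < eaf < hi:
                pair.palindromic_dropped = True
                pair.drop_reason = "palindromic_ambiguous"
                return pair
    if (ea_y, oa_y) == (ea_x, oa_x):
        return pair
    if (ea_y, oa_y) == (oa_x, ea_x):
        pair.beta_out = -pair.beta_out
        pair.flipped = True
        return pair
    pair.drop_reason = "allele_mismatch"
    return pair


def harmonize_tables(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     palindromic_window=(0.42, 0.58)) -> list[HarmonizedPair]:
    """Harmonize all shared SNPs between two canonical tables (kept pairs only)."""
    out_by_snp = outcome.set_index("snp_id")
    pairs = []
    for _, row in exposure.iterrows():
        if row["snp_id"] not in out_by_snp.index:
            continue
        p = harmonize(row, out_by_snp.loc[row["snp_id"]], palindromic_window)
        if not p.dropped:
            pairs.append(p)
    return pairs


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float, float]:
    """Single-instrument causal estimate with first-order delta-method SE."""
    if pair.beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return beta, se, float(pval)


def ivw(pairs: Sequence[HarmonizedPair], random_effects: bool = True
        ) -> tuple[float, float, float, float, float, float]:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    Per-SNP ratio b_i = beta_out_i / beta_exp_i with weight
    w_i = (beta_exp_i / se_out_i)^2 (first-order ratio variance). Returns
    (beta, se, pval, Q, df, q_pval); in multiplicative-random-effects mode
    the fixed-effect SE is scaled by max(1, sqrt(Q/df)).
    """
    if len(pairs) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    b_exp = np.array([p.beta_exp for p in pairs], dtype=float)
    if np.any(b_exp == 0):
        raise ZeroDivisionError("IVW undefined with beta_exp = 0 instrument")
    b_out = np.array([p.beta_out for p in pairs], dtype=float)
    se_out = np.array([p.se_out for p in pairs], dtype=float)
    ratios = b_out / b_exp
    w = (b_exp / se_out) ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(pairs) - 1
    q_pval = float(stats.chi2.sf(q, df))
    se = se_fixed * max(1.0, np.sqrt(q / df)) if random_effects else se_fixed
    pval = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, pval, q, float(df), q_pval


def run_mr(instruments: InstrumentSet, outcome: pd.DataFrame, trait: str,
           config: PipelineConfig) -> MRResult | None:
    """Harmonize an instrument set against one outcome and estimate.

    Routes to the Wald ratio for a single harmonized instrument and to IVW
    for two or more. Returns ``None`` (with a log-worthy reason) when no
    instrument survives harmonization.
    """
    pairs = harmonize_tables(instruments.records, outcome,
                             config.palindromic_eaf_window)
    if not pairs:
        return None
    symbol = (instruments.records["gene_symbol"].iloc[0]
              if "gene_symbol" in instruments.records.columns and len(instruments.records)
              else "")
    common = dict(gene_id=instruments.gene_id, cell_type=instruments.cell_type,
                  trait=trait, gene_symbol=symbol,
                  snp_ids=",".join(p.snp_id for p in pairs))
    if len(pairs) == 1:
        beta, se, pval = wald_ratio(pairs[0])
        return MRResult(method="wald_ratio", n_snp=1, beta=beta, se=se,
                        pval=pval, **common)
    beta, se, pval, q, df, q_pval = ivw(pairs, config.ivw_random_effects)
    return MRResult(method="ivw", n_snp=len(pairs), beta=beta, se=se,
                    pval=pval, q_stat=q, q_df=df, q_pval=q_pval, **common)


def bh_fdr_stratified(results: Iterable[MRResult]) -> list[MRResult]:
    """BH step-up adjustment applied separately within each (cell type, trait).

    Strata never share an adjustment pool, matching an FDR design where each
    cell type-trait combination is its own family of tests.
    """
    results = list(results)
    by_stratum: dict[tuple[str, str], list[MRResult]] = {}
    for r in results:
        by_stratum.setdefault((r.cell_type, r.trait), []).append(r)
    for group in by_stratum.values():
        pvals = np.array([r.pval for r in group])
        adj = multipletests(pvals, method="fdr_bh")[1]
        for r, a in zip(group, adj):
            r.fdr_p = float(a)
    return results


def heterogeneity_gate(results: Iterable[MRResult], q_alpha: float = 0.05
                       ) -> tuple[list[MRResult], list[MRResult]]:
    """Exclude multi-instrument results with Cochran's Q p-value < q_alpha.

    Single-instrument (Wald) results carry no Q statistic and are always
    retained.
    """
    retained, excluded = [], []
    for r in results:
        if r.n_snp >= 2 and np.isfinite(r.q_pval) and r.q_pval < q_alpha:
            excluded.append(r)
        else:
            retained.append(r)
    return retained, excluded


def mr_results_frame(results: Sequence[MRResult]) -> pd.DataFrame:
    import dataclasses
    if not results:
        return pd.DataFrame(columns=[f.name for f in dataclasses.fields(MRResult)])
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
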