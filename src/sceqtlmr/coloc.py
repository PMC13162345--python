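"""Approximate-Bayes-factor colocalization under a single causal variant.

For each trait, every SNP's evidence is a Wakefield log-ABF computed from
(beta, se) and a prior effect standard deviation. The five locus hypotheses
(H0 no association; H1/H2 one trait only; H3 both traits, distinct variants;
H4 both traits, shared variant) are scored in log space with per-SNP priors
p1, p2, p12; the H3 cross term is accumulated by a masked pairwise sum, so
no catastrophic cancellation can occur.

The composite decision rule is (PP.H3 + PP.H4) > rule_sum together with
PP.H4 / (PP.H3 + PP.H4) > rule_ratio; a stricter single-number gate uses
PP.H4 alone. An LD-check fallback accepts a locus when the instrument is in
r^2 >= 0.7 with a genome-wide-significant outcome SNP in the window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import PipelineConfig
from .records import LdMatrix

__all__ = [
    "ColocResult",
    "extract_window",
    "wakefield_log_abf",
    "coloc_abf",
    "coloc_decision",
    "ld_check",
    "run_coloc",
]

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass
class ColocResult:
    gene_id: str
    cell_type: str
    trait: str
    chrom: str
    window_start: int
    window_end: int
    n_snps: int
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    rule_pass: bool
    strict_pass: bool
    ldcheck_max_r2: float = np.nan
    ldcheck_pass: bool = False
    skipped: str = ""

    @property
    def evidence(self) -> bool:
        """Locus-level colocalization evidence: composite rule OR LD check."""
        return bool(self.rule_pass or self.ldcheck_pass)

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2,
                         self.pp_h3, self.pp_h4])


def extract_window(records: pd.DataFrame, chrom: str, pos: int,
                   half_width: int) -> pd.DataFrame:
    """Rows on ``chrom`` with |pos - anchor| <= half_width (closed interval)."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    mask = (records["chrom"].astype(str) == str(chrom)) & (
        (records["pos"] - pos).abs() <= half_width
    )
    return records.loc[mask].copy()


def wakefield_log_abf(beta, se, prior_sd: float):
    """Wakefield's log approximate Bayes factor for one association.

    With z = beta/se, V = se^2 and W = prior_sd^2:
        logABF = 0.5 * log(V / (V + W)) + (z^2 / 2) * W / (V + W)
    Positive values favor association; a null SNP is penalized by the
    shrinkage term alone.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    z = beta / se
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    out = 0.5 * np.log1p(-r) + 0.5 * z * z * r
    return float(out) if out.ndim == 0 else out


def coloc_abf(beta1, se1, beta2, se2,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              prior_sd1: float = 0.15, prior_sd2: float = 0.2) -> np.ndarray:
    """Posterior probabilities of the five hypotheses for one locus.

    The two traits must be supplied on an identical, identically ordered SNP
    panel. Returns ``[PP.H0, PP.H1, PP.H2, PP.H3, PP.H4]`` summing to 1.
    """
    l1 = np.atleast_1d(wakefield_log_abf(beta1, se1, prior_sd1))
    l2 = np.atleast_1d(wakefield_log_abf(beta2, se2, prior_sd2))
    if l1.shape != l2.shape:
        raise ValueError("trait SNP panels differ in length")
    n = l1.size
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    if n > 1:
        # H3 cross term sum_{i != j} exp(l1_i + l2_j): masked pairwise sum,
        # exact in log space (no subtraction of nearly equal sums)
        cross = l1[:, None] + l2[None, :]
        np.fill_diagonal(cross, -np.inf)
        s3 = logsumexp(cross)
    else:
        s3 = -np.inf
    log_w = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + s3,
        np.log(p12) + s12,
    ])
    pp = np.exp(log_w - logsumexp(log_w))
    return pp / pp.sum()


def coloc_decision(pp: np.ndarray, rule_sum: float = 0.8,
                   rule_ratio: float = 0.9, strict_pp4: float = 0.8
                   ) -> tuple[bool, bool]:
    """Apply the composite rule and the strict PP.H4 gate to one pp vector."""
    pp = np.asarray(pp, dtype=float)
    h3, h4 = pp[3], pp[4]
    total = h3 + h4
    ratio = h4 / total if total > 0 else 0.0
    rule_pass = bool(total > rule_sum and ratio > rule_ratio)
    strict_pass = bool(h4 > strict_pp4)
    return rule_pass, strict_pass


def ld_check(instrument_snp: str, gwas_window: pd.DataFrame, ld: LdMatrix,
             r2_min: float = 0.7, gwas_signal_p: float = 5e-8
             ) -> tuple[float, bool]:
    """Approximate colocalization via LD with a significant outcome SNP.

    Returns (max r^2 between the instrument and any window SNP with
    p < gwas_signal_p, pass flag). When no such signal SNP exists the check
    fails with max_r2 = NaN.
    """
    if instrument_snp not in ld:
        raise KeyError(f"instrument SNP {instrument_snp!r} absent from LD matrix")
    signals = gwas_window.loc[gwas_window["pval"] < gwas_signal_p, "snp_id"]
    signals = [s for s in signals if s in ld]
    if not signals:
        return float("nan"), False
    max_r2 = max(ld.r2(instrument_snp, s) for s in signals)
    return max_r2, bool(max_r2 >= r2_min)


def run_coloc(instruments: pd.DataFrame, eqtl: pd.DataFrame,
              gwas: pd.DataFrame, ld: LdMatrix, config: PipelineConfig,
              gene_id: str, cell_type: str, trait: str,
              binary_outcome: bool = False) -> ColocResult:
    """Colocalize one (gene, cell type, trait) signal.

    A +/- ``coloc_window_bp`` window is taken around each instrument SNP;
    evidence is the OR over instruments of the composite rule and LD check,
    and the reported posterior vector is the one from the most significant
    instrument's window.
    """
    sd2 = config.coloc_sd_binary if binary_outcome else config.coloc_sd_quant
    best: ColocResult | None = None
    any_rule = any_strict = any_ld = False
    max_r2_seen = np.nan
    ordered = instruments.sort_values(["pval", "chrom", "pos", "snp_id"],
                                      kind="mergesort")
    for _, inst in ordered.iterrows():
        chrom, pos = str(inst["chrom"]), int(inst["pos"])
        ew = extract_window(eqtl, chrom, pos, config.coloc_window_bp)
        gw = extract_window(gwas, chrom, pos, config.coloc_window_bp)
        shared = sorted(set(ew["snp_id"]) & set(gw["snp_id"]))
        r2, ld_pass = ld_check(inst["snp_id"], gw, ld,
                               config.ldcheck_r2, config.ldcheck_gwas_p)
        if np.isfinite(r2) and not (np.isfinite(max_r2_seen) and max_r2_seen >= r2):
            max_r2_seen = r2
        any_ld |= ld_pass
        if not shared:
            if best is None:
                best = ColocResult(gene_id, cell_type, trait, chrom,
                                   pos - config.coloc_window_bp,
                                   pos + config.coloc_window_bp, 0,
                                   *np.full(5, np.nan), False, False,
                                   skipped="no_shared_snps")
            continue
        e = ew.set_index("snp_id").loc[shared]
        g = gw.set_index("snp_id").loc[shared]
        pp = coloc_abf(e["beta"].to_numpy(), e["se"].to_numpy(),
                       g["beta"].to_numpy(), g["se"].to_numpy(),
                       config.coloc_p1, config.coloc_p2, config.coloc_p12,
                       config.coloc_sd_quant, sd2)
        rule_pass, strict_pass = coloc_decision(
            pp, config.coloc_rule_sum, config.coloc_rule_ratio,
            config.coloc_strict_pp4)
        any_rule |= rule_pass
        any_strict |= strict_pass
        if best is None or best.skipped:
            best = ColocResult(gene_id, cell_type, trait, chrom,
                               pos - config.coloc_window_bp,
                               pos + config.coloc_window_bp, len(shared),
                               *pp, rule_pass, strict_pass)
    if best is None:
        raise ValueError("run_coloc called with an empty instrument set")
    best.rule_pass = any_rule
    best.strict_pass = any_strict
    best.ldcheck_pass = any_ld
    best.ldcheck_max_r2 = max_r2_seen
    return best
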