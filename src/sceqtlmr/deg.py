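"""Single-cell lean-vs-obese differential expression for candidate genes.

Counts live in an :class:`anndata.AnnData` (cells x genes) whose ``obs``
carries ``donor``, ``group`` (lean/obese) and ``cell_type`` labels and whose
``var`` carries a ``mito`` flag. Cells are QC-filtered on detected-gene count
(closed range) and mitochondrial fraction (strictly-exceeding rule), counts
are library-size normalized to a fixed scale and log1p-transformed, and each
candidate gene is tested per cell type with a two-sided Wilcoxon rank-sum
(exact when both groups are small) under Bonferroni correction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import anndata as ad

log = logging.getLogger("sceqtlmr")

__all__ = [
    "DegResult",
    "qc_filter",
    "normalize",
    "deg_test",
    "direction_consistency",
]

GROUPS = ("lean", "obese")


@dataclass
class DegResult:
    gene: str
    cell_type: str
    mean_lean: float
    mean_obese: float
    log_fc: float            # natural-log FC, obese minus lean
    pct_lean: float
    pct_obese: float
    p: float
    bonferroni_p: float
    significant: bool
    n_lean: int = 0
    n_obese: int = 0


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def qc_filter(adata: ad.AnnData, gene_min: int = 200, gene_max: int = 8000,
              mito_max: float = 0.25) -> ad.AnnData:
    """Retain cells with detected genes in [gene_min, gene_max] and
    mitochondrial fraction <= mito_max (strictly exceeding cells removed)."""
    if "mito" not in adata.var.columns:
        raise ValueError("gene metadata must carry a 'mito' flag")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito_counts = X[:, adata.var["mito"].to_numpy(dtype=bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    keep = (detected >= gene_min) & (detected <= gene_max) & (mito_frac <= mito_max)
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("qc_filter: removed %d of %d cells", n_removed, adata.n_obs)
    return adata[keep].copy()


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Per-cell library-size normalization to ``scale`` followed by log1p.

    x -> log(1 + scale * x / total_counts). Cells with zero total counts are
    removed with a log entry. The result is stored in ``adata.X``; raw counts
    are kept in ``adata.layers["counts"]``.
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        log.info("normalize: removed %d zero-count cell(s)", int((~nonzero).sum()))
        adata = adata[nonzero].copy()
        X = X[nonzero]
        totals = totals[nonzero]
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(scale * X / totals[:, None])
    return out


def _wilcoxon_p(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact null distribution when both groups have <= ``exact_max``
    observations; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    method = "exact" if max(len(x), len(y)) <= exact_max else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def deg_test(adata: ad.AnnData, cell_type: str, genes: list[str],
             min_pct: float = 0.1, adj_p: float = 0.05) -> list[DegResult]:
    """Lean-vs-obese Wilcoxon tests for candidate genes in one cell type.

    ``adata`` must already be QC-filtered and normalized. Genes detected in
    fewer than ``min_pct`` of cells in both groups are not tested (and do
    not enter the Bonferroni denominator). The log fold change is computed
    on the de-logged normalized scale: log(mean(expm1(x)) + 1) per group.
    """
    sub = adata[adata.obs["cell_type"] == cell_type]
    lean = sub[sub.obs["group"] == "lean"]
    obese = sub[sub.obs["group"] == "obese"]
    if lean.n_obs < 3 or obese.n_obs < 3:
        raise ValueError(
            f"cell type {cell_type!r}: need >= 3 cells per group "
            f"(lean={lean.n_obs}, obese={obese.n_obs})")
    present = [g for g in genes if g in adata.var_names]
    testable = []
    for g in present:
        xl = _dense(lean[:, g].X).ravel()
        xo = _dense(obese[:, g].X).ravel()
        if (xl > 0).mean() >= min_pct or (xo > 0).mean() >= min_pct:
            testable.append((g, xl, xo))
    m = len(testable)
    results = []
    for g, xl, xo in testable:
        p = _wilcoxon_p(xo, xl)
        bonf = min(1.0, p * m)
        lfc = float(np.log(np.expm1(xo).mean() + 1.0)
                    - np.log(np.expm1(xl).mean() + 1.0))
        results.append(DegResult(
            gene=g, cell_type=cell_type,
            mean_lean=float(xl.mean()), mean_obese=float(xo.mean()),
            log_fc=lfc, pct_lean=float((xl > 0).mean()),
            pct_obese=float((xo > 0).mean()), p=p, bonferroni_p=bonf,
            significant=bool(bonf < adj_p),
            n_lean=len(xl), n_obese=len(xo)))
    return results


def direction_consistency(deg: DegResult, mr_beta: float) -> bool:
    """True iff the DEG is significant and its obese-minus-lean sign matches
    the MR effect sign. An exactly zero MR beta is never consistent."""
    if not deg.significant or mr_beta == 0 or deg.log_fc == 0:
        return False
    return bool(np.sign(deg.log_fc) == np.sign(mr_beta))
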