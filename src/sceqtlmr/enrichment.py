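"""Over-representation analysis of candidate genes against GMT gene sets.

The test is the hypergeometric upper tail P[X >= k] for k candidate genes
falling in a K-gene term, drawn from an N-gene universe. Raw p < 0.05 drives
the per-gene pathway counts used by the Tier system; BH-adjusted values are
reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "ora_test", "enrich_all"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_k: int
    term_size_K: int
    candidates_n: int
    universe_N: int
    p: float
    bh_p: float = np.nan
    overlap_genes: tuple[str, ...] = ()


def ora_test(candidates: set[str], term: set[str], universe: set[str],
             term_id: str = "", term_name: str = "") -> EnrichmentResult:
    """Hypergeometric over-representation test for one gene set."""
    if not universe:
        raise ValueError("empty gene universe")
    term = term & universe
    cands = candidates & universe
    overlap = cands & term
    k, K, n, N = len(overlap), len(term), len(cands), len(universe)
    # upper tail P[X >= k]
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    return EnrichmentResult(term_id=term_id, term_name=term_name,
                            overlap_k=k, term_size_K=K, candidates_n=n,
                            universe_N=N, p=p,
                            overlap_genes=tuple(sorted(overlap)))


def enrich_all(candidates: set[str],
               collection: Mapping[str, tuple[str, set[str]]],
               universe: set[str] | None = None,
               p_cutoff: float = 0.05
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Test every term in a GMT collection.

    The universe defaults to the union of all term genes; callers wanting
    the MR-tested background pass it explicitly. Returns (results table with
    ``significant`` flags, per-gene count of significant terms containing
    the gene).
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    if universe is None:
        universe = set().union(*(genes for _d, genes in collection.values()))
    results = [
        ora_test(candidates, genes, universe, term_id=tid, term_name=desc)
        for tid, (desc, genes) in collection.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["bh_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p"] < p_cutoff
    counts: dict[str, int] = {g: 0 for g in candidates & universe}
    for r, sig in zip(results, df["significant"]):
        if sig:
            for g in r.overlap_genes:
                counts[g] = counts.get(g, 0) + 1
    return df.drop(columns=["overlap_genes"]).assign(
        overlap_genes=[",".join(r.overlap_genes) for r in results]
    ), counts
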