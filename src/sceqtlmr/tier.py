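"""Drug-target Tier scoring for replicable candidate genes.

Five evidence components are scored and summed:

* MR sensitivity: number of exposure-outcome pairs (0-3) still significant
  when instruments are re-selected at the strict p < 5e-6 threshold;
  0 -> 0, 1 -> 0.1, 2 -> 0.3, 3 -> 0.5.
* Colocalization sensitivity: number of pairs (0-3) with PP.H4 > 0.8, same
  scale.
* Functional enrichment: number of significant pathways containing the gene;
  0 -> 0, 1-4 -> 0.1, 5-14 -> 0.3, >= 15 -> 0.5.
* Single-cell DEG evidence in blood or adipose: 0.3 if present.
* Druggability: available drug -> 1.0, druggable -> 0.5, none -> 0.

Tiers: total >= 1 -> Tier 1; 0.5 <= total < 1 -> Tier 2; total < 0.5 ->
Tier 3. All component scores are multiples of 0.1, so the arithmetic is done
in integer tenths internally; totals and the >=1 / >=0.5 tier boundaries are
exact by construction.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreCard",
    "NOVEL_GENE_EVIDENCE",
    "score_count_scale",
    "score_enrichment",
    "score_drug",
    "build_scorecard",
    "scorecards_frame",
    "scheme_sensitivity",
    "DEFAULT_SCHEMES",
]

DRUG_CLASSES = ("available_drug", "druggable", "none")
COMPONENTS = ("mr", "coloc", "enrich", "deg", "drug")

# Published 19-gene worked example: novel obesity candidate genes with their
# evidence counts/categories. Enrichment counts are representative members of
# the printed score band (the banded score, not the raw count, enters the
# total). Used by tests and by the acceptance script as a fixed input.
NOVEL_GENE_EVIDENCE: tuple[dict, ...] = tuple(
    dict(zip(("gene", "cell_types", "mr_sens_x", "coloc_sens_x",
              "enrich_x", "deg_evidence", "drug_class"), row))
    for row in [
        ("PYGB", "CD4 NC", 3, 3, 8, False, "available_drug"),
        ("ZCCHC7", "CD4 NC", 3, 3, 8, True, "none"),
        ("DDX42", "CD8 ET;CD8 NC", 3, 2, 8, False, "druggable"),
        ("PRUNE1", "CD8 ET", 0, 1, 8, False, "available_drug"),
        ("FTSJ3", "CD4 ET", 0, 2, 20, False, "druggable"),
        ("FNBP4", "B Mem;NK R", 3, 3, 0, True, "none"),
        ("SPN", "CD8 ET", 0, 3, 20, False, "none"),
        ("SF3B6", "Mono C", 0, 1, 8, False, "druggable"),
        ("SNRPD2", "Plasma", 0, 0, 8, False, "druggable"),
        ("MARCHF7", "CD4 SOX4", 0, 2, 20, False, "none"),
        ("SLC28A2", "CD4 ET", 0, 1, 2, False, "druggable"),
        ("VKORC1", "Mono NC;NK R", 0, 1, 2, False, "druggable"),
        ("UBE2Z", "Mono NC", 0, 1, 0, True, "none"),
        ("CMTR2", "NK R", 0, 0, 8, False, "none"),
        ("SCML4", "DC", 0, 2, 0, False, "none"),
        ("TIPARP-AS1", "Mono NC", 0, 2, 0, False, "none"),
        ("GABPB2", "CD4 ET", 0, 1, 0, False, "none"),
        ("ASTE1", "CD8 ET", 0, 1, 0, False, "none"),
        ("ZNF689", "CD8 NC", 0, 1, 0, False, "none"),
    ]
)


def score_count_scale(x: int) -> float:
    """Score a 0-3 count of significant exposure-outcome pairs."""
    if x < 0:
        raise ValueError("count must be nonnegative")
    if x > 3:
        raise ValueError("at most three exposure-outcome pairs exist")
    return {0: 0.0, 1: 0.1, 2: 0.3, 3: 0.5}[x]


def score_enrichment(x: int) -> float:
    """Score a pathway count: 0 -> 0; 1-4 -> 0.1; 5-14 -> 0.3; >= 15 -> 0.5."""
    if x < 0:
        raise ValueError("count must be nonnegative")
    if x == 0:
        return 0.0
    if x < 5:
        return 0.1
    if x < 15:
        return 0.3
    return 0.5


def score_drug(drug_class: str) -> float:
    """Score druggability: available_drug 1.0, druggable 0.5, none 0."""
    table = {"available_drug": 1.0, "druggable": 0.5, "none": 0.0}
    if drug_class not in table:
        raise ValueError(f"unknown drug class {drug_class!r}; "
                         f"expected one of {DRUG_CLASSES}")
    return table[drug_class]


def _tenths(x: float) -> int:
    t = round(x * 10)
    if abs(t - x * 10) > 1e-9:
        raise ValueError(f"score {x} is not a multiple of 0.1")
    return int(t)


@dataclass
class ScoreCard:
    gene: str
    cell_types: str
    mr_sens_x: int
    coloc_sens_x: int
    enrich_x: int
    deg_evidence: bool
    drug_class: str
    score_mr: float
    score_coloc: float
    score_enrich: float
    score_deg: float
    score_drug: float
    total: float
    tier: int

    @property
    def component_scores(self) -> dict[str, float]:
        return {"mr": self.score_mr, "coloc": self.score_coloc,
                "enrich": self.score_enrich, "deg": self.score_deg,
                "drug": self.score_drug}


def _tier_from_tenths(total_tenths: int) -> int:
    if total_tenths >= 10:
        return 1
    if total_tenths >= 5:
        return 2
    return 3


def build_scorecard(gene: str, mr_sens_x: int, coloc_sens_x: int,
                    enrich_x: int, deg_evidence: bool, drug_class: str,
                    cell_types: str = "") -> ScoreCard:
    """Score one gene's evidence bundle and assign its tier.

    The total is accumulated in integer tenths, so boundary totals of
    exactly 1.0 and 0.5 land in Tiers 1 and 2 as the >=/< rules require.
    """
    s_mr = score_count_scale(mr_sens_x)
    s_coloc = score_count_scale(coloc_sens_x)
    s_enrich = score_enrichment(enrich_x)
    s_deg = 0.3 if deg_evidence else 0.0
    s_drug = score_drug(drug_class)
    total_tenths = sum(_tenths(s) for s in (s_mr, s_coloc, s_enrich, s_deg, s_drug))
    return ScoreCard(gene=gene, cell_types=cell_types,
                     mr_sens_x=mr_sens_x, coloc_sens_x=coloc_sens_x,
                     enrich_x=enrich_x, deg_evidence=deg_evidence,
                     drug_class=drug_class,
                     score_mr=s_mr, score_coloc=s_coloc,
                     score_enrich=s_enrich, score_deg=s_deg,
                     score_drug=s_drug, total=total_tenths / 10.0,
                     tier=_tier_from_tenths(total_tenths))


def scorecards_frame(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(ScoreCard)]
    return pd.DataFrame([c.__dict__ for c in cards], columns=cols)


#: Alternative weighting schemes for the ranking-stability analysis. The
#: original scales give the domains different maximum contributions (1.0 for
#: druggability, 0.5 for MR/coloc/enrichment, 0.3 for DEG), so the
#: equal-weight model rescales every domain to a common maximum of 1, and
#: the down-weight model halves the annotation-dependent domains
#: (enrichment, DEG, druggability).
DEFAULT_SCHEMES: dict[str, dict[str, float]] = {
    "equal": {"mr": 2.0, "coloc": 2.0, "enrich": 2.0,
              "deg": 1.0 / 0.3, "drug": 1.0},
    "downweight_annotation": {"mr": 1.0, "coloc": 1.0,
                              "enrich": 0.5, "deg": 0.5, "drug": 0.5},
}


def _rank_desc(totals: np.ndarray) -> np.ndarray:
    """Ranks by descending total, average ranks for ties."""
    return stats.rankdata(-totals, method="average")


def scheme_sensitivity(cards: Sequence[ScoreCard],
                       schemes: Mapping[str, Mapping[str, float]] | None = None,
                       top_k: int = 5) -> pd.DataFrame:
    """Ranking stability of the Tier scores under alternative weights.

    Each scheme rescales the five component scores before summation. For
    every scheme the Spearman rank correlation (tie-corrected) between the
    original and reweighted rankings is reported, together with top-k
    persistence |top-k(original) & top-k(scheme)| / k. A scheme whose totals
    are all equal has no defined rho (reported as NaN).
    """
    if len(cards) < 2:
        raise ValueError("scheme sensitivity needs >= 2 genes")
    schemes = DEFAULT_SCHEMES if schemes is None else schemes
    genes = [c.gene for c in cards]
    comp = np.array([[c.component_scores[k] for k in COMPONENTS] for c in cards])
    base_totals = comp.sum(axis=1)
    base_rank = _rank_desc(base_totals)
    base_top = set(np.array(genes)[np.argsort(base_rank, kind="stable")][:top_k])
    rows = []
    for name, weights in schemes.items():
        w = np.array([weights[k] for k in COMPONENTS])
        totals = comp @ w
        if np.allclose(totals, totals[0]) or np.allclose(base_totals, base_totals[0]):
            rho = np.nan
        else:
            rho = float(stats.spearmanr(base_rank, _rank_desc(totals)).statistic)
        rank = _rank_desc(totals)
        top = set(np.array(genes)[np.argsort(rank, kind="stable")][:top_k])
        rows.append({"scheme": name, "spearman_rho": rho,
                     "top_k": top_k,
                     "top_k_persistence": len(base_top & top) / top_k})
    return pd.DataFrame(rows)
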