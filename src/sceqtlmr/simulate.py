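"""Synthetic summary statistics, LD matrices and single-cell counts with a
known causal structure.

Summary statistics are generated directly at the marginal-association level:
for a locus with LD correlation matrix R (AR(1) with parameter ``ld_rho``)
and a single causal SNP c with joint effect gamma, the marginal z-scores are
drawn from N(mu, R) with mu_j = (gamma / se_c) * R[j, c], and betas are
z * se with se_j = 1 / sqrt(2 * maf_j * (1 - maf_j) * n). Five locus
scenarios mirror the colocalization hypotheses:

* H0 - neither trait associated;
* H1 - exposure (eQTL) signal only;
* H2 - outcome (GWAS) signal only;
* H3 - both signals, anchored at well-separated causal SNPs;
* H4 - shared causal SNP, with outcome effect theta * gamma (expression ->
  trait causal effect theta), plus optional per-SNP pleiotropy noise.

The binary obesity outcome is simulated on the log-odds scale with standard
errors from the case/control effective sample size 4 / (1/cases + 1/controls).
Each gene owns ``loci_per_gene`` independent LD blocks, giving multi-
instrument genes after clumping; the per-gene LD matrix is block-diagonal.

Single-cell counts are negative binomial with designated lean/obese log-fold
shifts in a designated cell type, mitochondrial genes, and planted QC
violations (low-depth and mito-heavy cells) so the QC stage is exercised.

One master seed drives everything; per-gene streams are derived by
counter-based seed-sequence spawning, so results do not depend on iteration
order.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

import anndata as ad

from .records import CELL_TYPES, LdMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimDataset",
    "ar1_ld",
    "simulate_locus",
    "simulate_dataset",
    "simulate_sc_counts",
    "simulate_gmt",
]

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class TraitSpec:
    """One outcome GWAS: quantitative (n) or binary (cases/controls)."""

    name: str
    binary: bool = False
    n: float = 0.0
    n_cases: float = 0.0
    n_controls: float = 0.0
    #: causal effect of expression on this trait for H4 loci (log-odds per SD
    #: expression for binary traits, SD units otherwise); None falls back to
    #: SimConfig.theta_scale
    theta: float | None = None

    @property
    def n_total(self) -> float:
        return self.n_cases + self.n_controls if self.binary else self.n

    @property
    def n_effective(self) -> float:
        """Effective sample size for log-odds SEs of a binary trait."""
        if not self.binary:
            return self.n
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


def default_traits() -> tuple[TraitSpec, ...]:
    """The three obesity-related outcomes at their published sample sizes.

    Default causal effects for H4 loci are set so the shared variant reaches
    genome-wide significance in every outcome at its sample size (z near 7),
    mirroring loci with colocalizable signals across all three GWAS; the
    binary trait needs a larger log-odds effect because its case/control
    effective sample size is smaller.
    """
    return (
        TraitSpec("obesity", binary=True, n_cases=31_499, n_controls=468_693,
                  theta=0.04),
        TraitSpec("bmi", n=484_680, theta=0.02),
        TraitSpec("bodyfat", n=432_262, theta=0.02),
    )


@dataclass
class SimConfig:
    # locus architecture
    n_genes: int = 200
    n_cell_types: int = 14
    snps_per_locus: int = 40
    loci_per_gene: int = 2
    ld_rho: float = 0.9
    snp_spacing_bp: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    # effect sizes and sample sizes
    n_eqtl: int = 982
    traits: tuple[TraitSpec, ...] = field(default_factory=default_traits)
    eqtl_beta: float = 0.7          # |gamma| at the causal SNP, SD units
    theta_scale: float = 0.02       # |theta|: causal effect of expression
    pleiotropy_sd: float = 0.0
    scenario_mix: dict = field(default_factory=lambda: {
        "H0": 0.25, "H1": 0.15, "H2": 0.15, "H3": 0.15, "H4": 0.30})
    swap_coding_frac: float = 0.2   # outcome rows emitted with swapped alleles
    # single-cell counts
    sc_n_genes: int = 400
    n_mito_genes: int = 10
    nb_mean: float = 1.5
    nb_dispersion: float = 2.0
    deg_lfc: float = 1.0
    n_deg_genes: int = 5
    cells_per_donor: int = 200
    n_donors_per_group: int = 10
    sc_cell_types: tuple[str, ...] = ("Mono", "T", "B", "NK")
    qc_violation_frac: float = 0.04
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0,1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario_mix sums to {total}, not 1")
        if set(self.scenario_mix) - set(SCENARIOS):
            raise ValueError(f"unknown scenario in mix: {self.scenario_mix}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must be ordered within (0,1)")


@dataclass
class SimDataset:
    eqtl: pd.DataFrame
    outcomes: dict[str, pd.DataFrame]
    ld_store: dict[str, LdMatrix]
    truth: pd.DataFrame
    config: SimConfig


def ar1_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: R[i, j] = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _se_from_maf(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _marginal_stats(rng: np.random.Generator, chol: np.ndarray,
                    se: np.ndarray, mu_z: np.ndarray) -> pd.DataFrame:
    from scipy import stats
    z = mu_z + chol @ rng.standard_normal(len(se))
    beta = z * se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"beta": beta, "se": se,
                         "pval": np.clip(pval, 1e-300, 1.0)})


def _min_h3_separation(rho: float, r2_max: float = 0.05) -> int:
    if rho == 0:
        return 1
    return int(np.ceil(np.log(r2_max) / (2.0 * np.log(rho)))) + 1


def simulate_locus(
    config: SimConfig,
    scenario: str,
    rng: np.random.Generator,
    gene_id: str = "GENE0",
    gene_symbol: str | None = None,
    cell_type: str = "CD4 NC",
    chrom: str = "1",
    start_pos: int = 1_000_000,
    locus_key: str | None = None,
    theta: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], LdMatrix, dict]:
    """Simulate one LD block: eQTL records, per-trait GWAS records, LD, truth.

    ``theta`` maps trait name to the causal expression->trait effect used
    under H4 (default: +theta_scale for every trait).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"invalid scenario {scenario!r}; expected one of {SCENARIOS}")
    m = config.snps_per_locus
    locus_key = locus_key or f"{gene_id}_L0"
    gene_symbol = gene_symbol if gene_symbol is not None else gene_id
    snp_ids = [f"{locus_key}_snp{j:03d}" for j in range(m)]
    pos = start_pos + config.snp_spacing_bp * np.arange(m)
    maf = rng.uniform(*config.maf_range, size=m)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in allele_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in allele_idx])

    R = ar1_ld(m, config.ld_rho)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    ld = LdMatrix(snp_ids, R)

    exposure_causal = scenario in ("H1", "H3", "H4")
    gamma = 0.0
    c_exp = -1
    sep = _min_h3_separation(config.ld_rho)
    if exposure_causal:
        if scenario == "H3":
            # leave room for a well-separated (r^2 < 0.05) outcome SNP
            lo_c = m // 4
            if lo_c + sep > m - 1:
                raise ValueError(
                    f"locus of {m} SNPs too short for H3 separation {sep}")
            c_exp = int(rng.integers(lo_c, max(lo_c + 1, m - sep)))
        else:
            c_exp = int(rng.integers(m // 4, 3 * m // 4))
        gamma = float(rng.choice([-1.0, 1.0]) * config.eqtl_beta
                      * rng.uniform(0.8, 1.2))
    se_exp = _se_from_maf(maf, config.n_eqtl)
    mu_exp = (gamma / se_exp[c_exp]) * R[:, c_exp] if exposure_causal else np.zeros(m)
    exp_stats = _marginal_stats(rng, chol, se_exp, mu_exp)
    eqtl = pd.DataFrame({
        "snp_id": snp_ids, "chrom": str(chrom), "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": exp_stats["beta"], "se": exp_stats["se"],
        "pval": exp_stats["pval"], "n": float(config.n_eqtl),
        "gene_id": gene_id, "gene_symbol": gene_symbol,
        "cell_type": cell_type,
    })

    theta = dict(theta) if theta is not None else {
        t.name: (t.theta if t.theta is not None else config.theta_scale)
        for t in config.traits}
    outcomes: dict[str, pd.DataFrame] = {}
    causal_out: dict[str, str] = {}
    # H2/H3 outcome-only anchor, shared across traits within the locus
    c_alt = -1
    if scenario in ("H2", "H3"):
        if scenario == "H3":
            c_alt = int(rng.integers(c_exp + sep, m))
        else:
            c_alt = int(rng.integers(m // 4, 3 * m // 4))
    for trait in config.traits:
        se_out = _se_from_maf(maf, trait.n_effective)
        mu_out = np.zeros(m)
        if scenario == "H4":
            b_causal = theta[trait.name] * gamma
            mu_out = (b_causal / se_out[c_exp]) * R[:, c_exp]
            causal_out[trait.name] = snp_ids[c_exp]
        elif scenario in ("H2", "H3"):
            b_causal = float(rng.choice([-1.0, 1.0])) * abs(
                theta[trait.name] * config.eqtl_beta)
            mu_out = (b_causal / se_out[c_alt]) * R[:, c_alt]
            causal_out[trait.name] = snp_ids[c_alt]
        if config.pleiotropy_sd > 0 and exposure_causal:
            direct = rng.normal(0.0, config.pleiotropy_sd, size=m)
            mu_out = mu_out + R @ (direct / se_out)
        out_stats = _marginal_stats(rng, chol, se_out, mu_out)
        gw = pd.DataFrame({
            "snp_id": snp_ids, "chrom": str(chrom), "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": out_stats["beta"], "se": out_stats["se"],
            "pval": out_stats["pval"], "n": float(trait.n_total),
        })
        # emit a fraction of rows in swapped allele coding (harmonization work)
        swap = rng.random(m) < config.swap_coding_frac
        gw.loc[swap, ["effect_allele", "other_allele"]] = (
            gw.loc[swap, ["other_allele", "effect_allele"]].to_numpy())
        gw.loc[swap, "beta"] = -gw.loc[swap, "beta"]
        gw.loc[swap, "eaf"] = 1.0 - gw.loc[swap, "eaf"]
        outcomes[trait.name] = gw

    truth = {
        "gene_id": gene_id, "cell_type": cell_type, "locus": locus_key,
        "scenario": scenario, "gamma": gamma,
        "causal_snp_exposure": snp_ids[c_exp] if exposure_causal else "",
    }
    for t in config.traits:
        truth[f"theta_{t.name}"] = theta[t.name] if scenario == "H4" else 0.0
        truth[f"causal_snp_{t.name}"] = causal_out.get(t.name, "")
        truth[f"causal_{t.name}"] = scenario == "H4"
    return eqtl, outcomes, ld, truth


def _block_diag_ld(blocks: list[LdMatrix]) -> LdMatrix:
    ids = [s for b in blocks for s in b.snp_ids]
    n = len(ids)
    r = np.eye(n)
    off = 0
    for b in blocks:
        k = len(b)
        r[off:off + k, off:off + k] = b.r
        off += k
    return LdMatrix(ids, r)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate the full exposure table, one table per outcome, the per-gene
    LD store (block-diagonal over loci), and the truth table.

    Deterministic given ``config.rng_seed``: each gene draws from its own
    spawned seed-sequence stream.
    """
    master = np.random.SeedSequence(config.rng_seed)
    children = master.spawn(config.n_genes)
    names = list(config.scenario_mix)
    probs = np.array([config.scenario_mix[k] for k in names])
    scen_rng = np.random.default_rng(master.spawn(1)[0])
    scenarios = scen_rng.choice(names, size=config.n_genes, p=probs)

    cell_labels = CELL_TYPES[: config.n_cell_types]
    eqtl_parts, truth_rows = [], []
    outcome_parts: dict[str, list[pd.DataFrame]] = {t.name: [] for t in config.traits}
    ld_store: dict[str, LdMatrix] = {}
    for i in range(config.n_genes):
        rng = np.random.default_rng(children[i])
        gene_id = f"GENE{i:04d}"
        cell_type = cell_labels[i % len(cell_labels)]
        chrom = str((i % 22) + 1)
        base = 1_000_000 + (i // 22) * 5_000_000
        sign = float(rng.choice([-1.0, 1.0]))
        theta = {t.name: sign * (t.theta if t.theta is not None
                                 else config.theta_scale)
                 for t in config.traits}
        blocks = []
        for b in range(config.loci_per_gene):
            eqtl, outs, ld, truth = simulate_locus(
                config, scenarios[i], rng, gene_id=gene_id,
                cell_type=cell_type, chrom=chrom,
                start_pos=base + b * 500_000,
                locus_key=f"{gene_id}_L{b}", theta=theta)
            eqtl_parts.append(eqtl)
            for name, gw in outs.items():
                outcome_parts[name].append(gw)
            blocks.append(ld)
            truth_rows.append(truth)
        ld_store[gene_id] = _block_diag_ld(blocks)
    return SimDataset(
        eqtl=pd.concat(eqtl_parts, ignore_index=True),
        outcomes={k: pd.concat(v, ignore_index=True)
                  for k, v in outcome_parts.items()},
        ld_store=ld_store,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def simulate_sc_counts(config: SimConfig,
                       deg_genes: Mapping[str, tuple[str, float]] | None = None,
                       gene_names: list[str] | None = None,
                       seed: int | None = None) -> ad.AnnData:
    """Negative-binomial single-cell counts with lean/obese group structure.

    ``deg_genes`` maps gene -> (cell type, natural-log fold change applied
    to the obese group); by default the first ``n_deg_genes`` non-mito genes
    are shifted by ``deg_lfc`` in the first cell-type label. Mitochondrial
    genes are named ``MT-*`` and flagged; a small fraction of cells is
    planted as QC violations (low library depth, or mito-dominated).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed if seed is None else seed))
    n_main = config.sc_n_genes
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(n_main)]
    elif len(gene_names) < n_main:
        gene_names = list(gene_names) + [
            f"G{i:04d}" for i in range(len(gene_names), n_main)]
    mito_names = [f"MT-{i}" for i in range(config.n_mito_genes)]
    var_names = list(gene_names[:n_main]) + mito_names
    mito_flag = np.array([False] * n_main + [True] * config.n_mito_genes)

    if deg_genes is None:
        deg_genes = {g: (config.sc_cell_types[0], config.deg_lfc)
                     for g in var_names[: config.n_deg_genes]}

    n_genes = len(var_names)
    base_mu = config.nb_mean * rng.lognormal(0.0, 0.8, size=n_genes)
    base_mu[n_main:] = config.nb_mean * 2.0   # mito genes moderately expressed

    rows, obs_rows = [], []
    theta_disp = config.nb_dispersion
    for group_idx, group in enumerate(("lean", "obese")):
        for d in range(config.n_donors_per_group):
            donor = f"{group}_donor{d:02d}"
            donor_factor = rng.lognormal(0.0, 0.1)
            cts = rng.choice(config.sc_cell_types, size=config.cells_per_donor)
            for ct in cts:
                mu = base_mu * donor_factor
                if group == "obese":
                    for g, (deg_ct, lfc) in deg_genes.items():
                        if deg_ct == ct and g in var_names:
                            mu = mu.copy()
                            mu[var_names.index(g)] *= np.exp(lfc)
                tag = ""
                u = rng.random()
                if u < config.qc_violation_frac / 2:
                    mu = mu * 0.02          # low-depth cell, fails gene_min
                    tag = "low_depth"
                elif u < config.qc_violation_frac:
                    mu = mu.copy()
                    mu[n_main:] *= 60.0     # mito-dominated cell
                    tag = "high_mito"
                p = theta_disp / (theta_disp + mu)
                counts = rng.negative_binomial(theta_disp, p)
                rows.append(counts)
                obs_rows.append({"donor": donor, "group": group,
                                 "cell_type": str(ct), "qc_tag": tag})
    X = np.asarray(rows, dtype=np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:05d}" for i in range(len(obs))]
    var = pd.DataFrame({"gene_symbol": var_names, "mito": mito_flag},
                       index=var_names)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["deg_truth"] = {g: [ct, float(lfc)]
                              for g, (ct, lfc) in deg_genes.items()}
    return adata


def simulate_gmt(genes: list[str], n_terms: int = 40,
                 term_size_range: tuple[int, int] = (10, 40),
                 enriched_genes: list[str] | None = None,
                 n_enriched_terms: int = 8,
                 seed: int = 0) -> dict[str, tuple[str, set[str]]]:
    """Synthetic GMT collection over ``genes``.

    The first ``n_enriched_terms`` terms are seeded with ``enriched_genes``
    so that over-representation is detectable downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(genes)
    enriched = list(enriched_genes or [])
    collection: dict[str, tuple[str, set[str]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(*term_size_range))
        members = set(rng.choice(genes, size=min(size, len(genes)),
                                 replace=False))
        if t < n_enriched_terms and enriched:
            take = rng.choice(enriched,
                              size=max(1, int(0.7 * len(enriched))),
                              replace=False)
            members |= set(take)
        collection[f"TERM{t:03d}"] = (f"synthetic pathway {t}", members)
    return collection


def truth_table_frame(ds: SimDataset) -> pd.DataFrame:
    return ds.truth.copy()
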