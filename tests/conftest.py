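import numpy as np
import pandas as pd
import pytest

from sceqtlmr.config import PipelineConfig
from sceqtlmr.records import LdMatrix
from sceqtlmr.simulate import SimConfig, TraitSpec


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config() -> SimConfig:
    """A light simulation setup for unit tests."""
    return SimConfig(n_genes=12, snps_per_locus=30, loci_per_gene=2,
                     rng_seed=7)


def make_sumstats(snp_ids, betas, ses, chrom="1", pos_start=100_000,
                  spacing=1_000, eaf=0.3, n=10_000, **extra) -> pd.DataFrame:
    """Canonical summary-statistic frame from raw arrays (test helper)."""
    from scipy import stats

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore"):
        z = betas / np.where(ses > 0, ses, np.inf)
    df = pd.DataFrame({
        "snp_id": list(snp_ids),
        "chrom": str(chrom),
        "pos": pos_start + spacing * np.arange(len(betas)),
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "beta": betas,
        "se": ses,
        "pval": 2 * stats.norm.sf(np.abs(z)),
        "n": float(n),
    })
    for k, v in extra.items():
        df[k] = v
    return df


def make_eqtl(snp_ids, betas, ses, gene_id="GENE0", cell_type="CD4 NC",
              **kw) -> pd.DataFrame:
    return make_sumstats(snp_ids, betas, ses, gene_id=gene_id,
                         gene_symbol=gene_id, cell_type=cell_type, **kw)


def ld_from_r(snp_ids, r: np.ndarray) -> LdMatrix:
    return LdMatrix(list(snp_ids), np.asarray(r, dtype=float))
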