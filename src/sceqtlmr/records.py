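"""Domain record types for summary-statistic based MR.

All positions are 1-based and windows are closed intervals, following GWAS
summary-statistic convention. Alleles are stored uppercase; indel alleles are
kept as arbitrary (non-empty) strings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator

import numpy as np

__all__ = [
    "GwasRecord",
    "EqtlRecord",
    "LdMatrix",
    "RecordInvariantError",
    "CELL_TYPES",
]

#: The 14 immune cell-type labels of the OneK1K PBMC sc-eQTL resource.
CELL_TYPES = (
    "B IN", "B Mem", "CD4 ET", "CD4 NC", "CD4 SOX4", "CD8 ET", "CD8 NC",
    "CD8 S100B", "DC", "NK", "NK R", "Mono C", "Mono NC", "Plasma",
)


class RecordInvariantError(ValueError):
    """Raised when a record violates its declared invariants."""


@dataclass(slots=True)
class GwasRecord:
    """One SNP-trait association row from GWAS summary statistics.

    ``beta`` is per copy of ``effect_allele`` (log-odds for binary traits,
    SD units for quantitative traits).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()

    def validate(self) -> None:
        """Raise :class:`RecordInvariantError` on any invariant violation."""
        if not (self.se > 0):
            raise RecordInvariantError(f"{self.snp_id}: se must be > 0")
        if not (0.0 < self.eaf < 1.0):
            raise RecordInvariantError(f"{self.snp_id}: eaf must be in (0,1)")
        if not (0.0 < self.pval <= 1.0):
            raise RecordInvariantError(f"{self.snp_id}: pval must be in (0,1]")
        if self.effect_allele == self.other_allele:
            raise RecordInvariantError(f"{self.snp_id}: alleles must differ")
        if not self.effect_allele or not self.other_allele:
            raise RecordInvariantError(f"{self.snp_id}: empty allele")
        if not (self.n > 1):
            raise RecordInvariantError(f"{self.snp_id}: n must be > 1")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G SNPs whose strand cannot be resolved from alleles."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(slots=True)
class EqtlRecord(GwasRecord):
    """A cell-type-specific eQTL association (SNP -> gene expression)."""

    gene_id: str = ""
    gene_symbol: str = ""
    cell_type: str = ""

    def validate(self) -> None:
        GwasRecord.validate(self)
        if not self.cell_type:
            raise RecordInvariantError(f"{self.snp_id}: cell_type is empty")
        if not self.gene_id:
            raise RecordInvariantError(f"{self.snp_id}: gene_id is empty")


def record_fields(cls: type) -> list[str]:
    return [f.name for f in fields(cls)]


@dataclass
class LdMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered SNP panel."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self.validate()

    def validate(self) -> None:
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise RecordInvariantError(
                f"LD matrix shape {self.r.shape} does not match {n} SNP ids"
            )
        if len(self._index) != n:
            raise RecordInvariantError("duplicate SNP ids in LD matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise RecordInvariantError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise RecordInvariantError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise RecordInvariantError("LD entries must satisfy |r| <= 1")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} absent from LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs."""
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def submatrix(self, snp_ids: list[str]) -> "LdMatrix":
        idx = [self.index(s) for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        for i, a in enumerate(self.snp_ids):
            for j in range(i + 1, len(self.snp_ids)):
                yield a, self.snp_ids[j], float(self.r[i, j])
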