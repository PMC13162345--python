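"""Pipeline configuration: every numeric threshold used by the analysis.

Defaults are the thresholds of the published obesity sc-eQTL MR design:
relaxed instrument p < 0.005 with a strict 5e-6 sensitivity rerun, clumping
at r^2 < 0.01, F > 10, stratified BH FDR at 0.05, Cochran's Q gate at 0.05,
LD-check r^2 >= 0.7, +/-100 kb colocalization windows with priors
p1 = p2 = 1e-4, p12 = 1e-5 and the composite decision rule, and the
single-cell QC bounds (200-8000 detected genes, mito fraction <= 25%).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # instrument selection
    iv_pval: float = 0.005
    iv_pval_strict: float = 5e-6
    clump_r2: float = 0.01
    f_min: float = 10.0
    # MR
    fdr_alpha: float = 0.05
    q_alpha: float = 0.05
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)
    ivw_random_effects: bool = True
    # colocalization
    ldcheck_r2: float = 0.7
    ldcheck_gwas_p: float = 5e-8
    coloc_window_bp: int = 100_000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_rule_sum: float = 0.8
    coloc_rule_ratio: float = 0.9
    coloc_strict_pp4: float = 0.8
    coloc_sd_quant: float = 0.15
    coloc_sd_binary: float = 0.2
    # enrichment
    enrich_p: float = 0.05
    # single-cell DEG
    deg_adj_p: float = 0.05
    deg_min_pct: float = 0.1
    qc_gene_min: int = 200
    qc_gene_max: int = 8000
    qc_mito_max: float = 0.25
    norm_scale: float = 1e4
    # misc
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.palindromic_eaf_window = tuple(self.palindromic_eaf_window)
        self.validate()

    def validate(self) -> None:
        for name in ("iv_pval", "iv_pval_strict", "fdr_alpha", "q_alpha",
                     "enrich_p", "deg_adj_p", "ldcheck_gwas_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must be in (0,1)")
        for name in ("clump_r2", "ldcheck_r2", "coloc_rule_sum",
                     "coloc_rule_ratio", "coloc_strict_pp4", "qc_mito_max",
                     "deg_min_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be in [0,1]")
        for name in ("coloc_p1", "coloc_p2", "coloc_p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must be in (0,1)")
        if self.coloc_window_bp <= 0:
            raise ValueError("coloc_window_bp must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be nonnegative")
        if not (0 < self.qc_gene_min <= self.qc_gene_max):
            raise ValueError("qc gene bounds must satisfy 0 < min <= max")
        lo, hi = self.palindromic_eaf_window
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("palindromic_eaf_window must be ordered in [0,1]")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palindromic_eaf_window"] = list(self.palindromic_eaf_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
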