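"""Readers and writers for the pipeline's tab-delimited interchange formats.

Summary statistics travel as TSV with the canonical header
``snp_id chrom pos effect_allele other_allele eaf beta se pval n`` plus
``gene_id gene_symbol cell_type`` for eQTL tables. Arbitrary source headers
(e.g. FinnGen- or GIANT-style) are mapped onto the canonical fields through a
``dialect`` dictionary. Rows violating record invariants are dropped and the
drop count is logged, never silently repaired.

LD matrices are square TSVs (header and first column both list SNP ids);
gene sets use the standard GMT tab format.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import EqtlRecord, GwasRecord, LdMatrix, RecordInvariantError

log = logging.getLogger("sceqtlmr")

__all__ = [
    "GWAS_COLUMNS",
    "EQTL_COLUMNS",
    "read_sumstats",
    "frame_to_records",
    "records_to_frame",
    "write_results_table",
    "read_results_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_ld_store",
    "write_ld_store",
    "read_gmt",
    "write_gmt",
]

GWAS_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                "eaf", "beta", "se", "pval", "n")
EQTL_COLUMNS = GWAS_COLUMNS + ("gene_id", "gene_symbol", "cell_type")

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float,
            "pval": float, "n": float}

#: Example dialects for common source headers.
DIALECTS: dict[str, dict[str, str]] = {
    "finngen": {"rsids": "snp_id", "#chrom": "chrom", "pos": "pos",
                "alt": "effect_allele", "ref": "other_allele",
                "af_alt": "eaf", "beta": "beta", "sebeta": "se",
                "pval": "pval", "n": "n"},
    "giant": {"SNP": "snp_id", "CHR": "chrom", "POS": "pos",
              "Tested_Allele": "effect_allele", "Other_Allele": "other_allele",
              "Freq_Tested_Allele": "eaf", "BETA": "beta", "SE": "se",
              "P": "pval", "N": "n"},
}


def _validate_frame(df: pd.DataFrame, eqtl: bool) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (clean frame, n dropped)."""
    df = df.copy()
    for col, typ in _NUMERIC.items():
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    ok = (
        df[list(_NUMERIC)].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["eaf"] > 0) & (df["eaf"] < 1)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] > 1)
        & (df["effect_allele"] != df["other_allele"])
        & (df["effect_allele"].str.len() > 0)
        & (df["other_allele"].str.len() > 0)
    )
    if eqtl:
        ok &= df["cell_type"].astype(str).str.len() > 0
        ok &= df["gene_id"].astype(str).str.len() > 0
    dropped = int((~ok).sum())
    out = df.loc[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    return out, dropped


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | str | None = None,
    kind: str = "auto",
) -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical column layout.

    Parameters
    ----------
    path
        Tab-delimited text file with a header row.
    dialect
        Mapping from source column names to canonical field names, or the
        name of a built-in dialect (``"finngen"``, ``"giant"``). ``None``
        assumes canonical names.
    kind
        ``"gwas"``, ``"eqtl"`` or ``"auto"`` (eQTL iff gene/cell columns are
        present after mapping).

    Returns
    -------
    DataFrame in canonical layout. The number of invariant-violating rows
    that were dropped is logged and stored in ``df.attrs["n_dropped"]``.
    """
    path = Path(path)
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty summary-statistics file")
    if dialect:
        df = df.rename(columns=dict(dialect))
    if kind == "auto":
        kind = "eqtl" if {"gene_id", "cell_type"} <= set(df.columns) else "gwas"
    want = EQTL_COLUMNS if kind == "eqtl" else GWAS_COLUMNS
    missing = [c for c in want if c not in df.columns and c != "gene_symbol"]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if kind == "eqtl" and "gene_symbol" not in df.columns:
        df["gene_symbol"] = df["gene_id"]
    df = df[list(want)]
    df, dropped = _validate_frame(df, eqtl=(kind == "eqtl"))
    if dropped:
        log.info("read_sumstats(%s): dropped %d invalid row(s)", path.name, dropped)
    df.attrs["n_dropped"] = dropped
    return df


def frame_to_records(df: pd.DataFrame) -> list[GwasRecord]:
    """Materialize canonical rows as record dataclasses (validated)."""
    eqtl = "cell_type" in df.columns
    cls = EqtlRecord if eqtl else GwasRecord
    cols = EQTL_COLUMNS if eqtl else GWAS_COLUMNS
    out = []
    for row in df[list(cols)].itertuples(index=False):
        rec = cls(*row)
        rec.validate()
        out.append(rec)
    return out


def records_to_frame(records: Sequence[GwasRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=GWAS_COLUMNS)
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows)


def write_results_table(obj, path: str | Path, float_digits: int = 12) -> None:
    """Write any homogeneous record list or DataFrame as TSV.

    Floats are serialized with enough significant digits that a read/write
    round-trip is lossless to < 1e-9 relative error.
    """
    if isinstance(obj, pd.DataFrame):
        df = obj
    else:
        records = list(obj)
        if records and dataclasses.is_dataclass(records[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- LD matrices -------------------------------------------------------------

def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="snp_id")


def read_ld_matrix(path: str | Path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_store(store: Mapping[str, LdMatrix], directory: str | Path) -> None:
    """One TSV per locus key under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, ld in store.items():
        write_ld_matrix(ld, directory / f"{key}.ld.tsv")


def read_ld_store(directory: str | Path) -> dict[str, LdMatrix]:
    directory = Path(directory)
    return {
        p.name[: -len(".ld.tsv")]: read_ld_matrix(p)
        for p in sorted(directory.glob("*.ld.tsv"))
    }


# -- single-cell counts (MTX + TSV metadata) ---------------------------------

def write_sc_data(adata, directory: str | Path) -> None:
    """Write counts as MatrixMarket (genes x cells) plus cell/gene TSVs."""
    import scipy.io
    import scipy.sparse as sp

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if hasattr(X, "todense"):
        X = np.asarray(X.todense())
    scipy.io.mmwrite(str(directory / "counts.mtx"),
                     sp.csr_matrix(np.asarray(X).T))  # genes x cells
    adata.obs.to_csv(directory / "cells.tsv", sep="\t", index_label="cell_id")
    adata.var.to_csv(directory / "genes.tsv", sep="\t", index_label="gene")


def read_sc_data(directory: str | Path):
    """Read counts written by :func:`write_sc_data` into an AnnData."""
    import anndata as ad
    import scipy.io

    directory = Path(directory)
    X = scipy.io.mmread(str(directory / "counts.mtx")).toarray().T
    obs = pd.read_csv(directory / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(directory / "genes.tsv", sep="\t", index_col=0)
    if "qc_tag" in obs.columns:
        obs["qc_tag"] = obs["qc_tag"].fillna("")
    var.index = var.index.astype(str)
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=np.asarray(X, dtype=np.int64), obs=obs, var=var)


# -- gene sets (GMT) ---------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Parse GMT: term_id <tab> description <tab> gene1 <tab> gene2 ...

    Returns ``{term_id: (description, genes)}``.
    """
    out: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, genes = parts[0], parts[1], parts[2:]
        out[term] = (desc, {g for g in genes if g})
    if not out:
        raise ValueError(f"{path}: empty GMT file")
    return out


def write_gmt(collection: Mapping[str, tuple[str, set[str]]],
              path: str | Path) -> None:
    lines = [
        "\t".join([term, desc] + sorted(genes))
        for term, (desc, genes) in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
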