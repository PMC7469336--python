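"""Readers and writers for the tab-separated interchange files.

Dialect: UTF-8, tab-separated, '.' decimal, mandatory header row. Gene and
sample identifiers are case-preserved and matched case-sensitively.
Missing expression values are rejected at ingest rather than imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import validate_annotations, validate_expression

log = logging.getLogger(__name__)

#: significant digits preserved by the writers (round-trip guarantee)
FLOAT_FORMAT = "%.12g"


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns:
        raise ValueError("annotation file must have a 'sample_id' column")
    ann = ann.set_index("sample_id")
    return validate_annotations(ann)


def read_expression(path: str | Path,
                    annotation_path: str | Path | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a genes/probes x samples TSV, cross-validated against annotations.

    Returns ``(matrix, annotations)``; annotations are ``None`` when no
    annotation path is given. Every expression column must map to exactly one
    annotated sample.
    """
    with open(path) as fh:  # pandas mangles duplicate header names silently
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids in expression matrix: {dups[:5]}")
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cells in {path}: {exc}") from exc
    validate_expression(values)
    ann = None
    if annotation_path is not None:
        ann = read_annotations(annotation_path)
        unannotated = [s for s in values.columns if s not in ann.index]
        if unannotated:
            raise ValueError(
                f"samples without annotations: {unannotated[:5]}"
                f" ({len(unannotated)} total)")
    return values, ann


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    validate_expression(values)
    values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="id")


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(ann)
    ann.to_csv(path, sep="\t", index_label="sample_id")


def read_seed_list(path: str | Path) -> list[str]:
    """Read a seed gene list: one symbol per line, blanks ignored."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValueError(f"empty seed list: {path}")
    if len(set(genes)) != len(genes):
        raise ValueError("seed list contains duplicate symbols")
    return genes


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read gene-level GWAS records (columns gene, p_best, n_snps).

    A SNP-level file (columns gene, p — one row per SNP) is reduced to
    per-gene best-SNP records on the fly.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("GWAS file must have a 'gene' column")
    if {"p_best", "n_snps"} <= set(df.columns):
        out = df[["gene", "p_best", "n_snps"]].copy()
        if out["gene"].duplicated().any():
            raise ValueError("duplicate gene rows in gene-level GWAS file")
    elif "p" in df.columns:
        from .gwas import best_snp_reduce
        out = best_snp_reduce(df)
    else:
        raise ValueError("GWAS file needs either (p_best, n_snps) or SNP-level 'p'")
    p = out["p_best"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p_best values must lie in (0, 1]")
    n = out["n_snps"].to_numpy()
    if np.any(n < 1) or np.any(n != n.astype(int)):
        raise ValueError("n_snps must be positive integers")
    out["n_snps"] = out["n_snps"].astype(int)
    return out.reset_index(drop=True)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a gene -> knockout-phenotype table.

    Expected columns: ``gene`` and ``phenotypes`` (comma-separated codes,
    possibly empty). An optional ``ortholog_id`` column is carried through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna({"phenotypes": ""})
    if "gene" not in df.columns or "phenotypes" not in df.columns:
        raise ValueError("phenotype file needs 'gene' and 'phenotypes' columns")
    df["phenotypes"] = [
        tuple(sorted({c.strip() for c in cell.split(",") if c.strip()}))
        for cell in df["phenotypes"]
    ]
    return df.reset_index(drop=True)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked-candidate table (phenotypes joined with commas)."""
    out = results.copy()
    if "phenotypes" in out.columns:
        out["phenotypes"] = [",".join(p) for p in out["phenotypes"]]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
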