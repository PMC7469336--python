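"""Packaged reference tables: the 52-gene seed list and published rankings.

These small fixtures ship with the package so that the rank arithmetic and
the published summary statistics can be recomputed without any download:

* :func:`load_seed_genes` — the 52 established ("reproducible") AD genes.
* :func:`load_structure_cr` — per-seed CRs in the brain stem, cerebellum
  and cerebrum networks.
* :func:`load_braak_cr` — per-seed CRs in the early- vs late-affected
  cerebral region networks.
* :func:`load_ranked_candidates` — the published top-ranked novel
  candidates with phenotype codes, GWAS/network/combined Z, p and FDR q.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

_DATA = files("seednet") / "data"


def load_seed_genes() -> list[str]:
    genes = [ln for ln in (_DATA / "rad_genes.txt").read_text().splitlines()
             if ln.strip()]
    if len(genes) != 52 or len(set(genes)) != 52:
        raise RuntimeError("packaged seed list is corrupted")
    return genes


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_structure_cr() -> pd.DataFrame:
    """Seed CRs per high-level structure (columns brain_stem, cerebellum,
    cerebrum), indexed by gene."""
    df = _read("structure_cr.tsv").set_index("gene")
    if df.shape != (52, 3):
        raise RuntimeError("packaged structure CR table is corrupted")
    return df


def load_braak_cr() -> pd.DataFrame:
    """Seed CRs in the early- and late-affected cerebral networks."""
    df = _read("braak_cr.tsv").set_index("gene")
    if df.shape != (52, 2):
        raise RuntimeError("packaged early/late CR table is corrupted")
    return df


def load_ranked_candidates() -> pd.DataFrame:
    """Published ranked novel-candidate table (36 phenotype-filtered genes)."""
    df = _read("ranked_candidates.tsv")
    df["phenotypes"] = [tuple(sorted(c.split(","))) for c in df["phenotype"]]
    if len(df) != 36:
        raise RuntimeError("packaged candidate table is corrupted")
    return df.drop(columns=["phenotype"])
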