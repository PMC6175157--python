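"""Readers and writers for the plain-text formats shared by all stages.

Pedigree CSV (animal,sire,dam; 0 = unknown), PLINK-RAW-like genotype TSV
(header of SNP IDs, one row per animal, codes 0/1/2 and NA) with a
companion map TSV (snp, chrom, pos; 1-based), phenotype TSV, BED gene
intervals (0-based half-open on disk, 1-based inclusive in memory) and
GMT gene-set collections.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotypes import GenotypePanel


class IOError_(ValueError):
    pass


# -- genotypes ---------------------------------------------------------------

def write_genotypes(panel: GenotypePanel, geno_path, map_path) -> None:
    df = pd.DataFrame(panel.codes, columns=panel.snp_ids)
    df.insert(0, "animal", panel.animal_ids)
    with np.errstate(invalid="ignore"):
        df.to_csv(geno_path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    panel.map_frame().to_csv(map_path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> GenotypePanel:
    df = pd.read_csv(geno_path, sep="\t", dtype={"animal": str})
    if "animal" not in df.columns:
        raise IOError_("genotype file must have an 'animal' column")
    snp_ids = [c for c in df.columns if c != "animal"]
    codes = df[snp_ids].to_numpy(float)
    m = pd.read_csv(map_path, sep="\t", dtype={"snp": str, "chrom": str})
    if list(m["snp"]) != snp_ids:
        m = m.set_index("snp").loc[snp_ids].reset_index()
    return GenotypePanel(
        df["animal"].tolist(), snp_ids, codes,
        m["chrom"].to_numpy(object), m["pos"].to_numpy(np.int64),
    )


# -- phenotypes --------------------------------------------------------------

def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype TSV.

    Requires columns animal, record_id, value, reliability; extra columns
    are kept as covariates. Reliabilities must lie in (0, 1] and values
    be finite; offending rows are reported with line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    required = ["animal", "record_id", "value", "reliability"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"phenotype file missing columns: {missing}")
    rel = df["reliability"].to_numpy(float)
    val = df["value"].to_numpy(float)
    bad = np.flatnonzero((rel <= 0) | (rel > 1) | ~np.isfinite(rel) | ~np.isfinite(val))
    if bad.size:
        lines = [int(i) + 2 for i in bad[:20]]  # +2: header + 1-based
        raise IOError_(
            f"{bad.size} phenotype rows invalid (reliability outside (0,1] or "
            f"non-finite value); first offending lines: {lines}"
        )
    return df


# -- annotation --------------------------------------------------------------

def write_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals as standard 0-based
    half-open BED (chrom, start, end, name)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(np.int64) - 1,
            "end": genes["end"].astype(np.int64),
            "name": genes["gene"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED into the in-memory 1-based inclusive convention."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={0: str, 3: str},
    )
    if (df["start"] >= df["end"]).any():
        raise IOError_("BED intervals must satisfy start < end")
    if df["gene"].duplicated().any():
        raise IOError_("duplicate gene IDs in BED")
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df[["gene", "chrom", "start", "end"]]


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, members) in sets.items():
            fh.write("\t".join([term_id, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IOError_(f"GMT line {ln}: need term, description and >=1 gene")
            sets[parts[0]] = (parts[1], parts[2:])
    return sets


# -- matrices & provenance ---------------------------------------------------

def write_matrix_coo(mat, ids, path) -> None:
    """Coordinate-format text dump (i, j, value) of a relationship matrix."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\n")


def provenance_header(config: dict, seed) -> str:
    import sirescan

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return (
        f"# sirescan {sirescan.__version__}\n"
        f"# config_hash: {digest}\n"
        f"# seed: {seed}\n"
    )


def write_result_tsv(df: pd.DataFrame, path, config: dict | None = None, seed=None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_result_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
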