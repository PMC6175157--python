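"""SNP-to-gene assignment and hypergeometric gene-set enrichment.

A SNP is assigned to a gene when it lies within the gene body or at most
``flank_bp`` up- or downstream (boundaries inclusive). Significant genes
are those hit by at least one SNP in the top fraction of absolute
back-solved effects; each gene set is then tested with the exact
upper-tail hypergeometric probability P(X >= g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class GenesetError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # genes in term among the analyzed universe
    g: int  # significant genes in term
    S: int  # total significant genes
    N: int  # total analyzed genes
    p: float
    genes: tuple[str, ...]  # significant gene IDs in the term


def assign_snps_to_genes(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 15_000,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map each SNP to the genes whose flanked span contains it.

    ``snp_map`` needs columns snp/chrom/pos (1-based); ``genes`` needs
    gene/chrom/start/end with 1-based inclusive coordinates. Returns the
    SNP -> gene-ID mapping plus the list of unassigned SNPs.
    """
    mapping: dict[str, list[str]] = {}
    unassigned: list[str] = []
    gene_chroms = set(genes["chrom"].astype(str))
    snp_chroms = set(snp_map["chrom"].astype(str))
    orphan = snp_chroms - gene_chroms
    if orphan:
        n = int(snp_map["chrom"].astype(str).isin(orphan).sum())
        warnings.warn(
            f"{n} SNPs lie on chromosomes with no annotated genes: {sorted(orphan)}"
        )
    by_chrom = {str(c): grp for c, grp in genes.groupby(genes["chrom"].astype(str))}
    for c, snps in snp_map.groupby(snp_map["chrom"].astype(str)):
        grp = by_chrom.get(str(c))
        if grp is None:
            unassigned.extend(snps["snp"].astype(str))
            continue
        starts = grp["start"].to_numpy(np.int64) - flank_bp
        ends = grp["end"].to_numpy(np.int64) + flank_bp
        gids = grp["gene"].astype(str).to_numpy()
        for snp, pos in zip(snps["snp"].astype(str), snps["pos"].to_numpy(np.int64)):
            hits = gids[(starts <= pos) & (pos <= ends)]
            if hits.size:
                mapping[snp] = list(hits)
            else:
                unassigned.append(snp)
    return mapping, unassigned


def flag_significant_genes(
    effects: pd.DataFrame,
    mapping: dict[str, list[str]],
    top_fraction: float = 0.01,
) -> tuple[set[str], int, int, list[str]]:
    """Top-fraction SNP rule: the ceil(top_fraction * n_snps) SNPs with the
    largest |effect| are significant (ties broken by |effect| descending
    then SNP ID ascending); genes hit by >=1 significant SNP are the
    significant set.

    Returns (significant_genes, N, S, significant_snps) where N counts
    genes hit by any analyzed SNP and S the significant genes.
    """
    if not 0 < top_fraction <= 1:
        raise GenesetError("top_fraction must be in (0, 1]")
    df = effects[["snp", "effect"]].copy()
    df["snp"] = df["snp"].astype(str)
    df["abs_effect"] = df["effect"].abs()
    df = df.sort_values(["abs_effect", "snp"], ascending=[False, True], kind="stable")
    n_top = int(np.ceil(top_fraction * len(df)))
    top_snps = df["snp"].head(n_top).tolist()

    universe = {g for snp in df["snp"] for g in mapping.get(snp, ())}
    sig_genes = {g for snp in top_snps for g in mapping.get(snp, ())}
    return sig_genes, len(universe), len(sig_genes), top_snps


def hypergeometric_test(g: int, S: int, N: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= g) of seeing g
    significant genes in a k-gene set, with S significant among N."""
    if not (0 <= g <= min(S, k) and 0 <= S <= N and 0 <= k <= N):
        raise GenesetError(f"inconsistent counts g={g}, S={S}, N={N}, k={k}")
    if g == 0:
        return 1.0
    return float(hypergeom.sf(g - 1, N, S, k))


def run_enrichment(
    sig_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each term against the analyzed universe.

    ``gene_sets`` maps term_id -> (term_name, member gene IDs). Terms are
    intersected with the universe before counting; terms with no overlap
    are excluded. Results are sorted by raw P ascending.
    """
    if not gene_sets:
        warnings.warn("empty gene-set collection; nothing to test")
        return []
    N, S = len(universe), len(sig_genes)
    out = []
    for term_id, (name, members) in gene_sets.items():
        in_universe = sorted(set(members) & universe)
        k = len(in_universe)
        if k == 0:
            continue
        hits = tuple(sorted(set(in_universe) & sig_genes))
        p = hypergeometric_test(len(hits), S, N, k)
        out.append(EnrichmentResult(term_id, name, k, len(hits), S, N, p, hits))
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def enrichment_frame(results: list[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tabular enrichment results with a BH-adjusted column for users."""
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "g": [r.g for r in results],
            "S": [r.S for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "genes": [",".join(r.genes) for r in results],
        }
    )
    if len(df):
        m = len(df)
        order = df["p"].to_numpy()
        ranked = np.argsort(order, kind="stable")
        bh = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            j = ranked[i]
            running = min(running, order[j] * m / (i + 1))
            bh[j] = running
        df.insert(7, "p_bh", bh)
        df.insert(8, "significant", df["p"] < alpha)
    return df
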