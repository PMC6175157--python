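"""Synthetic pedigrees, genotypes, QTL architectures and phenotype records.

Everything is driven by a single validated configuration and a seed, so
simulated datasets are fully reproducible. Genotypes are gene-dropped
through the pedigree with unlinked transmission per marker; phenotypes
follow the repeatability model with an additive polygenic component,
optional additive QTL inside the breeding value, and recessive QTL
injected as genotype-conditional shifts outside the breeding value so
that they carry (almost) no additive signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel
from .pedigree import UNKNOWN, Pedigree


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snps: int = 1000
    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_additive_qtl: int = 0
    additive_qtl_var_fraction: float = 0.0
    n_recessive_qtl: int = 0
    recessive_effect: float = -6.0
    recessive_b_freq: float = 0.12
    sigma_u2: float = 4.0
    sigma_pe2: float = 3.0
    sigma_e2: float = 13.0
    records_per_animal_range: tuple[int, int] = (1, 5)
    reliability_range: tuple[float, float] = (0.3, 0.99)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 0 or self.offspring_per_mating < 1:
            raise ConfigError("invalid pedigree counts")
        if self.n_snps < 1 or self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ConfigError("invalid marker-panel geometry")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must lie in (0, 0.5]")
        for name in ("sigma_u2", "sigma_pe2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 < self.recessive_b_freq < 1:
            raise ConfigError("recessive_b_freq must be in (0, 1)")
        if not 0 <= self.additive_qtl_var_fraction <= 1:
            raise ConfigError("additive_qtl_var_fraction must be in [0, 1]")
        rlo, rhi = self.records_per_animal_range
        if not 1 <= rlo <= rhi:
            raise ConfigError("records_per_animal_range must be increasing and >= 1")
        blo, bhi = self.reliability_range
        if not 0 < blo <= bhi <= 1:
            raise ConfigError("reliability_range must lie in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    breeding_values: pd.Series  # per animal, trait units
    pe_values: pd.Series
    additive_qtl: pd.DataFrame  # snp, chrom, pos, effect
    recessive_qtl: pd.DataFrame  # snp, chrom, pos, effect, b_freq


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random-mating pedigree: generation g parents are drawn from
    generation g-1; animals are emitted in topological order."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    prev = []
    for i in range(config.n_founders):
        ids.append(f"F{i:05d}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        prev.append(i)
    for gen in range(1, config.n_generations + 1):
        perm = rng.permutation(prev)
        n_mating = len(perm) // 2
        cur = []
        for m in range(n_mating):
            s, d = int(perm[2 * m]), int(perm[2 * m + 1])
            for o in range(config.offspring_per_mating):
                cur.append(len(ids))
                ids.append(f"G{gen}_{m:05d}_{o}")
                sire.append(s)
                dam.append(d)
        if not cur:
            raise ConfigError("generation produced no offspring; increase n_founders")
        prev = cur
    return Pedigree(ids, np.array(sire), np.array(dam))


def simulate_genotypes(
    ped: Pedigree, config: SimConfig, founder_freqs: np.ndarray | None = None
) -> GenotypePanel:
    """Gene-drop genotypes through the pedigree.

    Founder alleles are Hardy-Weinberg draws at per-marker frequencies
    uniform in ``founder_maf_range`` (or the explicit ``founder_freqs``
    override); offspring receive one allele from each parent with
    unlinked transmission per marker. Markers are placed uniformly on the
    chromosomes and missing calls injected at ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n, m = len(ped), config.n_snps
    if founder_freqs is None:
        freqs = rng.uniform(*config.founder_maf_range, size=m)
    else:
        freqs = np.asarray(founder_freqs, float)
        if freqs.shape != (m,):
            raise ConfigError("founder_freqs must have one entry per SNP")

    # per-marker chromosome and position, sorted
    chrom_idx = np.sort(rng.integers(0, config.n_chromosomes, size=m))
    pos = np.empty(m, dtype=np.int64)
    for c in range(config.n_chromosomes):
        sel = chrom_idx == c
        k = int(sel.sum())
        p = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False)) + 1
        pos[sel] = p
    chrom = np.array([str(c + 1) for c in chrom_idx], dtype=object)
    snp_ids = [f"snp{j:06d}" for j in range(m)]

    # two allele matrices (paternal/maternal), gene dropping
    pat = np.empty((n, m), dtype=np.int8)
    mat = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            pat[i] = rng.random(m) < freqs
        else:
            pick = rng.random(m) < 0.5
            pat[i] = np.where(pick, pat[s], mat[s])
        if d == UNKNOWN:
            mat[i] = rng.random(m) < freqs
        else:
            pick = rng.random(m) < 0.5
            mat[i] = np.where(pick, pat[d], mat[d])
    codes = (pat + mat).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = np.nan
    return GenotypePanel(list(ped.ids), snp_ids, codes, chrom, pos)


def _polygenic_values(ped: Pedigree, sigma2: float, rng) -> np.ndarray:
    """Breeding values sampled down the pedigree (infinitesimal model)."""
    from .pedigree import inbreeding

    n = len(ped)
    a = np.zeros(n)
    if sigma2 == 0:
        return a
    F = inbreeding(ped)
    sd = np.sqrt(sigma2)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            a[i] = rng.normal(0.0, sd)
        else:
            mid, mendel = 0.0, 1.0
            if s != UNKNOWN and d != UNKNOWN:
                mid = 0.5 * (a[s] + a[d])
                mendel = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
            else:
                p = s if s != UNKNOWN else d
                mid = 0.5 * a[p]
                mendel = 0.75 - 0.25 * F[p]
            a[i] = mid + rng.normal(0.0, np.sqrt(mendel * sigma2))
    return a


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypePanel, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Repeated records under the weighted repeatability model.

    Record i of animal j is u_j + pe_j + recessive shifts + e_ij with
    Var(e_ij) = sigma_e2 / reliability_ij. Additive QTL contribute to u;
    recessive QTL add ``recessive_effect`` to BB carriers only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(ped)
    codes = np.nan_to_num(geno.codes, nan=1.0)  # QTL dosage: impute het
    _, _, zero = _freqs(geno)

    # choose QTL markers
    freq_b = np.nansum(geno.codes, axis=0) / (2.0 * (~np.isnan(geno.codes)).sum(axis=0))
    available = np.flatnonzero(~zero)
    rng.shuffle(available)
    add_idx = np.sort(available[: config.n_additive_qtl])

    rec_idx = []
    if config.n_recessive_qtl:
        has_bb = (geno.codes == 2).any(axis=0)
        cand = np.flatnonzero(has_bb & ~np.isin(np.arange(geno.n_snps), add_idx))
        order = np.argsort(np.abs(freq_b[cand] - config.recessive_b_freq), kind="stable")
        rec_idx = np.sort(cand[order[: config.n_recessive_qtl]])
        if len(rec_idx) < config.n_recessive_qtl:
            raise ConfigError("not enough markers with BB carriers for recessive QTL")

    # additive QTL effects scaled to the requested variance fraction
    qtl_var = config.additive_qtl_var_fraction * config.sigma_u2
    u = _polygenic_values(ped, config.sigma_u2 - qtl_var, rng)
    add_effects = np.zeros(len(add_idx))
    if len(add_idx) and qtl_var > 0:
        raw = rng.choice([-1.0, 1.0], size=len(add_idx))
        p = freq_b[add_idx]
        denom = float(np.sum(2 * p * (1 - p)))
        alpha = np.sqrt(qtl_var / max(denom, 1e-12))
        add_effects = raw * alpha
        centered = codes[:, add_idx] - 2 * p[None, :]
        u = u + centered @ add_effects

    rec_shift = np.zeros(n)
    rec_effects = []
    for j in rec_idx:
        rec_effects.append(config.recessive_effect)
        rec_shift += np.where(geno.codes[:, j] == 2, config.recessive_effect, 0.0)

    pe = rng.normal(0.0, np.sqrt(config.sigma_pe2), size=n)

    rows = []
    rlo, rhi = config.records_per_animal_range
    blo, bhi = config.reliability_range
    for i, animal in enumerate(ped.ids):
        n_rec = int(rng.integers(rlo, rhi + 1))
        for r in range(n_rec):
            rel = float(rng.uniform(blo, bhi))
            e = rng.normal(0.0, np.sqrt(config.sigma_e2 / rel))
            rows.append((animal, r + 1, u[i] + pe[i] + rec_shift[i] + e, rel))
    phen = pd.DataFrame(rows, columns=["animal", "record_id", "value", "reliability"])
    truth = TruthRecord(
        breeding_values=pd.Series(u, index=ped.ids),
        pe_values=pd.Series(pe, index=ped.ids),
        additive_qtl=pd.DataFrame(
            {
                "snp": [geno.snp_ids[j] for j in add_idx],
                "chrom": geno.chrom[add_idx] if len(add_idx) else [],
                "pos": geno.pos[add_idx] if len(add_idx) else [],
                "effect": add_effects,
            }
        ),
        recessive_qtl=pd.DataFrame(
            {
                "snp": [geno.snp_ids[j] for j in rec_idx],
                "chrom": geno.chrom[rec_idx] if len(rec_idx) else [],
                "pos": geno.pos[rec_idx] if len(rec_idx) else [],
                "effect": rec_effects,
                "b_freq": freq_b[rec_idx] if len(rec_idx) else [],
            }
        ),
    )
    return phen, truth


def _freqs(geno: GenotypePanel):
    from .genotypes import allele_frequencies

    return allele_frequencies(geno)


def simulate_annotation(
    geno: GenotypePanel, n_genes: int, n_sets: int, seed: int,
    set_size_range: tuple[int, int] = (4, 250),
) -> tuple[pd.DataFrame, dict[str, tuple[str, list[str]]]]:
    """Random non-overlapping gene intervals plus random gene sets.

    Returns a gene table (gene/chrom/start/end, 1-based inclusive) and a
    GMT-style dict term_id -> (description, member genes).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    chroms = list(dict.fromkeys(str(c) for c in geno.chrom))
    span = {c: int(geno.pos[np.asarray(geno.chrom, dtype=str) == c].max()) for c in chroms}
    per_chrom = [n_genes // len(chroms)] * len(chroms)
    for i in range(n_genes % len(chroms)):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for c, k in zip(chroms, per_chrom):
        slot = span[c] // max(k, 1)
        if k and slot < 2:
            raise ConfigError(f"n_genes too large for chromosome {c} length {span[c]}")
        for j in range(k):
            lo = j * slot
            width = int(rng.integers(1, max(2, min(slot - 1, 500_000))))
            start = int(rng.integers(lo, lo + slot - width)) + 1
            rows.append((f"gene{gid:05d}", c, start, start + width))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    all_ids = genes["gene"].tolist()
    lo, hi = set_size_range
    hi = min(hi, len(all_ids))
    lo = min(lo, hi)
    sets: dict[str, tuple[str, list[str]]] = {}
    for t in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(all_ids, size=size, replace=False))
        sets[f"SET{t:04d}"] = (f"synthetic term {t}", list(members))
    return genes, sets
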