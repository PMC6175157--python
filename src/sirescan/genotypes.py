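"""Genotype panel handling: QC, allele frequencies, G and H^-1.

Genotype codes count copies of the B allele (0/1/2); missing calls are
stored as NaN. The genomic relationship matrix follows VanRaden method 1,
blended with the pedigree block A22 to guarantee invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypePanel:
    animal_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # animals x SNPs, float with NaN = missing
    chrom: np.ndarray  # per-SNP chromosome label (str)
    pos: np.ndarray  # per-SNP position, 1-based bp

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.codes.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise GenotypeError("code matrix dimensions do not match ID lists")
        if self.chrom.shape != (m,) or self.pos.shape != (m,):
            raise GenotypeError("map arrays must have one entry per SNP")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos})

    def sorted_by_position(self) -> "GenotypePanel":
        """Panel with SNPs ordered by (chromosome, position)."""
        order = np.lexsort((self.pos, np.asarray(self.chrom, dtype=str)))
        return self.subset_snps(order)

    def subset_snps(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            self.animal_ids,
            [self.snp_ids[i] for i in index],
            self.codes[:, index],
            self.chrom[index],
            self.pos[index],
        )


@dataclass
class QCReport:
    n_input: int
    removed_sex_chrom: int
    removed_monomorphic: int
    removed_low_maf: int
    removed_low_callrate: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [
                    "sex_chromosome",
                    "monomorphic",
                    "low_maf",
                    "low_callrate",
                    "retained",
                ],
                "n_snps": [
                    self.removed_sex_chrom,
                    self.removed_monomorphic,
                    self.removed_low_maf,
                    self.removed_low_callrate,
                    self.n_retained,
                ],
            }
        )


@dataclass
class GenomicMatrix:
    """Blended genomic relationship matrix over genotyped animals."""

    matrix: np.ndarray
    animal_ids: list[str]
    blend_weight: float
    freqs: np.ndarray
    scale: float  # 2 * sum p(1-p), VanRaden denominator
    _inv: np.ndarray | None = field(default=None, repr=False)

    def inverse(self) -> np.ndarray:
        if self._inv is None:
            try:
                c = np.linalg.cholesky(self.matrix)
            except np.linalg.LinAlgError as exc:
                raise GenotypeError(
                    "G is singular; blend with A22 (blend_weight < 1)"
                ) from exc
            diag = np.diag(c)
            if diag.min() < 1e-6 * max(diag.max(), 1.0):
                raise GenotypeError(
                    "G is numerically singular; blend with A22 (blend_weight < 1)"
                )
            inv_c = np.linalg.inv(c)
            self._inv = inv_c.T @ inv_c
        return self._inv


def allele_frequencies(panel: GenotypePanel):
    """B-allele frequency and MAF per SNP, excluding missing calls.

    Returns ``(freq_b, maf, zero_call_mask)``; SNPs with no calls get NaN
    frequency and are flagged in the mask.
    """
    called = ~np.isnan(panel.codes)
    n_called = called.sum(axis=0)
    zero_calls = n_called == 0
    with np.errstate(invalid="ignore"):
        freq = np.nansum(panel.codes, axis=0) / np.where(zero_calls, np.nan, 2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    return freq, maf, zero_calls


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    autosomes_only: bool = True,
    sex_labels: tuple[str, ...] = ("X", "Y"),
):
    """Remove SNPs failing, in order: sex chromosome, monomorphic, MAF,
    call rate. Thresholds are strict: MAF exactly ``maf_min`` and call
    rate exactly ``callrate_min`` are retained.
    """
    _, maf, zero_calls = allele_frequencies(panel)
    callrate = (~np.isnan(panel.codes)).mean(axis=0)
    chrom = np.asarray(panel.chrom, dtype=str)

    removed = np.zeros(panel.n_snps, dtype=int)  # 0 keep, else 1-based filter index
    if autosomes_only:
        removed[np.isin(np.char.upper(chrom), [s.upper() for s in sex_labels])] = 1
    mono = zero_calls | (maf == 0.0)
    removed[(removed == 0) & mono] = 2
    removed[(removed == 0) & (maf < maf_min)] = 3
    removed[(removed == 0) & (callrate < callrate_min)] = 4

    keep = removed == 0
    report = QCReport(
        n_input=panel.n_snps,
        removed_sex_chrom=int((removed == 1).sum()),
        removed_monomorphic=int((removed == 2).sum()),
        removed_low_maf=int((removed == 3).sum()),
        removed_low_callrate=int((removed == 4).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise GenotypeError("no SNPs survive quality control")
    return panel.subset_snps(np.flatnonzero(keep)), report


def center_markers(panel: GenotypePanel, freqs: np.ndarray) -> np.ndarray:
    """Centered marker matrix: code - 2p, missing imputed to 0."""
    z = panel.codes - 2.0 * np.asarray(freqs)[None, :]
    return np.nan_to_num(z, nan=0.0)


def build_G(
    panel: GenotypePanel,
    freqs: np.ndarray,
    a22: np.ndarray,
    blend_weight: float = 0.95,
) -> GenomicMatrix:
    """VanRaden method-1 G blended with A22.

    G_raw = Z Z' / (2 sum p(1-p)); returned matrix is
    blend_weight * G_raw + (1 - blend_weight) * A22.
    """
    if panel.n_animals < 2 or panel.n_snps < 1:
        raise GenotypeError("G requires at least 2 animals and 1 SNP")
    a22 = np.asarray(a22)
    if a22.shape != (panel.n_animals, panel.n_animals):
        raise GenotypeError(
            f"A22 shape {a22.shape} does not match {panel.n_animals} genotyped animals"
        )
    p = np.asarray(freqs, dtype=float)
    z = center_markers(panel, p)
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise GenotypeError("all SNPs monomorphic; G undefined")
    g_raw = (z @ z.T) / scale
    g = blend_weight * g_raw + (1.0 - blend_weight) * a22
    return GenomicMatrix(g, list(panel.animal_ids), blend_weight, p, scale)


def build_H_inverse(
    a_inv: sp.spmatrix,
    g: GenomicMatrix,
    a22: np.ndarray,
    ped: Pedigree,
    genotyped_ids,
) -> sp.csr_matrix:
    """H^-1 = A^-1 with (G^-1 - A22^-1) added in the genotyped block."""
    idx = ped.index_of(genotyped_ids)
    if len(idx) == 0:
        return a_inv.tocsr()
    if g.matrix.shape[0] != len(idx) or np.asarray(a22).shape[0] != len(idx):
        raise GenotypeError("G/A22 dimensions do not match genotyped ID list")
    delta = g.inverse() - np.linalg.inv(np.asarray(a22))
    rows = np.repeat(idx, len(idx))
    cols = np.tile(idx, len(idx))
    block = sp.csr_matrix((delta.ravel(), (rows, cols)), shape=a_inv.shape)
    return (a_inv.tocsr() + block).tocsr()
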