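"""Two-step mixed-model scan for dominance, recessive and overdominance effects.

Step 1 fits y = X beta + u + e with u ~ N(0, G2 sigma_u2) on one record
per animal (the most reliable) and fixes V0 = G2 sigma_u2 + I sigma_e2.
Step 2 screens every SNP under a genotype recoding with the score
statistic z = x' V0^-1 (y - X beta_hat) / sqrt(x' V0^-1 x), which is
asymptotically standard normal; results are deflated by a median-based
genomic-control factor and Bonferroni-thresholded per coding family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .genotypes import GenomicMatrix, GenotypePanel, allele_frequencies

CODINGS = {
    "dominance": {0: 0.0, 1: 1.0, 2: 1.0},
    "recessive": {0: 0.0, 1: 0.0, 2: 1.0},
    "overdominance": {0: 0.0, 1: 1.0, 2: 0.0},
    "additive": {0: 0.0, 1: 1.0, 2: 2.0},
}

# median of the chi-square(1) distribution
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))


class ScanError(RuntimeError):
    pass


@dataclass
class NullModelFit:
    beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    eigvals: np.ndarray  # of G2
    eigvecs: np.ndarray
    resid: np.ndarray  # y - X beta_hat
    X: np.ndarray

    @property
    def xtvix(self) -> np.ndarray:
        return self.X.T @ self.v0_inv_dot(self.X)

    @property
    def v0(self) -> np.ndarray:
        d = self.sigma_u2 * self.eigvals + self.sigma_e2
        return (self.eigvecs * d) @ self.eigvecs.T

    def v0_inv_dot(self, m: np.ndarray) -> np.ndarray:
        """V0^-1 @ m via the eigendecomposition of G2."""
        d = self.sigma_u2 * self.eigvals + self.sigma_e2
        return self.eigvecs @ ((self.eigvecs.T @ m).T / d).T


@dataclass
class SnpTest:
    snp: str
    coding: str
    beta: float
    se: float
    z: float
    p_raw: float
    p_gc: float | None = None
    p_bonf: float | None = None
    flagged: bool = False
    skipped_reason: str | None = None


def select_best_record(phen: pd.DataFrame) -> pd.DataFrame:
    """One record per animal: maximal reliability, ties broken by the
    latest record_id (deterministic)."""
    df = phen.sort_values(
        ["animal", "reliability", "record_id"], kind="stable"
    )
    return df.groupby("animal", sort=False).tail(1).reset_index(drop=True)


def fit_null(
    y: np.ndarray, X: np.ndarray, g2: GenomicMatrix, max_iter: int = 200
) -> NullModelFit:
    """REML fit of the single-record animal model via eigendecomposition.

    Rotating by the eigenvectors of G2 diagonalizes the covariance, so
    each likelihood evaluation is O(n); the heritability ratio is
    profiled and sigma_e2 recovered in closed form.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    lam, U = np.linalg.eigh(g2.matrix)
    lam = np.maximum(lam, 0.0)
    yt, Xt = U.T @ y, U.T @ X

    from scipy.optimize import minimize_scalar

    def profiled(log_gamma):
        g = np.exp(log_gamma)
        d = g * lam + 1.0  # V / sigma_e2
        wx = Xt / d[:, None]
        xtvix = Xt.T @ wx
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return 1e12, None, None
        beta = np.linalg.solve(xtvix, wx.T @ yt)
        r = yt - Xt @ beta
        quad = float(r @ (r / d))
        s_e2 = quad / (n - p)
        nll = 0.5 * ((n - p) * np.log(s_e2) + np.sum(np.log(d)) + logdet_x + (n - p))
        return nll, s_e2, beta

    res = minimize_scalar(
        lambda t: profiled(t)[0], bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter * 10},
    )
    nll, s_e2, _ = profiled(res.x)
    if s_e2 is None or not np.isfinite(nll):
        raise ScanError("null-model REML failed to converge")
    gamma = float(np.exp(res.x))
    sigma_u2, sigma_e2 = gamma * s_e2, s_e2

    # GLS beta under the fitted V0, on the original scale
    d = sigma_u2 * lam + sigma_e2
    wx = Xt / d[:, None]
    beta = np.linalg.solve(Xt.T @ wx, wx.T @ yt)
    resid = y - X @ beta
    return NullModelFit(beta, float(sigma_u2), float(sigma_e2), lam, U, resid, X)


def recode_genotype(codes: np.ndarray, mode: str) -> np.ndarray:
    """Recode 0/1/2 genotypes as a single indicator; missing values are
    imputed to the mean of the recoded non-missing entries."""
    if mode not in CODINGS:
        raise ScanError(f"unknown coding {mode!r}; expected one of {sorted(CODINGS)}")
    codes = np.asarray(codes, float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ScanError(f"invalid genotype codes: {np.unique(codes[bad])}")
    table = CODINGS[mode]
    out = np.full(codes.shape, np.nan)
    for k, v in table.items():
        out[codes == k] = v
    if np.isnan(out).any():
        out = np.where(np.isnan(out), np.nanmean(out), out)
    return out


def score_test(null: NullModelFit, x_snp: np.ndarray, snp: str = "", coding: str = "") -> SnpTest:
    """Wald-approximating score test for one coded SNP vector.

    The SNP vector is adjusted for the null fixed effects under the
    V0^-1 inner product (the numerator is unchanged because the GLS
    residual is already V0^-1-orthogonal to X); without this adjustment
    the statistic is not asymptotically standard normal.
    """
    x = np.asarray(x_snp, float)
    if np.ptp(x) == 0:
        return SnpTest(snp, coding, np.nan, np.nan, np.nan, np.nan,
                       skipped_reason="constant genotype vector")
    vix = null.v0_inv_dot(x)
    cross = null.X.T @ vix
    denom = float(x @ vix - cross @ np.linalg.solve(null.xtvix, cross))
    if denom <= 0:
        return SnpTest(snp, coding, np.nan, np.nan, np.nan, np.nan,
                       skipped_reason="non-positive quadratic form")
    num = float(vix @ null.resid)
    z = num / np.sqrt(denom)
    beta = num / denom
    se = 1.0 / np.sqrt(denom)
    p = 2.0 * norm.sf(abs(z))
    return SnpTest(snp, coding, beta, se, z, max(p, np.finfo(float).tiny))


def score_test_many(null: NullModelFit, X_snps: np.ndarray, snp_ids, coding: str) -> list[SnpTest]:
    """Vectorized score tests for an animals x SNPs matrix of coded genotypes."""
    X_snps = np.asarray(X_snps, float)
    viX = null.v0_inv_dot(X_snps)
    num = viX.T @ null.resid
    cross = null.X.T @ viX  # p x m
    denom = np.einsum("ij,ij->j", X_snps, viX) - np.einsum(
        "ij,ij->j", cross, np.linalg.solve(null.xtvix, cross)
    )
    out = []
    const = np.ptp(X_snps, axis=0) == 0
    for j, snp in enumerate(snp_ids):
        if const[j]:
            out.append(SnpTest(snp, coding, np.nan, np.nan, np.nan, np.nan,
                               skipped_reason="constant genotype vector"))
            continue
        if denom[j] <= 0:
            out.append(SnpTest(snp, coding, np.nan, np.nan, np.nan, np.nan,
                               skipped_reason="non-positive quadratic form"))
            continue
        z = num[j] / np.sqrt(denom[j])
        p = max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny)
        out.append(SnpTest(snp, coding, num[j] / denom[j], 1.0 / np.sqrt(denom[j]), z, p))
    return out


def genomic_control(tests: list[SnpTest]) -> tuple[list[SnpTest], float]:
    """Median-based genomic control: lambda = median(z^2)/0.4549;
    statistics are deflated only when lambda > 1."""
    z2 = np.array([t.z**2 for t in tests if t.skipped_reason is None])
    if z2.size == 0:
        return tests, float("nan")
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    factor = lam if lam > 1.0 else 1.0
    for t in tests:
        if t.skipped_reason is None:
            z_corr = t.z / np.sqrt(factor)
            t.p_gc = max(2.0 * norm.sf(abs(z_corr)), np.finfo(float).tiny)
    return tests, lam


def bonferroni(tests: list[SnpTest], alpha: float = 0.01) -> list[SnpTest]:
    """Per-coding-family Bonferroni: adjusted P = min(1, P * n_tests);
    flagged when adjusted P < alpha (strict)."""
    n = sum(t.skipped_reason is None for t in tests)
    for t in tests:
        if t.skipped_reason is None:
            p = t.p_gc if t.p_gc is not None else t.p_raw
            t.p_bonf = min(1.0, p * n)
            t.flagged = t.p_bonf < alpha
    return tests


def scan_nonadditive(
    panel: GenotypePanel,
    phen: pd.DataFrame,
    g2: GenomicMatrix,
    codings=("dominance", "recessive", "overdominance"),
    covariates: tuple[str, ...] = (),
    alpha: float = 0.01,
    apply_gc: bool = True,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Full two-step scan. Returns one results frame per requested coding
    (each also carrying the additive-coding P) plus run metadata."""
    best = select_best_record(phen)
    best = best.set_index("animal").loc[[str(a) for a in panel.animal_ids]].reset_index()
    y = best["value"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(best))] + [best[c].to_numpy(float) for c in covariates]
    )
    null = fit_null(y, X, g2)

    add_coded = np.column_stack(
        [recode_genotype(panel.codes[:, j], "additive") for j in range(panel.n_snps)]
    )
    add_tests = score_test_many(null, add_coded, panel.snp_ids, "additive")
    p_add = {t.snp: t.p_raw for t in add_tests}

    _, maf, _ = allele_frequencies(panel)
    n_aa = (panel.codes == 0.0).sum(axis=0)
    n_ab = (panel.codes == 1.0).sum(axis=0)
    n_bb = (panel.codes == 2.0).sum(axis=0)

    results: dict[str, pd.DataFrame] = {}
    meta: dict = {"sigma_u2": null.sigma_u2, "sigma_e2": null.sigma_e2, "lambda_gc": {}}
    for mode in codings:
        coded = np.column_stack(
            [recode_genotype(panel.codes[:, j], mode) for j in range(panel.n_snps)]
        )
        tests = score_test_many(null, coded, panel.snp_ids, mode)
        if apply_gc:
            tests, lam = genomic_control(tests)
            meta["lambda_gc"][mode] = lam
        tests = bonferroni(tests, alpha=alpha)
        results[mode] = pd.DataFrame(
            {
                "snp": [t.snp for t in tests],
                "chrom": panel.chrom,
                "pos": panel.pos,
                "maf": maf,
                "n_aa": n_aa,
                "n_ab": n_ab,
                "n_bb": n_bb,
                "beta": [t.beta for t in tests],
                "se": [t.se for t in tests],
                "z": [t.z for t in tests],
                "p_raw": [t.p_raw for t in tests],
                "p_gc": [t.p_gc for t in tests],
                "p_bonf": [t.p_bonf for t in tests],
                "flagged": [t.flagged for t in tests],
                "p_add": [p_add.get(t.snp, np.nan) for t in tests],
                "skipped": [t.skipped_reason or "" for t in tests],
            }
        )
    return results, meta
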