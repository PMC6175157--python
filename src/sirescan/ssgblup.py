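"""Reliability-weighted repeatability animal model and window scan.

The model is y = X beta + Z u + W pe + e with u ~ N(0, H sigma_u^2),
pe ~ N(0, I sigma_pe^2) and Var(e_i) = sigma_e^2 / reliability_i.
Breeding values are solved from Henderson's mixed-model equations with
H^-1; per-SNP effects are back-solved from the genotyped animals' GEBVs
and summarized as the percentage of additive variance captured by
windows of adjacent SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import spsolve

from .genotypes import GenomicMatrix, GenotypePanel, center_markers
from .pedigree import Pedigree


class ModelError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    covariates: tuple[str, ...] = ()
    sigma_u2: float | None = None
    sigma_pe2: float | None = None
    sigma_e2: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_pe2", "sigma_e2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ModelError(f"{name} must be positive when supplied")

    @property
    def has_variances(self) -> bool:
        return None not in (self.sigma_u2, self.sigma_pe2, self.sigma_e2)


@dataclass
class MMESolution:
    beta: np.ndarray
    fixed_names: list[str]
    u: np.ndarray  # GEBV per pedigree animal, pedigree order
    animal_ids: list[str]
    pe: np.ndarray  # per phenotyped animal
    pe_ids: list[str]
    sigma_u2: float
    sigma_pe2: float
    sigma_e2: float
    relative_residual: float

    def u_for(self, ids) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        return self.u[[index[a] for a in ids]]


@dataclass
class MarkerEffects:
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    effects: np.ndarray
    d_weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos, "effect": self.effects}
        )


@dataclass
class WindowResult:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    pct_variance: float


def _design(phen: pd.DataFrame, ped: Pedigree, covariates) -> tuple:
    """Incidence matrices for the repeatability model."""
    n_rec = len(phen)
    animals = phen["animal"].astype(str).to_numpy()
    a_idx = ped.index_of(animals)
    Z = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), a_idx)), shape=(n_rec, len(ped))
    )
    pe_ids = list(dict.fromkeys(animals))  # first-seen order
    pe_pos = {a: i for i, a in enumerate(pe_ids)}
    W = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), [pe_pos[a] for a in animals])),
        shape=(n_rec, len(pe_ids)),
    )
    X = np.column_stack(
        [np.ones(n_rec)] + [phen[c].to_numpy(float) for c in covariates]
    )
    names = ["intercept", *covariates]
    # drop redundant columns (rank deficiency)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping redundant fixed-effect columns: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names, Z, W, pe_ids


def estimate_variance_components(
    phen: pd.DataFrame,
    h_inv: sp.spmatrix,
    ped: Pedigree,
    spec: ModelSpec | None = None,
    max_iter: int = 200,
) -> tuple[float, float, float]:
    """REML estimates of (sigma_u2, sigma_pe2, sigma_e2).

    Maximizes the restricted likelihood of the weighted repeatability
    model directly on the record-level covariance
    V = sigma_u2 ZHZ' + sigma_pe2 WW' + sigma_e2 diag(1/rel)
    over log-variances (quasi-Newton; equivalent stationary points to
    AI-REML, without its step-control pathologies at this scale).
    """
    spec = spec or ModelSpec()
    counts = phen.groupby("animal").size()
    if not (counts > 1).any():
        raise ModelError("sigma_pe2 unidentifiable: no animal has repeated records")
    X, _, Z, W, pe_ids = _design(phen, ped, spec.covariates)
    y = phen["value"].to_numpy(float)
    rel = phen["reliability"].to_numpy(float)
    n, p = X.shape

    # V/sigma_e2 = Zf Gt Zf' + diag(1/rel) with Gt = gu H_ff + gpe I over the
    # phenotyped animals; Woodbury reduces every likelihood evaluation to
    # factorizations of animals x animals matrices (records collapse to
    # reliability-weighted per-animal sums)
    f_idx = ped.index_of(pe_ids)
    H = np.linalg.inv(h_inv.toarray())
    H_ff = H[np.ix_(f_idx, f_idx)]
    nf = len(pe_ids)
    Zf = W  # record -> phenotyped-animal incidence (sparse)
    ZtR = (Zf.T.multiply(rel)).tocsr()  # nf x n
    ZtRZ_diag = np.asarray(Zf.multiply(rel[:, None]).sum(axis=0)).ravel()
    ZtRX = ZtR @ X
    ZtRy = ZtR @ y
    sum_log_rel = float(np.sum(np.log(rel)))

    from scipy.linalg import lu_factor, lu_solve

    eye_nf = np.eye(nf)

    def profiled(log_gamma):
        # determinant lemma: |V/se2| = |I + Gt D| / prod(rel); and
        # (Gt^-1 + D)^-1 = (I + Gt D)^-1 Gt, so one LU serves both
        gu, gpe = np.exp(np.clip(log_gamma, -30, 30))
        Gt = gu * H_ff + gpe * eye_nf
        T = eye_nf + Gt * ZtRZ_diag[None, :]
        try:
            lu = lu_factor(T, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12, None
        logdet_t = float(np.sum(np.log(np.abs(np.diag(lu[0])))))
        logdet_v = logdet_t - sum_log_rel
        minv_zx = lu_solve(lu, Gt @ ZtRX, check_finite=False)
        minv_zy = lu_solve(lu, Gt @ ZtRy, check_finite=False)
        vi_x = rel[:, None] * (X - np.asarray(Zf @ minv_zx))
        vi_y = rel * (y - np.asarray(Zf @ minv_zy).ravel())
        xtvix = X.T @ vi_x
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return 1e12, None
        beta = np.linalg.solve(xtvix, X.T @ vi_y)
        quad = float(y @ vi_y - (X.T @ vi_y) @ beta)
        if quad <= 0:
            return 1e12, None
        s_e2 = quad / (n - p)
        nll = 0.5 * ((n - p) * np.log(s_e2) + logdet_v + logdet_x + (n - p))
        return nll, s_e2

    best = None
    for start in ([0.3, 0.3], [1.0, 0.02]):
        res = minimize(
            lambda t: profiled(t)[0],
            np.log(start),
            method="Nelder-Mead",
            options={"maxiter": max_iter * 5, "xatol": 1e-6, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, s_e2 = profiled(best.x)
    if not np.isfinite(nll) or nll >= 1e12 or s_e2 is None:
        raise ModelError(f"REML failed to converge: {best.message}")
    gu, gpe = np.exp(best.x)
    out = np.array([gu * s_e2, gpe * s_e2, s_e2])
    floor = 1e-10
    if (out < floor).any():
        warnings.warn("variance component at boundary; clamped to 1e-10")
        out = np.maximum(out, floor)
    return float(out[0]), float(out[1]), float(out[2])


def solve_mme(
    phen: pd.DataFrame,
    h_inv: sp.spmatrix,
    ped: Pedigree,
    spec: ModelSpec,
) -> MMESolution:
    """Solve Henderson's mixed-model equations by sparse factorization."""
    if not spec.has_variances:
        raise ModelError("variance components required; estimate or supply them")
    X, names, Z, W, pe_ids = _design(phen, ped, spec.covariates)
    y = phen["value"].to_numpy(float)
    rel = phen["reliability"].to_numpy(float)
    R = sp.diags(rel)  # residual precision weights (x 1/sigma_e2)

    lam_u = spec.sigma_e2 / spec.sigma_u2
    lam_pe = spec.sigma_e2 / spec.sigma_pe2

    Xs = sp.csr_matrix(X)
    blocks = [
        [Xs.T @ R @ Xs, Xs.T @ R @ Z, Xs.T @ R @ W],
        [Z.T @ R @ Xs, Z.T @ R @ Z + lam_u * h_inv, Z.T @ R @ W],
        [W.T @ R @ Xs, W.T @ R @ Z, W.T @ R @ W + lam_pe * sp.eye(W.shape[1])],
    ]
    C = sp.bmat(blocks, format="csc")
    rhs = np.concatenate([Xs.T @ R @ y, Z.T @ R @ y, W.T @ R @ y])
    sol = spsolve(C, rhs)
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30)
    if resid > 1e-8:
        raise ModelError(f"MME solve did not reach tolerance (rel. residual {resid:.2e})")
    p = X.shape[1]
    na = len(ped)
    return MMESolution(
        beta=sol[:p],
        fixed_names=names,
        u=sol[p : p + na],
        animal_ids=list(ped.ids),
        pe=sol[p + na :],
        pe_ids=pe_ids,
        sigma_u2=spec.sigma_u2,
        sigma_pe2=spec.sigma_pe2,
        sigma_e2=spec.sigma_e2,
        relative_residual=float(resid),
    )


def backsolve_snp_effects(
    sol: MMESolution,
    panel: GenotypePanel,
    g: GenomicMatrix,
    d_weights: np.ndarray | None = None,
) -> MarkerEffects:
    """Back-solve SNP effects from GEBVs: s_hat = D M' [M D M']^-1 u_hat.

    M is the centered marker matrix scaled so that M D M' equals the
    (blended) G used to build H^-1; concretely
    s_hat = D Z' G^-1 u_g / scale with scale = 2 sum p(1-p).
    """
    d = np.ones(panel.n_snps) if d_weights is None else np.asarray(d_weights, float)
    if d.shape != (panel.n_snps,):
        raise ModelError("d_weights length must equal the SNP count")
    u_g = sol.u_for(panel.animal_ids)
    z = center_markers(panel, g.freqs)
    s = d * (z.T @ (g.inverse() @ u_g)) / g.scale
    return MarkerEffects(list(panel.snp_ids), panel.chrom, panel.pos, s, d)


def window_scan(
    effects: MarkerEffects,
    panel: GenotypePanel,
    sigma_u2: float,
    window_bp: int = 1_500_000,
    sliding: bool = True,
) -> list[WindowResult]:
    """Percentage of additive variance per window of adjacent SNPs.

    Sliding mode starts one window at every SNP and extends it while the
    spanned positions stay within ``window_bp``; fixed mode uses
    non-overlapping bins of ``window_bp`` from the chromosome start.
    The window genetic value is the centered window genotypes times the
    window effects; its empirical variance across genotyped animals is
    reported as a percentage of ``sigma_u2``.
    """
    if sigma_u2 <= 0:
        raise ModelError("sigma_u2 must be positive")
    if list(effects.snp_ids) != list(panel.snp_ids):
        raise ModelError("effects and panel must cover the same SNPs in order")
    # mean-impute missing codes; the variance is shift-invariant so no
    # further centering is needed
    codes = panel.codes
    col_mean = np.nanmean(codes, axis=0)
    z = np.where(np.isnan(codes), col_mean[None, :], codes)

    results: list[WindowResult] = []
    chrom = np.asarray(panel.chrom, dtype=str)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        pos = panel.pos[sel]
        order = np.argsort(pos, kind="stable")
        sel, pos = sel[order], pos[order]
        if sliding:
            starts = range(len(sel))
        else:
            starts = np.flatnonzero(np.diff(np.concatenate([[-1], pos // window_bp])) != 0)
        for i in starts:
            if sliding:
                j = i
                while j + 1 < len(sel) and pos[j + 1] - pos[i] <= window_bp:
                    j += 1
            else:
                bin_id = pos[i] // window_bp
                j = i
                while j + 1 < len(sel) and pos[j + 1] // window_bp == bin_id:
                    j += 1
            idx = sel[i : j + 1]
            w = z[:, idx] @ effects.effects[idx]
            pct = float(np.var(w, ddof=1) / sigma_u2 * 100.0)
            results.append(
                WindowResult(str(c), int(pos[i]), int(pos[j]), len(idx), pct)
            )
    return results


def collapse_windows(results: list[WindowResult]) -> list[WindowResult]:
    """Per-region maxima: keep windows that are local maxima among all
    overlapping windows on the same chromosome (reporting helper)."""
    out = []
    by_chrom: dict[str, list[WindowResult]] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs.sort(key=lambda r: r.start_bp)
        for r in rs:
            overlapping = [
                o for o in rs if o.start_bp <= r.end_bp and o.end_bp >= r.start_bp
            ]
            if r.pct_variance >= max(o.pct_variance for o in overlapping):
                out.append(r)
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def windows_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "start_bp": [r.start_bp for r in results],
            "end_bp": [r.end_bp for r in results],
            "n_snps": [r.n_snps for r in results],
            "pct_additive_variance": [r.pct_variance for r in results],
        }
    )
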