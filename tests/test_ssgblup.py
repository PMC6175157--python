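import numpy as np
import pandas as pd
import pytest

from sirescan.genotypes import (
    GenotypePanel,
    allele_frequencies,
    build_G,
    build_H_inverse,
    center_markers,
)
from sirescan.pedigree import Pedigree, UNKNOWN, build_A_inverse, subset_A22
from sirescan.ssgblup import (
    MarkerEffects,
    MMESolution,
    ModelError,
    ModelSpec,
    backsolve_snp_effects,
    estimate_variance_components,
    solve_mme,
    window_scan,
)


def dense_gls_solution(phen, H, ped, spec):
    """Dense oracle: GLS for beta, then u = s_u H Z' V^-1 r, pe analogous."""
    n = len(phen)
    ids = {a: i for i, a in enumerate(ped.ids)}
    Z = np.zeros((n, len(ped)))
    pe_ids = list(dict.fromkeys(phen["animal"]))
    wpos = {a: i for i, a in enumerate(pe_ids)}
    W = np.zeros((n, len(pe_ids)))
    for r, a in enumerate(phen["animal"]):
        Z[r, ids[a]] = 1.0
        W[r, wpos[a]] = 1.0
    X = np.ones((n, 1))
    y = phen["value"].to_numpy()
    rel = phen["reliability"].to_numpy()
    V = spec.sigma_u2 * Z @ H @ Z.T + spec.sigma_pe2 * W @ W.T + np.diag(spec.sigma_e2 / rel)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    u = spec.sigma_u2 * H @ Z.T @ Vi @ resid
    pe = spec.sigma_pe2 * W.T @ Vi @ resid
    return beta, u, pe


@pytest.fixture(scope="module")
def fitted(small_dataset):
    cfg, ped, panel, phen, truth = small_dataset
    freqs, _, _ = allele_frequencies(panel)
    ainv = build_A_inverse(ped)
    a22 = subset_A22(ped, panel.animal_ids)
    g = build_G(panel, freqs, a22, blend_weight=0.95)
    hinv = build_H_inverse(ainv, g, a22, ped, panel.animal_ids)
    spec = ModelSpec(sigma_u2=4.0, sigma_pe2=3.0, sigma_e2=13.0)
    sol = solve_mme(phen, hinv, ped, spec)
    return ped, panel, phen, freqs, a22, g, hinv, spec, sol


class TestSolveMME:
    def test_matches_dense_gls_oracle(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        H = np.linalg.inv(hinv.toarray())
        beta, u, pe = dense_gls_solution(phen, H, ped, spec)
        assert np.abs(sol.beta - beta).max() < 1e-8
        assert np.abs(sol.u - u).max() < 1e-8
        assert np.abs(sol.pe - pe).max() < 1e-8

    def test_u_shrinks_to_zero_as_sigma_u_vanishes(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, _, _ = fitted
        spec = ModelSpec(sigma_u2=1e-10, sigma_pe2=3.0, sigma_e2=13.0)
        sol = solve_mme(phen, hinv, ped, spec)
        assert np.abs(sol.u).max() < 1e-6

    def test_single_animal_single_record_shrinkage(self):
        import scipy.sparse as sp

        ped = Pedigree(["A"], np.array([UNKNOWN]), np.array([UNKNOWN]))
        phen = pd.DataFrame(
            {"animal": ["A"], "record_id": [1], "value": [5.0], "reliability": [1.0]}
        )
        spec = ModelSpec(sigma_u2=4.0, sigma_pe2=3.0, sigma_e2=13.0)
        sol = solve_mme(phen, sp.eye(1, format="csr"), ped, spec)
        # dense 3x3 oracle of the same normal equations
        lam_u, lam_pe = 13.0 / 4.0, 13.0 / 3.0
        C = np.array([[1, 1, 1], [1, 1 + lam_u, 1], [1, 1, 1 + lam_pe]], float)
        rhs = np.array([5.0, 5.0, 5.0])
        beta, u, pe = np.linalg.solve(C, rhs)
        assert sol.beta[0] == pytest.approx(beta, abs=1e-10)
        assert sol.u[0] == pytest.approx(u, abs=1e-10)
        assert sol.pe[0] == pytest.approx(pe, abs=1e-10)

    def test_permutation_invariance(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(phen))
        shuffled = phen.iloc[perm].reset_index(drop=True)
        sol2 = solve_mme(shuffled, hinv, ped, spec)
        assert np.abs(sol.u - sol2.u).max() < 1e-8
        pe1 = dict(zip(sol.pe_ids, sol.pe))
        pe2 = dict(zip(sol2.pe_ids, sol2.pe))
        assert max(abs(pe1[a] - pe2[a]) for a in pe1) < 1e-8

    def test_stronger_residual_shrinks_u(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        spec2 = ModelSpec(sigma_u2=4.0, sigma_pe2=3.0, sigma_e2=26.0)
        sol2 = solve_mme(phen, hinv, ped, spec2)
        assert np.abs(sol2.u).sum() < np.abs(sol.u).sum()

    def test_missing_variances_rejected(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, _, _ = fitted
        with pytest.raises(ModelError, match="variance"):
            solve_mme(phen, hinv, ped, ModelSpec())


class TestBacksolve:
    def test_zero_gebv_zero_effects(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        zero = MMESolution(
            sol.beta, sol.fixed_names, np.zeros_like(sol.u), sol.animal_ids,
            sol.pe, sol.pe_ids, 4.0, 3.0, 13.0, 0.0,
        )
        eff = backsolve_snp_effects(zero, panel, g)
        assert np.abs(eff.effects).max() == 0.0

    def test_gblup_snpblup_identity(self, small_dataset):
        cfg, ped, panel, phen, truth = small_dataset
        ainv = build_A_inverse(ped)
        a22 = subset_A22(ped, panel.animal_ids)
        # frequencies must not be the observed ones, else raw G is singular
        freqs = np.full(panel.n_snps, 0.4)
        g = build_G(panel, freqs, a22, blend_weight=1.0)
        hinv = build_H_inverse(ainv, g, a22, ped, panel.animal_ids)
        spec = ModelSpec(sigma_u2=4.0, sigma_pe2=3.0, sigma_e2=13.0)
        sol = solve_mme(phen, hinv, ped, spec)
        eff = backsolve_snp_effects(sol, panel, g)
        pred = center_markers(panel, freqs) @ eff.effects
        assert np.abs(pred - sol.u_for(panel.animal_ids)).max() < 1e-8

    def test_matches_dense_formula(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        sub = panel.subset_snps(np.arange(50))
        sub_idx = np.arange(100)
        sub = GenotypePanel(
            [panel.animal_ids[i] for i in sub_idx], sub.snp_ids,
            sub.codes[sub_idx, :], sub.chrom, sub.pos,
        )
        fr, _, _ = allele_frequencies(sub)
        a22s = subset_A22(ped, sub.animal_ids)
        gs = build_G(sub, fr, a22s, blend_weight=0.95)
        eff = backsolve_snp_effects(sol, sub, gs)
        # literal dense evaluation of D M'[M D M']^-1 u with M = Z/sqrt(scale)
        z = center_markers(sub, fr)
        m = z / np.sqrt(gs.scale)
        u = sol.u_for(sub.animal_ids)
        s = m.T @ np.linalg.inv(gs.matrix) @ u / np.sqrt(gs.scale)
        assert np.abs(eff.effects - s).max() < 1e-10

    def test_d_weights_scale_effects(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        base = backsolve_snp_effects(sol, panel, g)
        dw = np.full(panel.n_snps, 2.0)
        scaled = backsolve_snp_effects(sol, panel, g, d_weights=dw)
        assert np.allclose(scaled.effects, 2.0 * base.effects)


class TestWindowScan:
    def test_zero_effects_zero_percent(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        eff = MarkerEffects(
            list(panel.snp_ids), panel.chrom, panel.pos,
            np.zeros(panel.n_snps), np.ones(panel.n_snps),
        )
        res = window_scan(eff, panel, 4.0)
        assert all(w.pct_variance == 0.0 for w in res)

    def test_single_snp_window_self_normalizing(self):
        codes = np.array([[0.0], [1.0], [2.0]])
        panel = GenotypePanel(
            ["a", "b", "c"], ["s0"], codes, np.array(["1"], dtype=object), np.array([100])
        )
        eff = MarkerEffects(["s0"], panel.chrom, panel.pos, np.array([1.0]), np.ones(1))
        sigma_u2 = float(np.var(codes[:, 0], ddof=1))
        res = window_scan(eff, panel, sigma_u2)
        assert len(res) == 1
        assert res[0].pct_variance == pytest.approx(100.0)
        assert res[0].n_snps == 1

    def test_window_span_and_counts(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        eff = backsolve_snp_effects(sol, panel, g)
        res = window_scan(eff, panel, 4.0, window_bp=1_500_000)
        for w in res:
            assert w.end_bp - w.start_bp <= 1_500_000
            assert w.n_snps >= 1
            assert w.pct_variance >= 0.0

    def test_invariant_to_chromosome_order(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        eff = backsolve_snp_effects(sol, panel, g)
        res = window_scan(eff, panel, 4.0)
        order = np.argsort(np.asarray(panel.chrom, dtype=str), kind="stable")[::-1]
        panel2 = panel.subset_snps(order)
        eff2 = MarkerEffects(
            [eff.snp_ids[i] for i in order], eff.chrom[order], eff.pos[order],
            eff.effects[order], eff.d_weights[order],
        )
        res2 = window_scan(eff2, panel2, 4.0)
        key = lambda w: (w.chrom, w.start_bp, w.end_bp)
        d1 = {key(w): w.pct_variance for w in res}
        d2 = {key(w): w.pct_variance for w in res2}
        assert d1.keys() == d2.keys()
        assert all(abs(d1[k] - d2[k]) < 1e-10 for k in d1)

    def test_invalid_sigma_rejected(self, fitted):
        ped, panel, phen, freqs, a22, g, hinv, spec, sol = fitted
        eff = backsolve_snp_effects(sol, panel, g)
        with pytest.raises(ModelError):
            window_scan(eff, panel, 0.0)


class TestREML:
    def test_balanced_oneway_matches_anova(self):
        # unrelated animals, identity H: animal + pe are confounded, so
        # their REML sum equals the balanced one-way ANOVA between-animal
        # component and sigma_e2 the within mean square
        import scipy.sparse as sp

        rng = np.random.default_rng(21)
        n_animal, n_rec = 150, 4
        u = rng.normal(0, np.sqrt(5.0), n_animal)
        y = u[:, None] + rng.normal(0, np.sqrt(8.0), (n_animal, n_rec))
        phen = pd.DataFrame(
            {
                "animal": np.repeat([f"a{i}" for i in range(n_animal)], n_rec),
                "record_id": np.tile(np.arange(n_rec), n_animal),
                "value": y.ravel(),
                "reliability": 1.0,
            }
        )
        ped = Pedigree(
            [f"a{i}" for i in range(n_animal)],
            np.full(n_animal, UNKNOWN),
            np.full(n_animal, UNKNOWN),
        )
        su, spe, se = estimate_variance_components(phen, sp.eye(n_animal, format="csr"), ped)
        gm = y.mean()
        msb = n_rec * np.sum((y.mean(axis=1) - gm) ** 2) / (n_animal - 1)
        msw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (n_animal * (n_rec - 1))
        assert se == pytest.approx(msw, rel=1e-3)
        assert su + spe == pytest.approx((msb - msw) / n_rec, rel=1e-2)

    def test_requires_repeated_records(self, small_dataset):
        import scipy.sparse as sp

        cfg, ped, panel, phen, truth = small_dataset
        single = phen.groupby("animal").head(1)
        with pytest.raises(ModelError, match="unidentifiable"):
            estimate_variance_components(single, sp.eye(len(ped), format="csr"), ped)

    def test_boundary_when_no_genetic_signal(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(3)
        n = 120
        phen = pd.DataFrame(
            {
                "animal": np.repeat([f"a{i}" for i in range(n)], 2),
                "record_id": np.tile([1, 2], n),
                "value": rng.normal(0, 1, 2 * n),
                "reliability": 1.0,
            }
        )
        ped = Pedigree([f"a{i}" for i in range(n)], np.full(n, UNKNOWN), np.full(n, UNKNOWN))
        su, spe, se = estimate_variance_components(phen, sp.eye(n, format="csr"), ped)
        assert su + spe < 0.3  # pure noise: between-animal variance near zero
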