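import numpy as np
import pandas as pd
import pytest

import corrscan as cs
from corrscan.gblup import AllMissingError, ConfoundedFixedEffectsError, DegenerateGrmError

from conftest import make_pheno


def geno_from_values(values, snp_map=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    snp_map = snp_map or cs.SnpMap(
        chromosome=np.array(["1"] * m, dtype=object),
        position=np.arange(1, m + 1, dtype=np.int64),
        snp_id=np.array([f"s{j}" for j in range(m)], dtype=object),
    )
    return cs.GenotypeMatrix(
        individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        snp_ids=snp_map.snp_id,
        values=values,
        map=snp_map,
    )


class TestAlleleFreqs:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 1, 2], 0.5),
            ([0, 0, 0], 0.0),
            ([2, np.nan, 0], 0.5),  # mean of observed counts only
        ],
    )
    def test_frequency_values(self, column, expected):
        geno = geno_from_values(np.array(column)[:, None])
        assert cs.allele_freqs(geno)[0] == pytest.approx(expected)

    def test_all_missing_column_names_snp(self):
        geno = geno_from_values([[0, np.nan], [1, np.nan]])
        with pytest.raises(AllMissingError, match="s1"):
            cs.allele_freqs(geno)


class TestGrm:
    def test_single_snp_hand_example(self):
        # genotypes (0,1,2): p=0.5, Zc=(-1,0,1), scale=0.5
        grm = cs.build_grm(geno_from_values([[0], [1], [2]]))
        assert grm.scale == pytest.approx(0.5)
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        assert np.allclose(grm.matrix, expected)

    def test_symmetric_and_psd(self, small_geno):
        grm = cs.build_grm(small_geno)
        assert np.array_equal(grm.matrix, grm.matrix.T)
        w = np.linalg.eigvalsh(grm.matrix)
        assert w.min() > -1e-8 * w.max()

    def test_mean_diagonal_near_one_under_hw(self):
        geno = cs.simulate_genotypes(200, cs.uniform_map(1, 5000), ld_rho=0.0, seed=5)
        grm = cs.build_grm(geno)
        assert np.mean(np.diag(grm.matrix)) == pytest.approx(1.0, abs=0.05)

    def test_all_monomorphic_error(self):
        with pytest.raises(DegenerateGrmError):
            cs.build_grm(geno_from_values([[0, 2], [0, 2]]))

    def test_missing_mean_imputed(self):
        vals = np.array([[0.0, 1], [1, 0], [np.nan, 2], [2, 1]])
        grm = cs.build_grm(geno_from_values(vals))
        # imputed entry contributes zero to its own centered column
        p = cs.allele_freqs(geno_from_values(vals))
        assert grm.zc[2, 0] == pytest.approx(0.0)
        assert grm.zc[0, 0] == pytest.approx(-2 * p[0])


class TestSolveMme:
    def test_identity_grm_closed_form(self, tiny_map):
        # G = I, intercept-only X, y=(1,2,3), alpha=1 -> a = (y - ybar)/2
        grm = cs.Grm(
            matrix=np.eye(3),
            scale=1.0,
            freqs=np.full(3, 0.5),
            zc=np.eye(3),
            individual_ids=np.array(["i0", "i1", "i2"], dtype=object),
            map=tiny_map,
        )
        pheno = make_pheno(["i0", "i1", "i2"], [1.0, 2.0, 3.0])
        fit = cs.solve_mme(pheno, grm, cs.VarianceComponents(1.0, 1.0))
        assert np.allclose(fit.a_hat, [-0.5, 0.0, 0.5], atol=1e-10)
        assert fit.b[0] == pytest.approx(2.0)

    def test_matches_dense_bruteforce_oracle(self, rng):
        """The substitution-form solve equals a brute-force dense solve of the
        untransformed Henderson system with explicit R^-1 and (G sigma_g^2)^-1."""
        for trial in range(10):
            n = int(rng.integers(10, 50))
            geno = cs.simulate_genotypes(n, cs.uniform_map(1, 200), seed=int(rng.integers(2**31)))
            grm = cs.build_grm(geno)
            ridge = 0.01  # makes G safely invertible so the oracle exists
            y = rng.normal(size=n)
            groups = rng.choice(["a", "b"], size=n)
            pheno = make_pheno(geno.individual_ids, y, groups)
            vc = cs.VarianceComponents(sigma_g2=float(rng.uniform(0.5, 2)),
                                       sigma_e2=float(rng.uniform(0.2, 2)))
            fit = cs.solve_mme(pheno, grm, vc, ridge=ridge)
            x = pheno.design
            gr = grm.matrix + ridge * np.eye(n)
            ginv = np.linalg.inv(gr)
            se, sg = vc.sigma_e2, vc.sigma_g2
            coeff = np.block([
                [x.T @ x / se, x.T / se],
                [x / se, np.eye(n) / se + ginv / sg],
            ])
            rhs = np.concatenate([x.T @ y / se, y / se])
            sol = np.linalg.solve(coeff, rhs)
            p = x.shape[1]
            assert np.allclose(fit.b, sol[:p], atol=1e-8)
            assert np.allclose(fit.a_hat, sol[p:], atol=1e-8)

    def test_residual_orthogonal_to_design(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        pheno = make_pheno(small_geno.individual_ids, rng.normal(size=small_geno.n_individuals),
                           rng.choice(["a", "b", "c"], size=small_geno.n_individuals))
        fit = cs.solve_mme(pheno, grm, cs.VarianceComponents(1.0, 0.5))
        resid = pheno.y - pheno.design @ fit.b - fit.a_hat
        assert np.abs(pheno.design.T @ resid).max() < 1e-8

    def test_near_zero_genetic_variance_shrinks_gebvs_to_zero(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        pheno = make_pheno(small_geno.individual_ids, rng.normal(size=small_geno.n_individuals))
        fit = cs.solve_mme(pheno, grm, cs.VarianceComponents(1e-12, 1.0))
        assert np.abs(fit.a_hat).max() < 1e-9

    def test_shrinkage_monotone_in_alpha(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        y = rng.normal(size=small_geno.n_individuals)
        pheno = make_pheno(small_geno.individual_ids, y)
        norms = []
        for alpha in (0.25, 1.0, 4.0, 16.0):
            fit = cs.solve_mme(pheno, grm, cs.VarianceComponents(1.0, alpha))
            norms.append(np.linalg.norm(fit.a_hat))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_scaling_equivariance(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        y = rng.normal(size=small_geno.n_individuals)
        vc = cs.VarianceComponents(1.0, 0.8)
        vc_scaled = cs.VarianceComponents(9.0, 7.2)  # variances x c^2, same alpha
        f1 = cs.solve_mme(make_pheno(small_geno.individual_ids, y), grm, vc)
        f2 = cs.solve_mme(make_pheno(small_geno.individual_ids, 3 * y), grm, vc_scaled)
        assert np.allclose(3 * f1.b, f2.b)
        assert np.allclose(3 * f1.a_hat, f2.a_hat)
        u1 = cs.backsolve_effects(f1).u_hat
        u2 = cs.backsolve_effects(f2).u_hat
        assert np.allclose(3 * u1, u2)

    def test_rank_deficient_design_rejected(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        n = small_geno.n_individuals
        df = pd.DataFrame({
            "id": small_geno.individual_ids,
            "t": rng.normal(size=n),
            "x1": np.ones(n),  # collinear with the intercept
        })
        pheno = cs.PhenotypeTable.from_frame(df, "t", fixed=["x1"])
        with pytest.raises(ConfoundedFixedEffectsError):
            cs.solve_mme(pheno, grm, cs.VarianceComponents(1.0, 1.0))


class TestGrmPcs:
    def test_sign_rule_and_reconstruction(self, small_geno):
        grm = cs.build_grm(small_geno)
        n = grm.n
        pcs = cs.grm_pcs(grm, n)
        v = pcs.to_numpy()
        for j in range(n):
            assert v[np.argmax(np.abs(v[:, j])), j] > 0
        w = np.sort(np.linalg.eigvalsh(grm.matrix))[::-1]
        assert np.allclose(v @ np.diag(w) @ v.T, grm.matrix, atol=1e-8)

    def test_two_cluster_separation(self, tiny_map):
        # block kinship: within-cluster excess relatedness, between-cluster deficit
        n = 20
        contrast = np.array([1.0] * 10 + [-1.0] * 10)
        g = np.eye(n) + 0.8 * np.outer(contrast, contrast) / n
        grm = cs.Grm(
            matrix=g, scale=1.0, freqs=np.full(3, 0.5), zc=np.zeros((n, 3)),
            individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
            map=tiny_map,
        )
        pc1 = cs.grm_pcs(grm, 1)["PC1"].to_numpy()
        assert len(np.unique(np.sign(pc1[:10]))) == 1
        assert len(np.unique(np.sign(pc1[10:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[-1])

    def test_k_validation(self, small_geno):
        grm = cs.build_grm(small_geno)
        with pytest.raises(ValueError):
            cs.grm_pcs(grm, 0)
        with pytest.raises(ValueError):
            cs.grm_pcs(grm, grm.n + 1)


class TestBacksolve:
    def test_reconstruction_identity(self, small_geno, rng):
        grm = cs.build_grm(small_geno)
        pheno = make_pheno(small_geno.individual_ids, rng.normal(size=small_geno.n_individuals))
        fit = cs.solve_mme(pheno, grm, cs.VarianceComponents(1.0, 1.0))
        u = cs.backsolve_effects(fit)
        rel = np.linalg.norm(grm.zc @ u.u_hat - fit.a_hat) / np.linalg.norm(fit.a_hat)
        assert rel < 1e-8

    def test_single_snp_toy_against_pinv_oracle(self):
        # 1-SNP GRM from genotypes (0,1,2) with a = (-1, 0, 1):
        # u = Zc' G^+ a / scale computed by explicit pseudo-inverse
        geno = geno_from_values([[0], [1], [2]])
        grm = cs.build_grm(geno)
        a = np.array([-1.0, 0.0, 1.0])
        expected = grm.zc.T @ np.linalg.pinv(grm.matrix) @ a / grm.scale
        fit = cs.GblupFit(
            b=np.zeros(1), a_hat=a, varcomps=cs.VarianceComponents(1.0, 1.0),
            grm=grm, ginv_a=np.linalg.pinv(grm.matrix) @ a,
            design_names=["intercept"], trait="t",
        )
        u = cs.backsolve_effects(fit)
        assert u.u_hat[0] == pytest.approx(expected[0])
        assert u.u_hat[0] == pytest.approx(1.0)  # hand-computed value

    def test_zero_gebvs_give_zero_effects(self, small_geno):
        grm = cs.build_grm(small_geno)
        fit = cs.GblupFit(
            b=np.zeros(1), a_hat=np.zeros(grm.n), varcomps=cs.VarianceComponents(1.0, 1.0),
            grm=grm, ginv_a=np.zeros(grm.n), design_names=["intercept"], trait="t",
        )
        assert np.all(cs.backsolve_effects(fit).u_hat == 0.0)


class TestVarianceComponents:
    def test_alpha_from_h2(self):
        vc = cs.VarianceComponents.from_h2(0.4, 10.0)
        assert vc.sigma_g2 == pytest.approx(4.0)
        assert vc.alpha == pytest.approx(1.5)  # (1 - h2) / h2

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.VarianceComponents(0.0, 1.0)
        with pytest.raises(ValueError):
            cs.VarianceComponents(1.0, -0.1)
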