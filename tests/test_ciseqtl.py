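"""cis-eQTL mapping: OLS oracle equivalence, permutation scheme, q-values, NB pass."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scqtl import ciseqtl, simdata


def ols_oracle(y, x, cov):
    """Closed-form full-design OLS for the dosage coefficient (independent oracle)."""
    n = len(y)
    design = np.column_stack([np.ones(n), x, cov])
    p = design.shape[1]
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = xtx_inv @ design.T @ y
    resid = y - design @ coef
    df = n - p
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = coef[1] / se
    return coef[1], se, 2 * stats.t.sf(abs(t), df)


def _toy_genotypes(n_donors, positions, dosages, mafs=None):
    m = len(positions)
    dosages = np.asarray(dosages, dtype=float)
    p_emp = dosages.mean(axis=0) / 2
    return simdata.GenotypeMatrix(
        dosages=dosages,
        variants=pd.DataFrame(
            dict(
                variant_id=[f"v{j}" for j in range(m)],
                chrom="1",
                pos=positions,
                ref="A",
                alt="G",
                maf=np.minimum(p_emp, 1 - p_emp) if mafs is None else mafs,
                impq=1.0,
            )
        ),
        donors=[f"d{i}" for i in range(n_donors)],
    )


class TestNominalPass:
    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(20, 50)
            k = rng.integers(1, 5)
            x = rng.binomial(2, 0.4, n).astype(float)
            cov = rng.standard_normal((n, k))
            y = 0.4 * x + cov @ rng.standard_normal(k) + rng.standard_normal(n)
            geno = _toy_genotypes(n, [1000], x[:, None], mafs=[0.4])
            pheno = pd.DataFrame([y], index=["g"], columns=geno.donors)
            tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[1000]))
            rec = ciseqtl.nominal_pass(pheno, geno, cov, tss).iloc[0]
            b, se, p = ols_oracle(y, x, cov)
            assert rec["beta"] == pytest.approx(b, abs=1e-10)
            assert rec["se"] == pytest.approx(se, abs=1e-10)
            assert rec["p_nominal"] == pytest.approx(p, abs=1e-10)

    def test_orthogonal_dosage_gives_zero_beta_p_one(self):
        n = 24
        x = np.r_[np.ones(n // 2), -np.ones(n // 2)] + 1.0  # dosage 0/2
        y = np.tile([1.0, -1.0], n // 2)
        y = y - y.mean()
        x_c = x - x.mean()
        assert abs(x_c @ y) < 1e-12
        geno = _toy_genotypes(n, [1000], x[:, None], mafs=[0.5])
        pheno = pd.DataFrame([y], index=["g"], columns=geno.donors)
        tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[1000]))
        rec = ciseqtl.nominal_pass(pheno, geno, np.zeros((n, 0)), tss).iloc[0]
        assert abs(rec["beta"]) < 1e-12
        assert rec["p_nominal"] == pytest.approx(1.0, abs=1e-12)

    def test_cis_window_boundary_inclusive(self):
        n = 30
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        tss_pos = 2_000_000
        geno = _toy_genotypes(
            n, [tss_pos - 1_000_000, tss_pos + 1_000_001], dos, mafs=[0.4, 0.4]
        )
        pheno = pd.DataFrame(
            [rng.standard_normal(n)], index=["g"], columns=geno.donors
        )
        tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[tss_pos]))
        out = ciseqtl.nominal_pass(pheno, geno, np.zeros((n, 0)), tss)
        assert list(out["variant_id"]) == ["v0"]
        assert out["tss_distance"].iloc[0] == -1_000_000

    def test_allele_flip_negates_beta(self):
        rng = np.random.default_rng(2)
        n = 40
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * x + rng.standard_normal(n)
        tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[1000]))
        rec1 = ciseqtl.nominal_pass(
            pd.DataFrame([y], index=["g"], columns=[f"d{i}" for i in range(n)]),
            _toy_genotypes(n, [1000], x[:, None], mafs=[0.3]),
            np.zeros((n, 0)), tss,
        ).iloc[0]
        rec2 = ciseqtl.nominal_pass(
            pd.DataFrame([y], index=["g"], columns=[f"d{i}" for i in range(n)]),
            _toy_genotypes(n, [1000], (2 - x)[:, None], mafs=[0.3]),
            np.zeros((n, 0)), tss,
        ).iloc[0]
        assert rec1["beta"] == pytest.approx(-rec2["beta"], abs=1e-12)
        assert rec1["p_nominal"] == pytest.approx(rec2["p_nominal"], rel=1e-9)

    def test_maf_and_impq_filter(self):
        vf = ciseqtl.VariantFilter()
        variants = pd.DataFrame(
            dict(maf=[0.04, 0.06, 0.5], impq=[1.0, 0.2, 0.9])
        )
        np.testing.assert_array_equal(vf.apply(variants), [False, False, True])

    def test_rank_deficient_covariates_error(self):
        n = 20
        cov = np.ones((n, 2))  # collinear with intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            ciseqtl._check_covariates(n, cov)


class TestPermutationPass:
    def test_single_variant_null_beta_fit_near_uniform(self):
        rng = np.random.default_rng(3)
        n = 60
        y = rng.standard_normal(n)
        x = rng.binomial(2, 0.4, (n, 1)).astype(float)
        res = ciseqtl.permutation_pass(y, x, np.zeros((n, 0)), n_perm=5000, seed=1)
        assert 0.8 <= res["beta_shape1"] <= 1.25
        assert 0.8 <= res["beta_shape2"] <= 1.25

    def test_top_p_of_one_maps_to_adjusted_one(self):
        # direct check of the beta CDF mapping at the upper endpoint
        assert stats.beta.cdf(1.0, 0.9, 1.1) == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        n = 50
        y = rng.standard_normal(n)
        x = rng.binomial(2, 0.3, (n, 5)).astype(float)
        cov = rng.standard_normal((n, 2))
        a = ciseqtl.permutation_pass(y, x, cov, n_perm=200, seed=7)
        b = ciseqtl.permutation_pass(y, x, cov, n_perm=200, seed=7)
        assert a["p_beta_adjusted"] == b["p_beta_adjusted"]
        np.testing.assert_array_equal(a["perm_minima"], b["perm_minima"])

    def test_refuses_too_few_permutations(self):
        with pytest.raises(ValueError):
            ciseqtl.permutation_pass(
                np.zeros(10), np.ones((10, 1)), np.zeros((10, 0)), n_perm=50
            )

    def test_beta_adjusted_matches_empirical(self):
        # moderate-effect gene: the two gene-level p-values agree
        rng = np.random.default_rng(5)
        n = 80
        x = rng.binomial(2, 0.3, (n, 10)).astype(float)
        y = 0.35 * x[:, 3] + rng.standard_normal(n)
        res = ciseqtl.permutation_pass(y, x, np.zeros((n, 0)), n_perm=10_000, seed=2)
        if 0.001 <= res["p_perm_empirical"] <= 0.5:
            assert res["p_beta_adjusted"] == pytest.approx(
                res["p_perm_empirical"], abs=0.01
            )

    def test_refit_mode_agrees_with_residual_mode_without_covariates(self):
        rng = np.random.default_rng(6)
        n = 40
        y = rng.standard_normal(n)
        x = rng.binomial(2, 0.4, (n, 3)).astype(float)
        a = ciseqtl.permutation_pass(y, x, np.zeros((n, 0)), n_perm=200, seed=3, mode="residual")
        b = ciseqtl.permutation_pass(y, x, np.zeros((n, 0)), n_perm=200, seed=3, mode="refit")
        np.testing.assert_allclose(a["perm_minima"], b["perm_minima"], atol=1e-12)


class TestBetaFit:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(7)
        x = rng.beta(2.0, 5.0, size=20_000)
        a, b = ciseqtl.fit_beta_ml(x)
        assert a == pytest.approx(2.0, rel=0.1)
        assert b == pytest.approx(5.0, rel=0.1)


class TestCallEgenes:
    def test_all_p_one_gives_zero_egenes(self):
        df = pd.DataFrame(dict(p_beta_adjusted=np.ones(50)))
        out = ciseqtl.call_egenes(df)
        assert out["is_egene"].sum() == 0

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        q, _ = ciseqtl.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_few_genes_falls_back_to_bh(self):
        p = np.array([0.001, 0.2, 0.9])
        with pytest.warns(UserWarning):
            q, pi0 = ciseqtl.storey_qvalues(p)
        assert pi0 == 1.0
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_false_discovery_proportion_controlled(self):
        # 10 true signals at p = 1e-4, 990 nulls: FDP <= 0.10 on average
        rng = np.random.default_rng(9)
        fdps = []
        for _ in range(20):
            p = np.r_[np.full(10, 1e-4), rng.random(990)]
            df = pd.DataFrame(dict(p_beta_adjusted=p))
            out = ciseqtl.call_egenes(df, alpha=0.05)
            called = out.index[out["is_egene"]]
            n_false = (called >= 10).sum()
            fdps.append(n_false / max(len(called), 1))
        assert np.mean(fdps) <= 0.10


class TestNbPass:
    def _setup(self, n=60, seed=0, beta=0.5, theta=2.0):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.4, n).astype(float)
        lib = rng.lognormal(np.log(5000), 0.2, n)
        mu = np.exp(np.log(0.002) + beta * x) * lib
        y = rng.poisson(rng.gamma(theta, mu / theta))
        return x, lib, y

    def test_known_effect_recovered(self):
        hits = 0
        for rep in range(60):
            x, lib, y = self._setup(seed=rep)
            geno = _toy_genotypes(len(y), [1000], x[:, None], mafs=[0.4])
            raw = pd.DataFrame([y], index=["g"], columns=geno.donors)
            raw.loc["filler"] = (lib - y).astype(int)  # fix library size
            tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[1000]))
            out = ciseqtl.nb_pass(raw, geno, np.zeros((len(y), 0)), tss)
            rec = out[out["gene_id"] == "g"].iloc[0]
            hits += abs(rec["beta"] - 0.5) < 3 * rec["se"]
        assert hits >= 0.9 * 60

    def test_poisson_limit_matches_poisson_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 150
        x = rng.binomial(2, 0.4, n).astype(float)
        lib = np.full(n, 2000.0)
        mu = np.exp(np.log(0.05) + 0.3 * x) * lib
        y = rng.poisson(mu)  # no overdispersion
        geno = _toy_genotypes(n, [1000], x[:, None], mafs=[0.4])
        raw = pd.DataFrame([y], index=["g"], columns=geno.donors)
        raw.loc["filler"] = (lib - y).astype(int)
        tss = pd.DataFrame(dict(gene_id=["g"], chrom=["1"], tss=[1000]))
        rec = ciseqtl.nb_pass(raw, geno, np.zeros((n, 0)), tss)
        rec = rec[rec["gene_id"] == "g"].iloc[0]
        design = np.column_stack([np.ones(n), x])
        pois = sm.GLM(y, design, family=sm.families.Poisson(), offset=np.log(lib)).fit()
        z_pois = pois.params[1] / pois.bse[1]
        assert rec["t_stat"] == pytest.approx(z_pois, rel=0.01)

    def test_all_zero_gene_skipped(self):
        n = 30
        rng = np.random.default_rng(11)
        x = rng.binomial(2, 0.4, n).astype(float)
        geno = _toy_genotypes(n, [1000], x[:, None], mafs=[0.4])
        raw = pd.DataFrame(
            [np.zeros(n, dtype=int), np.full(n, 100)],
            index=["dead", "alive"],
            columns=geno.donors,
        )
        tss = pd.DataFrame(
            dict(gene_id=["dead", "alive"], chrom=["1", "1"], tss=[1000, 1000])
        )
        out = ciseqtl.nb_pass(raw, geno, np.zeros((n, 0)), tss)
        assert "dead" not in set(out["gene_id"])


class TestTypeIControl:
    def test_null_cohort_uniform_p_and_no_egenes(self):
        cfg = simdata.SimConfig(
            n_donors=100,
            n_variants=40,
            n_genes=60,
            n_cell_types=1,
            cells_per_donor_per_type=(25, 5),
            effect_grid=[(0.0, "null")],
            variant_spacing=100_000,
            seed=12,
        )
        from scqtl import pseudobulk as pb

        geno = simdata.simulate_genotypes(cfg)
        cells, _ = simdata.simulate_cells(cfg, geno)
        pbs = pb.normalize_all(pb.aggregate(cells))
        age = simdata.donor_ages(cfg)
        cov = pb.build_covariates(pbs, geno, age, n_factors=2)
        ct = pbs.cell_types[0]
        design = cov.design(ct, pbs.qualifying_donors[ct])
        nominal = ciseqtl.nominal_pass(
            pbs.normalized[ct], geno, design, cells.genes
        )
        ks = stats.kstest(nominal["p_nominal"], "uniform")
        assert ks.pvalue > 0.01 or len(nominal) > 500  # pairs share LD, KS approximate
        eg = ciseqtl.map_cell_type(
            pbs.normalized[ct], geno, design, cells.genes, n_perm=300, seed=1
        )
        assert eg["is_egene"].sum() == 0
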