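"""Pseudotime quantiles, NB mixed-effects interaction model, trend classification."""

import numpy as np
import pandas as pd
import pytest

from scqtl import dynamic as dyn
from scqtl import simdata
from scqtl.nbglmm import fit_nb_glmm

from conftest import make_cell_table


def _with_pseudotime(cells, pt):
    cells.cells["pseudotime"] = pt
    return cells


class TestAssignQuantiles:
    def test_600_cells_six_equal_bins(self):
        cells = make_cell_table([("d0", "AT2", 600)])
        rng = np.random.default_rng(0)
        _with_pseudotime(cells, rng.uniform(0, 30, 600))
        a = dyn.assign_quantiles(cells, q=6)
        sizes = a.quantile.value_counts().sort_index()
        assert (sizes == 100).all()

    def test_601_cells_one_bin_of_101(self):
        cells = make_cell_table([("d0", "AT2", 601)])
        _with_pseudotime(cells, np.random.default_rng(1).uniform(0, 30, 601))
        a = dyn.assign_quantiles(cells, q=6)
        sizes = sorted(a.quantile.value_counts().sort_index())
        assert sizes == [100, 100, 100, 100, 100, 101]

    def test_infinite_pseudotime_removed(self):
        cells = make_cell_table([("d0", "AT2", 610)])
        pt = np.r_[np.random.default_rng(2).uniform(0, 30, 600), [np.inf] * 10]
        _with_pseudotime(cells, pt)
        a = dyn.assign_quantiles(cells, q=6)
        assert (a.quantile > 0).sum() == 600
        assert (a.quantile.iloc[-10:] == 0).all()

    def test_monotone_transform_invariance(self):
        cells = make_cell_table([("d0", "AT2", 200)])
        pt = np.random.default_rng(3).uniform(0, 30, 200)
        _with_pseudotime(cells, pt)
        a = dyn.assign_quantiles(cells, q=6)
        _with_pseudotime(cells, np.exp(pt / 10))
        b = dyn.assign_quantiles(cells, q=6)
        pd.testing.assert_series_equal(a.quantile, b.quantile)

    def test_too_few_finite_cells_errors(self):
        cells = make_cell_table([("d0", "AT2", 4)])
        _with_pseudotime(cells, [1.0, 2.0, 3.0, np.inf])
        with pytest.raises(ValueError):
            dyn.assign_quantiles(cells, q=6)

    def test_branch_mask_restricts_cell_types(self):
        cells = make_cell_table([("d0", "AT2", 50), ("d0", "NK", 50)])
        _with_pseudotime(cells, np.r_[np.linspace(0, 30, 50), np.linspace(0, 30, 50)])
        a = dyn.assign_quantiles(cells, trajectory_cell_types=["AT2"], q=5)
        ct = cells.cells.set_index("cell_id")["cell_type"]
        assert (a.quantile[ct == "NK"] == 0).all()
        assert (a.quantile[ct == "AT2"] > 0).all()


def _simulate_interaction_data(seed, slope, n_donors=80, cells_per=6, maf=0.5,
                               donor_sd=0.3, theta=2.0):
    rng = np.random.default_rng(seed)
    donors = np.repeat(np.arange(n_donors), cells_per)
    n = len(donors)
    dos = rng.binomial(2, maf, n_donors)[donors].astype(float)
    q = rng.integers(1, 7, n).astype(float)
    qc = q - 3.5
    u = rng.normal(0, donor_sd, n_donors)
    n_umi = rng.lognormal(np.log(2000), 0.3, n)
    eta = np.log(0.02) + 0.4 * dos + 0.05 * qc + slope * dos * qc + u[donors] + np.log(n_umi)
    y = rng.poisson(rng.gamma(theta, np.exp(eta) / theta))
    design = dict(
        quantile_centered=qc,
        covariates=np.zeros((n, 0)),
        covariate_names=[],
        offset=np.log(n_umi),
        donors=donors,
    )
    return y, dos, q, design


class TestFitInteraction:
    def test_recovers_positive_slope(self):
        y, dos, _, design = _simulate_interaction_data(0, slope=0.15)
        out = dyn.fit_interaction(y, dos, design)
        assert out["converged"]
        assert out["beta_interaction"] == pytest.approx(0.15, abs=3 * out["se_interaction"])
        assert out["p_interaction"] < 0.05

    def test_null_slope_not_significant_usually(self):
        ps = []
        for seed in range(12):
            y, dos, _, design = _simulate_interaction_data(100 + seed, slope=0.0)
            ps.append(dyn.fit_interaction(y, dos, design)["p_interaction"])
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_zero_donor_sd_matches_fixed_effect_glm(self):
        from statsmodels.discrete.discrete_model import NegativeBinomial
        from scipy import stats as st

        y, dos, _, design = _simulate_interaction_data(7, slope=0.1, donor_sd=0.0)
        mixed = dyn.fit_interaction(y, dos, design, re_mode="aghq")
        assert mixed["result"].sigma < 0.1
        qc = design["quantile_centered"]
        x = np.column_stack([np.ones(len(y)), dos, qc, dos * qc])
        glm = NegativeBinomial(y, x, offset=design["offset"]).fit(disp=0, maxiter=500)
        p_glm = 2 * st.norm.sf(abs(glm.params[3] / glm.bse[3]))
        assert mixed["p_interaction"] == pytest.approx(p_glm, rel=0.10, abs=0.005)

    def test_mixed_loglik_at_least_poisson_on_overdispersed_data(self):
        import statsmodels.api as sm

        y, dos, _, design = _simulate_interaction_data(8, slope=0.1, theta=0.8)
        qc = design["quantile_centered"]
        x = np.column_stack([np.ones(len(y)), dos, qc, dos * qc])
        res = fit_nb_glmm(y, x, design["offset"], design["donors"])
        pois = sm.GLM(y, x, family=sm.families.Poisson(), offset=design["offset"]).fit()
        assert res.loglik >= pois.llf

    def test_singular_design_flagged(self):
        y, dos, _, design = _simulate_interaction_data(9, slope=0.0)
        design = dict(design)
        design["covariates"] = dos[:, None]  # duplicates the dosage column
        design["covariate_names"] = ["dup"]
        out = dyn.fit_interaction(y, dos, design)
        assert not out["converged"] and np.isnan(out["p_interaction"])


class TestPerQuantileEffects:
    def test_constant_effect_recovered_in_each_quantile(self):
        y, dos, q, design = _simulate_interaction_data(
            10, slope=0.0, n_donors=120, cells_per=12
        )
        out = dyn.per_quantile_effects(y, dos, design, q, min_cells=30)
        ok = out.dropna(subset=["beta_q"])
        assert len(ok) == 6
        within = np.abs(ok["beta_q"] - 0.4) <= 3 * ok["se_q"]
        assert within.sum() >= 5

    def test_sign_flip_trajectory(self):
        # strong interaction crossing zero mid-trajectory
        y, dos, q, design = _simulate_interaction_data(
            11, slope=0.35, n_donors=120, cells_per=12
        )
        # remove the main effect so beta crosses 0: regenerate directly
        rng = np.random.default_rng(11)
        n = len(y)
        qc = design["quantile_centered"]
        eta = np.log(0.02) + 0.35 * dos * qc + design["offset"]
        y2 = rng.poisson(rng.gamma(2.0, np.exp(eta) / 2.0))
        out = dyn.per_quantile_effects(y2, dos, design, q, min_cells=30)
        betas = out["beta_q"].to_numpy()
        assert np.sign(betas[0]) == -np.sign(betas[5])

    def test_quantile_without_alt_carriers_missing(self):
        y, dos, q, design = _simulate_interaction_data(12, slope=0.0)
        dos = dos.copy()
        dos[q == 3] = 0.0  # monomorphic within quantile 3
        out = dyn.per_quantile_effects(y, dos, design, q, min_cells=5)
        assert np.isnan(out.loc[out["quantile"] == 3, "beta_q"].iloc[0])
        assert out.loc[out["quantile"] != 3, "beta_q"].notna().all()

    def test_small_quantile_skipped(self):
        y, dos, q, design = _simulate_interaction_data(13, slope=0.0)
        q = q.copy()
        q[q == 2] = 1
        q[np.flatnonzero(q == 1)[:3]] = 2  # quantile 2 has 3 cells
        out = dyn.per_quantile_effects(y, dos, design, q, min_cells=30)
        assert np.isnan(out.loc[out["quantile"] == 2, "beta_q"].iloc[0])


class TestClassifyTrend:
    def test_exact_line_is_linear(self):
        out = dyn.classify_trend([1, 2, 3, 4, 5, 6], [1e-3] * 6)
        assert out["trend_class"] == "linear"
        assert out["p_linear"] < 1e-10 and out["p_quadratic"] > 0.05

    def test_symmetric_parabola_is_quadratic(self):
        out = dyn.classify_trend([4, 1, 0, 0, 1, 4], [1e-3] * 6)
        assert out["trend_class"] == "quadratic"

    def test_constant_is_none(self):
        out = dyn.classify_trend([2.0] * 6, [0.1] * 6)
        assert out["trend_class"] == "none"

    def test_line_plus_curvature_is_both(self):
        q = np.arange(1, 7)
        beta = 1.0 * q + 0.2 * (q - 3.5) ** 2
        out = dyn.classify_trend(beta, [1e-3] * 6)
        assert out["trend_class"] == "both"

    def test_fewer_than_four_points_flagged_none(self):
        out = dyn.classify_trend([1, 2, np.nan, np.nan, np.nan, 6], [0.1] * 6)
        assert out["trend_class"] == "none" and out["flagged"]


class TestRegulonTrends:
    def _assignment(self, n=600, seed=0):
        cells = make_cell_table([("d0", "AT2", n)])
        _with_pseudotime(cells, np.random.default_rng(seed).uniform(0, 30, n))
        return cells, dyn.assign_quantiles(cells, q=6)

    def test_activity_equal_to_quantile_is_linear(self):
        cells, a = self._assignment()
        act = pd.DataFrame(
            [a.quantile.loc[cells.cells["cell_id"]].to_numpy(dtype=float)],
            index=["reg1"],
            columns=cells.cells["cell_id"],
        )
        out = dyn.regulon_trends(act, a)
        assert out["p_linear"].iloc[0] < 1e-10 and out["significant"].iloc[0]

    def test_peak_at_middle_has_negative_quadratic(self):
        cells, a = self._assignment()
        q = a.quantile.loc[cells.cells["cell_id"]].to_numpy(dtype=float)
        act = pd.DataFrame(
            [-((q - 3.5) ** 2) + np.random.default_rng(1).normal(0, 0.1, len(q))],
            index=["reg1"],
            columns=cells.cells["cell_id"],
        )
        out = dyn.regulon_trends(act, a)
        assert out["quadratic_coef"].iloc[0] < 0
        assert out["p_quadratic"].iloc[0] < 1e-6

    def test_null_regulons_false_positive_rate(self):
        cells, a = self._assignment(n=300)
        rng = np.random.default_rng(2)
        act = pd.DataFrame(
            rng.standard_normal((1000, 300)),
            index=[f"r{i}" for i in range(1000)],
            columns=cells.cells["cell_id"],
        )
        out = dyn.regulon_trends(act, a)
        assert out["significant"].mean() == pytest.approx(
            1 - 0.95**2, abs=0.035
        )  # two 5%-level tests per regulon

    def test_constant_activity_flagged(self):
        cells, a = self._assignment(n=100)
        act = pd.DataFrame(
            np.ones((1, 100)), index=["flat"], columns=cells.cells["cell_id"]
        )
        out = dyn.regulon_trends(act, a)
        assert out["flagged"].iloc[0] and out["p_linear"].iloc[0] == 1.0


class TestOverlapSummary:
    def test_disjoint_lists(self):
        out = dyn.overlap_summary({"a": ["g1"], "b": ["g2"]})
        row = out[(out["list_a"] == "a") & (out["list_b"] == "b")].iloc[0]
        assert row["n_overlap"] == 0

    def test_self_overlap_full(self):
        out = dyn.overlap_summary({"a": ["g1", "g2"]})
        assert out["n_overlap"].iloc[0] == 2

    def test_ten_of_494(self):
        dynamic_genes = [f"g{i}" for i in range(494)]
        gwas_genes = [f"g{i}" for i in range(10)] + [f"x{i}" for i in range(26)]
        out = dyn.overlap_summary({"dynamic": dynamic_genes, "gwas": gwas_genes})
        row = out[(out["list_a"] == "dynamic") & (out["list_b"] == "gwas")].iloc[0]
        assert row["n_overlap"] == 10
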