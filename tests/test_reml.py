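import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from microbiability import (SimConfig, build_A, build_design, fit_reml,
                            likelihood_ratio_test, simulate_pedigree,
                            simulate_phenotype, taxon_heritability_scan,
                            wald_interval, wald_pvalue)
from microbiability.kernels import Kernel
from microbiability.microbiome import AbundanceMatrix
from microbiability.reml import VarianceEstimate
from microbiability.simulate import simulate_otu_table


def _meta(n, rng, n_herds=6, n_parities=4):
    return pd.DataFrame({
        "herd": rng.integers(1, n_herds + 1, n),
        "parity": rng.integers(1, n_parities + 1, n),
        "dim": rng.integers(1, 351, n),
    })


def _brute_force_loglik(y, X, K, sg, se):
    """Independent textbook REML log-likelihood evaluation."""
    n = len(y)
    V = sg * K + se * np.eye(n)
    cf = linalg.cho_factor(V)
    ldV = 2 * np.sum(np.log(np.diag(cf[0])))
    Viy = linalg.cho_solve(cf, y)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    b = np.linalg.solve(XtViX, X.T @ Viy)
    yPy = y @ Viy - (X.T @ Viy) @ b
    return -0.5 * (ldV + np.linalg.slogdet(XtViX)[1] + yPy)


class TestDesign:
    def test_dummy_column_count(self, rng):
        md = pd.DataFrame({
            "herd": np.repeat(np.arange(1, 7), 8),
            "parity": np.tile(np.arange(1, 5), 12),
            "dim": rng.integers(1, 351, 48)})
        X, names = build_design(md)
        assert X.shape[1] == 1 + 5 + 3 + 2 == 11

    def test_wilmink_values(self, rng):
        md = _meta(40, rng)
        md.loc[0, "dim"] = 0  # hypothetical boundary: Wilmink term is e^0
        md.loc[1, "dim"] = 350
        md.loc[2, "dim"] = 100
        with pytest.warns(UserWarning, match="days-in-milk"):
            X, names = build_design(md)
        w = X[:, names.index("wilmink")]
        assert w[0] == pytest.approx(1.0)              # e^0
        assert w[1] == pytest.approx(np.exp(-22.75))   # e^(-0.065*350)
        assert w[2] == pytest.approx(np.exp(-6.5))

    def test_rank_deficiency_names_aliased_columns(self):
        md = pd.DataFrame({"herd": [1, 1, 2, 2], "parity": [1, 1, 2, 2],
                           "dim": [10, 20, 30, 40]})
        with pytest.raises(ValueError, match="aliased"):
            build_design(md)


class TestRemlOracles:
    def test_balanced_one_way_anova_closed_form(self, rng):
        """Block-of-ones kernel: REML equals the expected-mean-square
        ANOVA estimator on a balanced one-way design."""
        g, k = 30, 6  # groups, members each
        n = g * k
        sb, se = 2.5, 1.0
        group = np.repeat(np.arange(g), k)
        K = (group[:, None] == group[None, :]).astype(float)
        y = (np.sqrt(sb) * rng.standard_normal(g))[group] \
            + np.sqrt(se) * rng.standard_normal(n)
        X = np.ones((n, 1))
        means = y.reshape(g, k).mean(axis=1)
        msb = k * means.var(ddof=1)
        msw = (y.reshape(g, k).var(axis=1, ddof=1)).mean()
        fit = fit_reml(y, X, {"grp": K})
        assert fit.components["grp"] == pytest.approx((msb - msw) / k, rel=1e-5)
        assert fit.components["residual"] == pytest.approx(msw, rel=1e-5)

    def test_grid_search_oracle_small_n(self, rng):
        n = 40
        B = rng.standard_normal((n, 10))
        K = B @ B.T / 10
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.8 * rng.standard_normal(n)
        fit = fit_reml(y, X, {"K": K})
        grid = [(_brute_force_loglik(y, X, K, sg, se), sg, se)
                for sg in np.linspace(0.02, 5, 150)
                for se in np.linspace(0.02, 5, 150)]
        ll_grid = max(grid)[0]
        assert fit.loglik >= ll_grid - 1e-4
        assert fit.loglik == pytest.approx(
            _brute_force_loglik(y, X, K, fit.components["K"],
                                fit.components["residual"]), abs=1e-8)

    def test_ai_equals_eigen_single_kernel(self, rng):
        n = 60
        B = rng.standard_normal((n, 15))
        K = B @ B.T / 15
        X = np.ones((n, 1))
        y = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.standard_normal(n) \
            + rng.standard_normal(n)
        fe = fit_reml(y, X, {"K": K}, method="eigen")
        fa = fit_reml(y, X, {"K": K}, method="ai")
        assert fa.loglik == pytest.approx(fe.loglik, abs=1e-6)
        assert fa.components["K"] == pytest.approx(fe.components["K"], rel=1e-3)

    def test_null_truth_h2_near_zero(self, rng):
        ped = simulate_pedigree(SimConfig(n_founders=200, n_generations=2,
                                          n_sires=10, seed=21))
        cfg = SimConfig(n_founders=200, n_generations=2, n_sires=10,
                        true_h2=0.0, true_m2=0.0, seed=21)
        pheno, _ = simulate_phenotype(cfg, ped)
        A = build_A(ped, subset=pheno["animal"].tolist())
        X, _ = build_design(pheno)
        fit = fit_reml(pheno["ch4_g_day"].to_numpy(), X, {"A": A.values})
        assert fit.ratios["A"] < 0.15
        lo, hi = wald_interval(fit.ratios["A"], max(fit.ratio_se["A"], 1e-6))
        assert lo <= 0.0  # CI covers zero

    def test_joint_ratios_sum_to_one_with_residual(self, rng):
        n = 80
        B1 = rng.standard_normal((n, 20))
        B2 = rng.standard_normal((n, 20))
        K1, K2 = B1 @ B1.T / 20, B2 @ B2.T / 20
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = fit_reml(y, X, {"A": K1, "M": K2})
        resid_ratio = fit.components["residual"] / fit.sigma2_p
        assert fit.ratios["A"] + fit.ratios["M"] + resid_ratio \
            == pytest.approx(1.0, abs=1e-12)


class TestLrt:
    def _ve(self, ll, names):
        return VarianceEstimate({}, {}, {}, {}, ll, True, 1, "x", tuple(names))

    def test_identical_models_give_p_one(self):
        null = self._ve(-100.0, ["A"])
        full = self._ve(-100.0, ["A", "M"])
        res = likelihood_ratio_test(null, full)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_boundary_mixture_quantile(self):
        # statistic 2.706 is the 5% point of the 0.5*chi2_0 + 0.5*chi2_1 mix
        null = self._ve(-100.0, [])
        full = self._ve(-100.0 + 2.706 / 2, ["A"])
        res = likelihood_ratio_test(null, full)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_error(self):
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(self._ve(-1, ["A"]), self._ve(-1, ["M"]))

    def test_type_I_error_under_boundary_null(self, rng):
        """Null simulations reject at about the nominal 5% level."""
        n, reps = 50, 400
        B = rng.standard_normal((n, 12))
        K = B @ B.T / 12
        X = np.ones((n, 1))
        S, U = np.linalg.eigh(K)
        rej = 0
        for _ in range(reps):
            y = rng.standard_normal(n)  # no kernel variance: boundary null
            full = fit_reml(y, X, {"K": K})
            null = fit_reml(y, X, {})
            p = likelihood_ratio_test(null, full).p_value
            rej += p < 0.05
        rate = rej / reps
        assert 0.015 <= rate <= 0.09  # binomial tolerance around 5%


class TestWald:
    @pytest.mark.parametrize("est,se,lo,hi", [
        (0.25, 0.10, 0.05, 0.45),   # printed genus-level interval
        (0.22, 0.09, 0.04, 0.40),   # printed genus-level interval
    ])
    def test_reproduces_printed_intervals(self, est, se, lo, hi):
        a, b = wald_interval(est, se)
        assert round(a, 2) == lo
        assert round(b, 2) == hi

    def test_zero_estimate_p_one(self):
        assert wald_pvalue(0.0, 0.3) == pytest.approx(1.0)

    def test_bad_se_errors(self):
        with pytest.raises(ValueError):
            wald_interval(0.2, 0.0)
        with pytest.raises(ValueError):
            wald_pvalue(0.2, -1.0)


@pytest.fixture(scope="module")
def scan_setup():
    cfg = SimConfig(n_founders=300, n_generations=2, n_sires=12,
                    n_bact_otus=50, n_arch_otus=10,
                    frac_heritable_otus=1.0, otu_h2=0.25,
                    frac_low_depth_samples=0.0, seed=31)
    ped = simulate_pedigree(cfg)
    F = build_A(ped).values.diagonal() - 1.0
    table = simulate_otu_table(cfg, ped, inbreeding=F)
    pheno, _ = simulate_phenotype(cfg, ped, table, inbreeding=F)
    A = build_A(ped, subset=pheno["animal"].tolist())
    from microbiability.microbiome import (filter_samples, filter_otus,
                                           to_relative_abundance,
                                           log_transform)
    t = filter_otus(filter_samples(table))
    logx = log_transform(to_relative_abundance(t))
    return cfg, pheno, A, logx


class TestHeritabilityScan:

    def test_recovers_taxon_heritability_on_average(self, scan_setup):
        cfg, pheno, A, logx = scan_setup
        scan = taxon_heritability_scan(logx, pheno, A)
        assert scan["converged"].all()
        # every simulated taxon is heritable at otu_h2 = 0.25
        assert scan["h2"].mean() == pytest.approx(0.25, abs=0.08)

    def test_identical_taxa_get_identical_estimates(self, scan_setup):
        cfg, pheno, A, logx = scan_setup
        dup = AbundanceMatrix(
            np.column_stack([logx.values[:, 0], logx.values[:, 0]]),
            logx.sample_ids, ["copy1", "copy2"])
        scan = taxon_heritability_scan(dup, pheno, A)
        assert scan.loc[0, "h2"] == scan.loc[1, "h2"]
        assert scan.loc[0, "p"] == scan.loc[1, "p"]

    def test_null_taxa_center_near_zero(self):
        cfg = SimConfig(n_founders=200, n_generations=2, n_sires=10,
                        n_bact_otus=40, n_arch_otus=10,
                        frac_heritable_otus=0.0, frac_low_depth_samples=0.0,
                        seed=41)
        ped = simulate_pedigree(cfg)
        F = build_A(ped).values.diagonal() - 1.0
        table = simulate_otu_table(cfg, ped, inbreeding=F)
        pheno, _ = simulate_phenotype(cfg, ped, table, inbreeding=F)
        A = build_A(ped, subset=pheno["animal"].tolist())
        from microbiability.microbiome import (filter_samples, filter_otus,
                                               to_relative_abundance,
                                               log_transform)
        t = filter_otus(filter_samples(table))
        logx = log_transform(to_relative_abundance(t))
        scan = taxon_heritability_scan(logx, pheno, A)
        assert scan["h2"].mean() < 0.12
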