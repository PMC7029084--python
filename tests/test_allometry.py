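"""OLS/PGLS fits and the type II conjunction rule."""

import numpy as np
import pytest

from lhinvar.allometry import evaluate_type2, ols_fit, pgls_fit
from lhinvar.phylo import bm_covariance, read_newick
from lhinvar.synthetic_data import TraitSpec, simulate_trait, simulate_yule_tree
from lhinvar.trait_io import InsufficientSample


class TestOLS:
    def test_hand_computed_normal_equations(self):
        fit = ols_fit([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1 / 6)
        assert fit.r2 == pytest.approx(27 / 28)

    def test_noiseless_line_recovered(self, rng):
        x = rng.normal(0, 1, 20)
        fit = ols_fit(x, 0.25 * x + 2)
        assert fit.slope == pytest.approx(0.25, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.3 * x + rng.normal(0, 0.5, 50)
        fit = ols_fit(x, y)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                       abs=1e-12)

    def test_p_ci_duality(self, rng):
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 25)
            y = 0.1 * x + r.normal(0, 1, 25)
            fit = ols_fit(x, y)
            contains_zero = fit.slope_ci[0] <= 0 <= fit.slope_ci[1]
            assert contains_zero == (fit.p_slope >= 0.05)

    def test_constant_x_and_small_n_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(InsufficientSample):
            ols_fit([1, 2], [1, 2])


class TestPGLS:
    def test_star_tree_uniform_weights_equals_ols(self, rng):
        cov = bm_covariance(read_newick(
            data="(" + ",".join(f"S{i}:1" for i in range(12)) + ");"))
        x = rng.normal(0, 1, 12)
        y = 1 + 0.5 * x + rng.normal(0, .2, 12)
        g = pgls_fit(x, y, cov, weights_mode="uniform", lam=1.0)
        o = ols_fit(x, y)
        assert g.slope == pytest.approx(o.slope, abs=1e-8)
        assert g.intercept == pytest.approx(o.intercept, abs=1e-8)

    def test_lambda_zero_uniform_equals_ols(self, rng):
        t = simulate_yule_tree(30, seed=3)
        cov = bm_covariance(t)
        x = rng.normal(0, 1, 30)
        y = 0.4 * x + rng.normal(0, .3, 30)
        g = pgls_fit(x, y, cov, weights_mode="uniform", lam=0.0)
        o = ols_fit(x, y)
        assert g.slope == pytest.approx(o.slope, abs=1e-8)
        assert g.intercept == pytest.approx(o.intercept, abs=1e-8)

    def test_three_taxon_gls_mean_hand_oracle(self):
        cov = bm_covariance(read_newick(data="((A:1,B:1):1,C:2);"))
        y = np.array([2.0, 4.0, 3.0])[[cov.taxa.index(s) for s in "ABC"]]
        fit = pgls_fit(None, y, cov, weights_mode="depth", lam=1.0)
        assert fit.intercept == pytest.approx(3.0, abs=1e-12)

    def test_profiled_lambda_beats_endpoints(self, rng):
        t = simulate_yule_tree(60, seed=8)
        m = rng.normal(1, .8, 60)
        vals = simulate_trait(
            t, TraitSpec("a", "allometric", b=0.3, sigma=0.1, lam=0.7),
            m, rng)
        cov = bm_covariance(t)
        from lhinvar.allometry import _profile_loglik
        X = np.column_stack([np.ones(60), m])
        fit = pgls_fit(m, np.log10(vals), cov)
        for l in (0.0, 1.0):
            assert fit.loglik >= _profile_loglik(
                l, X, np.log10(vals), cov, False, False) - 1e-9

    def test_fixed_lambda_skips_estimation(self, rng):
        t = simulate_yule_tree(20, seed=1)
        cov = bm_covariance(t)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, .1, 20)
        fit = pgls_fit(x, y, cov, lam=0.5)
        assert fit.lam == 0.5

    def test_size_mismatch_rejected(self, rng):
        cov = bm_covariance(simulate_yule_tree(10, seed=0))
        with pytest.raises(ValueError):
            pgls_fit(np.ones(5), np.ones(5), cov)


class TestType2Rule:
    def make(self, r2, p_ols, p_pgls):
        ols = ols_fit([0, 1, 2, 3], [0, 1, 2, 3.1])
        ols = type(ols)(**{**ols.__dict__, "r2": r2, "p_slope": p_ols,
                           "adj_r2": min(r2, ols.adj_r2)})
        pgls = None
        if p_pgls is not None:
            pgls = pgls_fit(
                np.arange(4.0),
                np.array([0, 1, 2, 3.1]),
                bm_covariance(read_newick(data="((A:1,B:1):1,(C:1,D:1):1);")),
                lam=0.0)
            pgls = type(pgls)(**{**pgls.__dict__, "p_slope": p_pgls})
        return ols, pgls

    @pytest.mark.parametrize("r2,p_ols,p_pgls,expect", [
        (0.01, 0.97, 0.92, True),    # all three point to invariance
        (0.18, 0.001, 0.001, False),  # clear allometry
        (0.04, 0.03, 0.50, False),   # conjunction: one significant slope
        (0.06, 0.50, 0.50, False),   # R2 above threshold
    ])
    def test_conjunction(self, r2, p_ols, p_pgls, expect):
        ols, pgls = self.make(r2, p_ols, p_pgls)
        v = evaluate_type2(ols, pgls)
        assert v.verdict_type2 is expect

    def test_missing_pgls_blocks_unless_degraded(self):
        ols, _ = self.make(0.01, 0.9, None)
        assert evaluate_type2(ols, None).verdict_type2 is None
        v = evaluate_type2(ols, None, degraded_ok=True)
        assert v.degraded and v.verdict_type2 is True
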