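"""OLS/PGLS/RegOU fitting against independent oracles, plus ANCOVA."""

import numpy as np
import pytest
import statsmodels.api as sm

import phylogls as pg
from conftest import gls_oracle, pic_slope, regression_dataset
from phylogls.data_io import AlignedDataset
from phylogls.gls import AncovaDesignError, FitError, ancova_fit
from phylogls.phylo_core import TipCovariance
from phylogls.synthetic_data import pure_birth_tree, simulate_bm_trait


@pytest.fixture
def four_tip_data():
    tree = pg.parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
    x = np.array([1.0, 2.0, 4.0, 3.0])
    y = np.array([2.0, 3.0, 9.0, 5.0])
    return tree, regression_dataset(tree, x, y)


class TestGLSCore:
    def test_matches_explicit_inversion_oracle(self, four_tip_data):
        _, ds = four_tip_data
        fit = pg.fit_gls(ds)
        beta, s2, lnl = gls_oracle(ds.y, ds.X, ds.V.matrix)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-12)
        assert fit.sigma2_hat == pytest.approx(s2, rel=1e-12)
        assert fit.lnL_ML == pytest.approx(lnl, rel=1e-12)

    def test_ols_matches_statsmodels(self, four_tip_data):
        _, ds = four_tip_data
        fit = pg.fit_ols(ds)
        ref = sm.OLS(ds.y, ds.X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        assert fit.lnL_ML == pytest.approx(ref.llf, rel=1e-10)
        assert fit.p_regression == pytest.approx(ref.pvalues[1], rel=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)

    def test_pgls_matches_statsmodels_gls(self, four_tip_data):
        _, ds = four_tip_data
        fit = pg.fit_gls(ds)
        ref = sm.GLS(ds.y, ds.X, sigma=ds.V.matrix).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        assert fit.lnL_ML == pytest.approx(ref.llf, rel=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)

    def test_star_tree_equivalence_bit_for_bit(self, four_tip_data):
        _, ds = four_tip_data
        eye = TipCovariance(np.eye(ds.n), list(ds.tips), np.ones(ds.n))
        a = pg.fit_gls(ds, V=eye, model="OLS")
        b = pg.fit_ols(ds)
        assert (a.beta == b.beta).all()
        assert a.lnL_ML == b.lnL_ML
        assert a.r2 == b.r2
        assert (a.residuals == b.residuals).all()

    def test_collinear_response_gives_perfect_fit(self, balanced8):
        x = np.arange(8.0)
        ds = regression_dataset(pg.balanced_tree(8), x, 2.0 + 3.0 * x)
        fit = pg.fit_ols(ds)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_regression < 1e-12

    def test_needs_more_rows_than_columns(self):
        tree = pg.star_tree(["a", "b", "c"])
        ds = regression_dataset(tree, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        ds.X = np.column_stack([ds.X, ds.X[:, 1] ** 2])
        with pytest.raises(FitError):
            pg.fit_ols(ds)

    def test_affine_equivariance_of_slope(self, four_tip_data):
        _, ds = four_tip_data
        fit1 = pg.fit_gls(ds)
        c = 3.7
        ds2 = AlignedDataset(
            y=ds.y,
            X=np.column_stack([ds.X[:, 0], c * ds.X[:, 1]]),
            V=ds.V,
            tips=list(ds.tips),
            var_names=ds.var_names,
        )
        fit2 = pg.fit_gls(ds2)
        assert fit2.slope == pytest.approx(fit1.slope / c, rel=1e-10)
        assert fit2.p_regression == pytest.approx(fit1.p_regression, rel=1e-10)

    def test_tip_order_invariance(self):
        tree = pure_birth_tree(15, seed=1)
        x = simulate_bm_trait(tree, 1.0, seed=2)[0]
        y = 1.0 - 0.8 * x + simulate_bm_trait(tree, 0.3, seed=3)[0]
        ds = regression_dataset(tree, x, y)
        fit1 = pg.fit_gls(ds)
        perm = np.random.default_rng(4).permutation(15)
        ds2 = AlignedDataset(
            y=ds.y[perm],
            X=ds.X[perm],
            V=ds.V.reorder([ds.tips[i] for i in perm]),
            tips=[ds.tips[i] for i in perm],
            var_names=ds.var_names,
        )
        fit2 = pg.fit_gls(ds2)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-10)
        assert fit2.lnL_ML == pytest.approx(fit1.lnL_ML, rel=1e-10)
        assert fit2.r2 == pytest.approx(fit1.r2, rel=1e-10)


class TestContrastsEquivalence:
    def test_pgls_slope_equals_pic_through_origin_slope(self):
        rng = np.random.default_rng(10)
        for seed in range(50):
            n = int(rng.integers(5, 25))
            tree = pure_birth_tree(n, seed=seed)
            x = simulate_bm_trait(tree, 1.0, seed=1000 + seed)[0]
            y = simulate_bm_trait(tree, 1.0, seed=2000 + seed)[0]
            ds = regression_dataset(tree, x, y)
            labels = ds.tips
            expected = pic_slope(
                tree, dict(zip(labels, x)), dict(zip(labels, y))
            )
            assert pg.fit_gls(ds).slope == pytest.approx(expected, abs=1e-8)


class TestRegOU:
    def test_d_zero_forced_reproduces_ols(self, four_tip_data):
        tree, ds = four_tip_data
        fit0 = pg.fit_regou(ds, tree=tree, d_fixed=0.0)
        ols = pg.fit_ols(ds)
        np.testing.assert_allclose(fit0.beta, ols.beta, atol=1e-8)
        assert fit0.lnL_ML == pytest.approx(ols.lnL_ML, abs=1e-8)

    def test_iid_data_drives_d_to_zero(self):
        cfg = pg.SimConfig(
            tree_spec="balanced", n_tips=32, residual_d=0.0, residual_sd=1.0,
            seed=21, n_reps=20,
        )
        d_hats = [
            pg.fit_regou(s.dataset, tree=s.tree).d_hat
            for s in pg.simulate_regression_dataset(cfg)
        ]
        assert np.median(d_hats) < 0.2

    def test_nests_pgls_at_d_one(self):
        # PGLS is the d = 1 member of the OU family, so the profiled fit can
        # never do worse than it on the criterion it optimizes: the ML-profiled
        # fit dominates on the ML scale, the REML-profiled fit on the REML scale
        cfg = pg.SimConfig(
            tree_spec="balanced", n_tips=32, residual_d=1.0, seed=22, n_reps=10
        )
        for s in pg.simulate_regression_dataset(cfg):
            pgls = pg.fit_gls(s.dataset)
            ml_fit = pg.fit_regou(s.dataset, tree=s.tree, reml=False)
            assert ml_fit.lnL_ML >= pgls.lnL_ML - 1e-6
            reml_fit = pg.fit_regou(s.dataset, tree=s.tree)
            at_one = pg.fit_regou(s.dataset, tree=s.tree, d_fixed=1.0)
            assert reml_fit.lnL_REML >= at_one.lnL_REML - 1e-6

    def test_reml_profile_matches_fixed_d_evaluation(self, four_tip_data):
        tree, ds = four_tip_data
        free = pg.fit_regou(ds, tree=tree)
        pinned = pg.fit_regou(ds, tree=tree, d_fixed=free.d_hat)
        assert pinned.lnL_REML == pytest.approx(free.lnL_REML, abs=1e-9)
        # no interior d beats the optimum on a fine grid
        grid = np.linspace(0, 5, 101)
        vals = [pg.fit_regou(ds, tree=tree, d_fixed=d).lnL_REML for d in grid]
        assert free.lnL_REML >= max(vals) - 1e-6

    def test_boundary_flagging(self, four_tip_data):
        tree, ds = four_tip_data
        fit = pg.fit_regou(ds, tree=tree, d_fixed=0.0)
        assert fit.d_boundary

    def test_lnl_comparable_with_ols_at_forced_zero(self):
        cfg = pg.SimConfig(n_tips=16, seed=23)
        s = pg.simulate_regression_dataset(cfg)[0]
        forced = pg.fit_regou(s.dataset, tree=s.tree, d_fixed=0.0)
        assert forced.lnL_ML == pytest.approx(pg.fit_ols(s.dataset).lnL_ML, abs=1e-10)


class TestAncova:
    @staticmethod
    def make_group_dataset(seed, offset, n=32, balanced_groups=True):
        tree = pg.balanced_tree(n)
        x = simulate_bm_trait(tree, 1.0, seed=seed)[0]
        eps = simulate_bm_trait(tree, 0.25, seed=seed + 5000)[0]
        if balanced_groups:
            group = np.array(["low", "high"] * (n // 2))
        else:
            group = np.array(["low"] * (n - 2) + ["high"] * 2)
        y = 1.0 + 0.5 * x + offset * (group == "high") + eps
        V = pg.bm_covariance(tree)
        return AlignedDataset(
            y=y,
            X=np.column_stack([np.ones(n), x]),
            V=V,
            tips=list(V.tip_order),
            var_names=["intercept", "x"],
            group=group,
        )

    def test_offset_recovered_within_ci(self):
        true_offset = 1.5
        hits = 0
        n_reps = 50
        for seed in range(n_reps):
            ds = self.make_group_dataset(seed, true_offset)
            fit, report = ancova_fit(ds)
            i = fit.coef_names.index("group[low]") if "group[low]" in fit.coef_names else 2
            # group indicator codes the second sorted label; offset sign follows
            est, se = fit.beta[2], fit.se[2]
            lo, hi = est - 2.01 * se, est + 2.01 * se
            hits += lo <= -true_offset <= hi or lo <= true_offset <= hi
        assert hits >= 0.9 * n_reps

    def test_imbalance_warning_below_five(self):
        ds = self.make_group_dataset(1, 1.0, balanced_groups=False)
        fit, report = ancova_fit(ds)
        assert report.imbalanced
        assert report.counts == {"low": 30, "high": 2}

    def test_refuses_single_member_group(self):
        ds = self.make_group_dataset(1, 1.0)
        ds.group = np.array(["low"] * 31 + ["high"])
        with pytest.raises(AncovaDesignError) as exc:
            ancova_fit(ds)
        assert exc.value.report.counts == {"high": 1, "low": 31}

    def test_interaction_adds_column(self):
        ds = self.make_group_dataset(2, 1.0)
        fit, _ = ancova_fit(ds, interaction=True)
        assert fit.p == 4

    def test_two_groups_required(self):
        ds = self.make_group_dataset(3, 1.0)
        ds.group = np.array((["a", "b", "c"] * 11)[:32])
        with pytest.raises(AncovaDesignError):
            ancova_fit(ds)
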