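"""Phylogenetic mixed model: transforms, Gibbs sampler calibration,
parameter recovery, pooling and variance-explained summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uvplume
from uvplume import (
    ChainSettings,
    PMMPrior,
    PosteriorDraws,
    VarPrior,
    estimate_H2,
    fit_pmm_binary,
    fit_pmm_gaussian,
    make_comparative_dataset,
    pool_over_trees,
    prepare_response,
    r2_marginal_conditional,
    summarize,
)
from uvplume.errors import SeparationWarning, SpecError, TransformError

TIGHT_ZERO = VarPrior(1e-10, 1e8)  # pins a variance component at ~0


def make_draws(beta, sa2, se2, names=("x0",), tree=0):
    df = pd.DataFrame(np.atleast_2d(beta), columns=[f"beta_{n}" for n in names])
    df["sigma2_a"] = sa2
    df["sigma2_e"] = se2
    df["tree"] = tree
    return PosteriorDraws(df=df, beta_names=tuple(names))


class TestPrepareResponse:
    def _table(self):
        return pd.DataFrame({
            "species": ["a", "b", "c", "d"],
            "sex": ["M", "F", "M", "F"],
            "view": ["back", "back", "belly", "belly"],
            "mean_u": [0.01, 0.1, 1.0, 0.1],
            "uv_plus_present_5": [0, 1, 1, 0],
            "uvb": [1.0, 2.0, 3.0, 4.0],
        })

    def test_continuous_response_log10_then_standardised(self):
        y, X, species = prepare_response(self._table(), "mean_u", ["uvb"])
        logs = np.array([-2.0, -1.0, 0.0, -1.0])
        np.testing.assert_allclose(y, (logs - logs.mean()) / logs.std())
        assert abs(y.mean()) < 1e-12 and abs(y.std() - 1) < 1e-12

    def test_binary_response_passes_through(self):
        y, X, _ = prepare_response(self._table(), "uv_plus_present_5", ["sex", "view"])
        np.testing.assert_array_equal(y, [0, 1, 1, 0])
        assert {"intercept", "sex_M", "view_back"} == set(X.columns)

    def test_predictors_standardised(self):
        _, X, _ = prepare_response(self._table(), "mean_u", ["uvb"])
        assert X["uvb"].mean() == pytest.approx(0, abs=1e-12)
        assert X["uvb"].std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_nonpositive_values_raise_with_rows(self):
        table = self._table()
        table.loc[2, "mean_u"] = 0.0
        with pytest.raises(TransformError) as exc:
            prepare_response(table, "mean_u", [])
        assert exc.value.rows == [2]


class TestChainSettings:
    def test_draw_count(self):
        assert ChainSettings(11000, 25, 1000).n_draws == 400

    def test_validation(self):
        with pytest.raises(ValueError):
            ChainSettings(100, 25, 200)
        with pytest.raises(ValueError):
            VarPrior(V=-1.0)


class TestGibbsCalibration:
    def test_matches_closed_form_regression_posterior(self):
        """With A = I and the phylogenetic variance pinned at zero the
        sampler must reproduce the conjugate Bayesian linear regression
        posterior (multivariate t marginals for beta)."""
        rng = np.random.default_rng(42)
        n, p = 20, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, -0.5]) + rng.normal(0, 0.7, n)
        prior = PMMPrior(residual=VarPrior(1.0, 0.002), phylo=TIGHT_ZERO)
        draws = fit_pmm_gaussian(
            y, X, np.eye(n), prior=prior,
            chain=ChainSettings(iterations=11000, thin=1, burn_in=1000, seed=3),
        )
        assert len(draws) == 10000
        nu, V = 0.002, 1.0
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ bhat) ** 2).sum())
        df = nu + n - p
        s2 = (nu * V + rss) / df
        Vb = s2 * np.linalg.inv(X.T @ X)
        for j in range(p):
            ks = stats.kstest(
                draws.beta[:, j],
                lambda q, j=j: stats.t.cdf(q, df, loc=bhat[j], scale=np.sqrt(Vb[j, j])),
            )
            assert ks.statistic < 0.05

    def test_all_draws_have_positive_variances(self):
        ds = make_comparative_dataset(30, sigma2_a=0.5, sigma2_e=0.5, seed=5,
                                      sexes=("M",), views=("back",))
        draws = fit_pmm_gaussian(
            ds.traits["response"].to_numpy(), np.ones((30, 1)), ds.A,
            chain=ChainSettings(iterations=2000, thin=5, burn_in=200, seed=1),
        )
        assert (draws.sigma2_a > 0).all() and (draws.sigma2_e > 0).all()
        assert len(draws) == (2000 - 200) // 5


class TestGaussianRecovery:
    def test_fixed_effects_recovered_within_credible_intervals(self):
        """beta = (1, -0.5) at n=200 species, H2=0.5: the 95% CI should
        cover the truth in nearly all replicate fits."""
        beta_true = np.array([1.0, -0.5])
        covered = 0
        reps = 10
        for rep in range(reps):
            ds = make_comparative_dataset(
                200, beta=beta_true, sigma2_a=0.5, sigma2_e=0.5, seed=300 + rep,
                sexes=("M",), views=("back",),
            )
            X = np.column_stack([
                np.ones(200),
                ds.traits["uvb"].to_numpy(),
                ds.traits["temperature"].to_numpy(),
            ])
            draws = fit_pmm_gaussian(
                ds.traits["response"].to_numpy(), X, ds.A,
                chain=ChainSettings(seed=rep),
                feature_names=["intercept", "uvb", "temperature"],
            )
            lo = np.quantile(draws.beta[:, 1:], 0.025, axis=0)
            hi = np.quantile(draws.beta[:, 1:], 0.975, axis=0)
            covered += bool(np.all((lo <= beta_true) & (beta_true <= hi)))
        assert covered >= int(0.9 * reps)


class TestBinaryModel:
    def test_recovers_probit_slope(self):
        covered = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n = 300
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = (X @ np.array([0.2, 1.0]) + rng.normal(size=n) > 0).astype(float)
            prior = PMMPrior(residual=VarPrior(1.0, fix=True), phylo=TIGHT_ZERO)
            draws = fit_pmm_binary(
                y, X, np.eye(n), prior=prior,
                chain=ChainSettings(iterations=6000, thin=5, burn_in=1000, seed=rep),
            )
            lo, hi = np.quantile(draws.beta[:, 1], [0.025, 0.975])
            covered += bool(lo <= 1.0 <= hi)
        assert covered >= 4

    def test_matches_independent_probit_augmentation_oracle(self):
        """A = I, phylo variance pinned: agrees with a standalone
        Albert-Chib probit Gibbs sampler written independently here."""
        rng = np.random.default_rng(7)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (X @ np.array([0.3, 0.8]) + rng.normal(size=n) > 0).astype(float)
        prior = PMMPrior(residual=VarPrior(1.0, fix=True), phylo=TIGHT_ZERO)
        draws = fit_pmm_binary(
            y, X, np.eye(n), prior=prior,
            chain=ChainSettings(iterations=8000, thin=2, burn_in=1000, seed=1),
        )

        # independent oracle: textbook Albert-Chib with flat beta prior
        rng_o = np.random.default_rng(99)
        XtXinv = np.linalg.inv(X.T @ X)
        chol = np.linalg.cholesky(XtXinv)
        beta = np.zeros(2)
        keep = []
        for it in range(8000):
            mu = X @ beta
            u = rng_o.uniform(size=n)
            p0 = np.clip(stats.norm.cdf(-mu), 1e-12, 1 - 1e-12)
            arg = np.where(y > 0, p0 + u * (1 - p0), u * p0)
            z = mu + stats.norm.ppf(np.clip(arg, 1e-12, 1 - 1e-12))
            bhat = XtXinv @ (X.T @ z)
            beta = bhat + chol @ rng_o.standard_normal(2)
            if it >= 1000:
                keep.append(beta.copy())
        oracle = np.array(keep)
        for j in range(2):
            assert abs(np.median(draws.beta[:, j]) - np.median(oracle[:, j])) < 0.1

    def test_constant_response_flags_separation(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.warns(SeparationWarning):
            fit_pmm_binary(
                np.ones(20), X, np.eye(20),
                chain=ChainSettings(iterations=200, thin=10, burn_in=50, seed=0),
            )


class TestHeritability:
    def test_equal_variance_draws_give_exact_half(self):
        draws = make_draws(np.zeros((100, 1)), np.full(100, 0.7), np.full(100, 0.7))
        assert estimate_H2(draws).h2["median"] == 0.5

    def test_recovery_at_high_heritability(self):
        ds = make_comparative_dataset(200, sigma2_a=0.8, sigma2_e=0.2, seed=21)
        labels = {s: i for i, s in enumerate(ds.species)}
        sp_idx = np.array([labels[s] for s in ds.traits["species"]])
        draws = fit_pmm_gaussian(
            ds.traits["response"].to_numpy(), np.ones((len(ds.traits), 1)), ds.A,
            species_idx=sp_idx, chain=ChainSettings(seed=2),
        )
        assert abs(estimate_H2(draws).h2["median"] - 0.8) <= 0.1

    def test_star_tree_data_has_low_heritability(self):
        rng = np.random.default_rng(3)
        n_sp = 100
        y = rng.normal(size=n_sp * 4)  # iid: no between-species structure
        sp_idx = np.repeat(np.arange(n_sp), 4)
        draws = fit_pmm_gaussian(
            y, np.ones((n_sp * 4, 1)), np.eye(n_sp), species_idx=sp_idx,
            chain=ChainSettings(iterations=4000, thin=10, burn_in=500, seed=4),
        )
        assert estimate_H2(draws).h2["median"] < 0.2


class TestPooling:
    def test_pooling_identical_sets_preserves_summary(self):
        d = make_draws(np.random.default_rng(0).normal(size=(50, 1)), 1.0, 1.0)
        pooled = pool_over_trees([d, d])
        assert len(pooled) == 100
        pd.testing.assert_frame_equal(
            summarize(pooled).table, summarize(d).table
        )

    def test_pooled_count_is_sum(self):
        parts = [
            make_draws(np.zeros((k, 1)), 1.0, 1.0, tree=i)
            for i, k in enumerate((10, 20, 30))
        ]
        pooled = pool_over_trees(parts)
        assert len(pooled) == 60
        assert set(pooled.df["tree"]) == {0, 1, 2}

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        parts = [make_draws(rng.normal(size=(30, 1)), 1.0, 1.0, tree=i) for i in range(3)]
        a = summarize(pool_over_trees(parts)).table
        b = summarize(pool_over_trees(parts[::-1])).table
        pd.testing.assert_frame_equal(a, b)

    def test_pooled_ci_at_least_narrowest(self):
        rng = np.random.default_rng(2)
        parts = [
            make_draws(rng.normal(loc=m, size=(200, 1)), 1.0, 1.0, tree=i)
            for i, m in enumerate((-0.5, 0.5))
        ]
        def width(d):
            t = summarize(d).table
            return t.loc["beta_x0", "hi95"] - t.loc["beta_x0", "lo95"]
        assert width(pool_over_trees(parts)) >= min(width(p) for p in parts)

    def test_mismatched_parameters_rejected(self):
        a = make_draws(np.zeros((5, 1)), 1.0, 1.0, names=("x0",))
        b = make_draws(np.zeros((5, 1)), 1.0, 1.0, names=("other",))
        with pytest.raises(SpecError):
            pool_over_trees([a, b])


class TestR2:
    def test_zero_beta_gives_zero_marginal(self):
        draws = make_draws(np.zeros((50, 1)), 1.0, 1.0)
        X = np.random.default_rng(0).normal(size=(30, 1))
        s = r2_marginal_conditional(draws, X)
        assert s.r2_marginal["median"] == 0.0

    def test_zero_phylo_variance_equates_r2s(self):
        draws = make_draws(np.ones((50, 1)), 0.0, 1.0)
        X = np.random.default_rng(0).normal(size=(30, 1))
        s = r2_marginal_conditional(draws, X)
        np.testing.assert_allclose(s.r2_marginal["draws"], s.r2_conditional["draws"])

    def test_known_variance_partition_recovered(self):
        """var_f=1, sigma2_a=1, sigma2_e=2 -> R2m ~ 0.25, R2c ~ 0.5."""
        ds = make_comparative_dataset(
            300, beta=(1.0,), sigma2_a=1.0, sigma2_e=2.0, seed=17,
        )
        labels = {s: i for i, s in enumerate(ds.species)}
        sp_idx = np.array([labels[s] for s in ds.traits["species"]])
        X = np.column_stack([np.ones(len(ds.traits)), ds.traits["uvb"].to_numpy()])
        draws = fit_pmm_gaussian(
            ds.traits["response"].to_numpy(), X, ds.A, species_idx=sp_idx,
            chain=ChainSettings(seed=6), feature_names=["intercept", "uvb"],
        )
        s = r2_marginal_conditional(draws, X)
        assert s.r2_marginal["median"] == pytest.approx(0.25, abs=0.08)
        assert s.r2_conditional["median"] == pytest.approx(0.50, abs=0.12)
        assert s.r2_marginal["median"] <= s.r2_conditional["median"]
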