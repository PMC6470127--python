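import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from addgp.data import Covariate, LongitudinalDataset
from addgp.gp import AdditiveGP
from addgp.kernels import GramBuilder
from addgp.priors import PriorSpec

from conftest import small_model, toy_frame


def _random_instance(declarations, seed, n_subjects=3, n_visits=2):
    rng = np.random.default_rng(seed)
    df = toy_frame(n_subjects=n_subjects, n_visits=n_visits, seed=seed)
    ds = LongitudinalDataset.from_frame(df, declarations.values(), target="y", subject="id")
    std, _ = ds.standardise()
    model = small_model(declarations, "id", "age", "id*age", "diseaseAge")
    theta = []
    for name in model.param_names:
        if name.endswith("lengthscale"):
            theta.append(rng.uniform(0.3, 2.0))
        else:
            theta.append(rng.uniform(0.3, 4.0))
    return std, model, np.array(theta)


def _dense_logpdf(gp, theta):
    K = gp.builder.model_gram(gp.params_dict(theta), rows=gp.rows, cols=gp.rows, include_noise=False)
    K = K + theta[-1] * np.eye(len(gp.rows))
    return stats.multivariate_normal(mean=np.zeros(len(gp.rows)), cov=K, allow_singular=True).logpdf(gp.y)


class TestMarginalLikelihood:
    def test_univariate_closed_form(self, declarations):
        df = pd.DataFrame({"id": ["a"], "group": [1], "y": [0.0]})
        ds = LongitudinalDataset.from_frame(df, [declarations["group"]], target="y", subject="id")
        gp = AdditiveGP(small_model(declarations, "group"), ds)
        # one constant component sigma2=1 plus noise 1: y ~ N(0, 2)
        got = gp.log_marginal_likelihood(np.array([1.0, 1.0]))
        assert got == pytest.approx(-0.5 * math.log(4 * math.pi), abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_mvn_oracle(self, declarations, seed):
        std, model, theta = _random_instance(declarations, seed)
        gp = AdditiveGP(model, std)
        assert gp.log_marginal_likelihood(theta) == pytest.approx(_dense_logpdf(gp, theta), abs=1e-6)

    def test_zero_magnitude_term_changes_nothing(self, declarations):
        std, model, theta = _random_instance(declarations, 1)
        gp = AdditiveGP(model, std)
        base = gp.log_marginal_likelihood(theta)
        bigger = small_model(declarations, "id", "age", "id*age", "diseaseAge", "loc")
        gp2 = AdditiveGP(bigger, std)
        theta2 = gp2.params_vector({**gp.params_dict(theta), "loc.magnitude": 1e-300})
        assert gp2.log_marginal_likelihood(theta2) == pytest.approx(base, abs=1e-6)

    def test_rejects_nonpositive_params(self, declarations):
        std, model, theta = _random_instance(declarations, 2)
        gp = AdditiveGP(model, std)
        theta[0] = -1.0
        with pytest.raises(ValueError):
            gp.log_marginal_likelihood(theta)


class TestLogPosterior:
    def test_all_fixed_priors_reduce_to_likelihood(self, declarations):
        std, model, theta = _random_instance(declarations, 3)
        fixed = {name: PriorSpec("fixed") for name in model.param_names}
        gp = AdditiveGP(model, std, priors=fixed)
        assert gp.log_posterior(np.log(theta)) == pytest.approx(
            gp.log_marginal_likelihood(theta), abs=1e-9
        )

    def test_finite_at_prior_modes_and_rejections(self, declarations):
        std, model, _ = _random_instance(declarations, 4)
        gp = AdditiveGP(model, std)
        assert np.isfinite(gp.log_posterior(gp.initial_log_params()))
        assert gp.log_posterior(np.full(gp.n_params, 100.0)) == -math.inf

    def test_jacobian_via_central_differences(self, declarations):
        # d/dg log p(g) must match the symmetric finite difference
        std, model, theta = _random_instance(declarations, 5)
        gp = AdditiveGP(model, std)
        g = np.log(theta)
        h = 1e-5
        for k in range(len(g)):
            e = np.zeros_like(g)
            e[k] = h
            d_plus = gp.log_posterior(g + e)
            d_minus = gp.log_posterior(g - e)
            second = (d_plus - 2 * gp.log_posterior(g) + d_minus) / h**2
            # smoothness check: second difference is finite (no kinks)
            assert np.isfinite(second)
            grad = (d_plus - d_minus) / (2 * h)
            grad2 = (gp.log_posterior(g + 2 * e) - gp.log_posterior(g - 2 * e)) / (4 * h)
            assert grad == pytest.approx(grad2, rel=5e-3, abs=5e-4)


class TestPrediction:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_conditional_gaussian_oracle(self, declarations, seed):
        std, model, theta = _random_instance(declarations, seed, n_subjects=3, n_visits=3)
        train = np.array([0, 1, 3, 5, 7])
        test = np.array([2, 4, 6])
        gp = AdditiveGP(model, std, rows=train)
        mu, Sigma = gp.predict(theta, test)
        params = gp.params_dict(theta)
        builder = GramBuilder(model, std)
        Ktt = builder.model_gram(params, rows=train, cols=train, include_noise=False) + theta[-1] * np.eye(5)
        Kst = builder.model_gram(params, rows=test, cols=train, include_noise=False)
        Kss = builder.model_gram(params, rows=test, cols=test, include_noise=False)
        mu_o = Kst @ np.linalg.solve(Ktt, std.y[train])
        Sigma_o = Kss - Kst @ np.linalg.solve(Ktt, Kst.T)
        assert np.allclose(mu, mu_o, atol=1e-6)
        assert np.allclose(Sigma, Sigma_o, atol=1e-6)

    def test_interpolates_as_noise_vanishes(self, declarations):
        std, model, theta = _random_instance(declarations, 11)
        gp = AdditiveGP(model, std)
        theta = theta.copy()
        theta[-1] = 1e-10
        mu, _ = gp.predict(theta, gp.rows)
        assert np.allclose(mu, gp.y, atol=1e-3)

    def test_predictive_variance_below_prior_variance(self, declarations):
        std, model, theta = _random_instance(declarations, 12, n_subjects=4, n_visits=3)
        gp = AdditiveGP(model, std)
        _, var = gp.predict(theta, gp.rows, full_cov=False)
        prior_var = np.diag(gp.builder.model_gram(gp.params_dict(theta), include_noise=False))
        assert np.all(var <= prior_var + 1e-8)

    def test_components_sum_to_full_mean(self, declarations):
        std, model, theta = _random_instance(declarations, 13, n_subjects=4, n_visits=3)
        gp = AdditiveGP(model, std)
        test = np.arange(std.n_rows)
        mu_full, _ = gp.predict(theta, test)
        total = np.zeros_like(mu_full)
        for j in range(model.D):
            mu_j, _ = gp.predict_component(j, theta, test)
            total += mu_j
        assert np.allclose(total, mu_full, atol=1e-8)

    def test_masked_component_predicts_exact_zero(self, declarations):
        std, model, theta = _random_instance(declarations, 14)
        gp = AdditiveGP(model, std)
        j = [t.label for t in model.terms].index("diseaseAge")
        controls = np.flatnonzero(std.flag("diseaseAge") == 0)
        mu_j, _ = gp.predict_component(j, theta, controls)
        assert np.all(mu_j == 0.0)

    def test_single_component_model_equals_full_prediction(self, declarations):
        df = toy_frame(n_subjects=2, n_visits=3, seed=3)
        ds = LongitudinalDataset.from_frame(df, declarations.values(), target="y", subject="id")
        std, _ = ds.standardise()
        model = small_model(declarations, "age")
        gp = AdditiveGP(model, std)
        theta = np.array([1.0, 2.0, 0.5])
        test = np.arange(std.n_rows)
        mu, Sigma = gp.predict(theta, test)
        mu0, Sigma0 = gp.predict_component(0, theta, test)
        assert np.allclose(mu, mu0)
        assert np.allclose(Sigma, Sigma0)

    def test_component_index_out_of_range(self, declarations):
        std, model, theta = _random_instance(declarations, 15)
        gp = AdditiveGP(model, std)
        with pytest.raises(IndexError):
            gp.predict_component(model.D, theta, np.array([0]))


class TestMixture:
    def test_single_draw_reduces_to_plug_in(self, declarations):
        std, model, theta = _random_instance(declarations, 20)
        gp = AdditiveGP(model, std)
        test = np.arange(std.n_rows)
        pred = gp.predictive_mixture(theta[None, :], test)
        mu, var = gp.predict(theta, test, full_cov=False)
        assert np.allclose(pred.mean, mu)
        assert np.allclose(pred.var, var, atol=1e-10)

    def test_mixture_moments(self, declarations):
        std, model, theta = _random_instance(declarations, 21)
        gp = AdditiveGP(model, std)
        test = np.arange(std.n_rows)
        thetas = np.stack([theta, theta * 1.5, theta * 0.7])
        w = np.array([0.5, 0.3, 0.2])
        pred = gp.predictive_mixture(thetas, test, weights=w)
        mus = np.stack([gp.predict(t, test, full_cov=False)[0] for t in thetas])
        vars_ = np.stack([gp.predict(t, test, full_cov=False)[1] for t in thetas])
        assert np.allclose(pred.mean, w @ mus)
        # law of total variance: mixture variance >= average within variance
        assert np.all(pred.var >= (w @ vars_) - 1e-10)
        assert np.allclose(pred.var, w @ vars_ + w @ mus**2 - (w @ mus) ** 2, atol=1e-10)

    def test_cumulative_equals_full_mean(self, declarations):
        std, model, theta = _random_instance(declarations, 22)
        gp = AdditiveGP(model, std)
        pred = gp.predictive_mixture(np.stack([theta, theta * 1.2]), gp.rows)
        assert np.allclose(pred.cumulative_mean, pred.mean, atol=1e-8)

    def test_empty_mixture_fatal(self, declarations):
        std, model, _ = _random_instance(declarations, 23)
        gp = AdditiveGP(model, std)
        with pytest.raises(ValueError):
            gp.predictive_mixture(np.empty((0, gp.n_params)), gp.rows)


class TestExplainedVariance:
    def test_fractions_bounded_and_normalised(self, declarations):
        std, model, theta = _random_instance(declarations, 30)
        gp = AdditiveGP(model, std)
        ev = gp.explained_variance(np.stack([theta, theta * 1.3]))
        vals = np.array(list(ev.values()))
        assert np.all(vals >= 0)
        assert vals.sum() <= 1.0 + 1e-12

    def test_noise_free_strong_component_dominates(self, declarations):
        # target generated by a pure age effect with tiny noise
        rng = np.random.default_rng(0)
        age = np.tile(np.linspace(0, 36, 8), 3)
        df = pd.DataFrame({
            "id": np.repeat(["a", "b", "c"], 8), "age": age,
            "y": np.sin(age / 6.0) * 3.0 + 0.001 * rng.standard_normal(24),
        })
        covs = [Covariate("id", kind="categorical"), Covariate("age", kind="continuous")]
        ds = LongitudinalDataset.from_frame(df, covs, target="y", subject="id")
        std, _ = ds.standardise()
        model = small_model({c.name: c for c in covs}, "age")
        gp = AdditiveGP(model, std)
        theta = gp.params_vector({"age.lengthscale": 1.0, "age.magnitude": 1.0, "noise.variance": 1e-6})
        ev = gp.explained_variance(theta[None, :])
        assert ev["age"] == pytest.approx(1.0, abs=1e-3)


class TestBackTransform:
    def test_affine_closure(self, declarations):
        # predicting on the standardised scale and inverting must match the
        # prediction for an affinely transformed target directly
        df = toy_frame(n_subjects=3, n_visits=3, seed=7)
        model = small_model(declarations, "id", "age")
        df2 = df.assign(y=3.5 * df["y"] - 2.0)
        preds = []
        for frame in (df, df2):
            ds = LongitudinalDataset.from_frame(frame, declarations.values(), target="y", subject="id")
            std, record = ds.standardise()
            gp = AdditiveGP(model, std)
            theta = gp.params_vector({
                "id.magnitude": 1.0, "age.lengthscale": 1.0, "age.magnitude": 1.0,
                "noise.variance": 0.5,
            })
            mu, _ = gp.predict(theta, np.arange(std.n_rows))
            preds.append(record.inverse_target(mu))
        assert np.allclose(3.5 * preds[0] - 2.0, preds[1], atol=1e-8)

    def test_prediction_table_layout(self, declarations):
        std_df = toy_frame(n_subjects=2, n_visits=3, seed=9)
        ds = LongitudinalDataset.from_frame(std_df, declarations.values(), target="y", subject="id")
        std, record = ds.standardise()
        model = small_model(declarations, "id", "age")
        gp = AdditiveGP(model, std)
        theta = gp.params_vector({
            "id.magnitude": 1.0, "age.lengthscale": 1.0, "age.magnitude": 1.0, "noise.variance": 0.5,
        })
        table = gp.predictive_mixture(theta[None, :], gp.rows).to_table(record=record)
        assert set(table.columns) == {"row_id", "component", "mean", "sd", "cumulative_mean"}
        assert len(table) == 2 * std.n_rows
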