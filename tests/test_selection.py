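import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from addgp.data import Covariate, LongitudinalDataset
from addgp.gp import AdditiveGP
from addgp.inference import SamplerSettings, ccd_fit, run_mcmc
from addgp.kernels import GramBuilder
from addgp.selection import (
    SearchConfig,
    bootstrap_factor,
    candidate_model_space,
    exact_loo,
    extend_model,
    forward_search,
    psis_loo,
    rank_probabilities,
    scv,
)

from conftest import small_model, toy_frame


class TestBootstrapFactor:
    def test_identical_models_tie_at_half(self):
        lpd = np.array([-1.0, -2.0, -0.5])
        assert bootstrap_factor(lpd, lpd, n_boot=500, seed=0) == 0.5

    def test_dominating_model_wins_always(self):
        a = np.array([-1.0, -1.0, -1.0, -1.0])
        assert bootstrap_factor(a, a - 1.0, n_boot=500, seed=0) == 1.0

    def test_two_one_split_matches_beta_marginal(self):
        # differences (+1, +1, -1): the weighted mean is positive unless the
        # third Dirichlet weight exceeds 1/2; w3 ~ Beta(1, 2), so
        # P = 1 - (1 - 1/2)^2 = 0.75
        lpd_a = np.array([1.0, 1.0, 0.0])
        lpd_b = np.array([0.0, 0.0, 1.0])
        got = bootstrap_factor(lpd_a, lpd_b, n_boot=100_000, seed=1)
        assert got == pytest.approx(0.75, abs=0.01)

    def test_antisymmetry_with_shared_draws(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert bootstrap_factor(a, b, 2000, seed=5) + bootstrap_factor(b, a, 2000, seed=5) == pytest.approx(1.0)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            bootstrap_factor(np.zeros(3), np.zeros(4))


class TestRankProbabilities:
    def test_sum_to_one_and_two_model_consistency(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        probs = rank_probabilities(np.stack([a, b]), n_boot=20_000, seed=2)
        assert probs.sum() == pytest.approx(1.0)
        factor = bootstrap_factor(a, b, n_boot=20_000, seed=3)
        assert probs[0] == pytest.approx(factor, abs=0.02)

    def test_three_model_toy_against_independent_oracle(self):
        rng = np.random.default_rng(1)
        lpds = np.stack([
            rng.standard_normal(15) + 0.5,
            rng.standard_normal(15),
            rng.standard_normal(15) - 0.5,
        ])
        probs = rank_probabilities(lpds, n_boot=100_000, seed=4)
        # independent oracle: explicit Gamma(1) construction of the weights
        oracle_rng = np.random.default_rng(99)
        g = oracle_rng.gamma(1.0, size=(1_000_000, 15))
        w = g / g.sum(axis=1, keepdims=True)
        winners = np.argmax(w @ lpds.T, axis=1)
        oracle = np.bincount(winners, minlength=3) / len(winners)
        assert np.allclose(probs, oracle, atol=0.01)


class TestPsisLoo:
    def _small_fit(self, seed=0, n_subjects=3, n_visits=3):
        covs = [Covariate("id", kind="categorical"), Covariate("age", kind="continuous")]
        df = toy_frame(n_subjects=n_subjects, n_visits=n_visits, seed=seed)[["id", "age", "y"]]
        ds = LongitudinalDataset.from_frame(df, covs, target="y", subject="id")
        std, _ = ds.standardise()
        model = small_model({c.name: c for c in covs}, "id", "age")
        gp = AdditiveGP(model, std)
        return gp, std, model

    def test_point_posterior_reduces_to_plug_in(self):
        gp, _, _ = self._small_fit()
        theta = gp.params_vector({"id.magnitude": 1.0, "age.lengthscale": 1.0,
                                  "age.magnitude": 1.0, "noise.variance": 0.5})
        from addgp.inference import SampleSet

        draws = np.tile(np.log(theta), (2, 50, 1))
        res = psis_loo(gp, SampleSet(draws=draws, names=gp.names))
        assert np.allclose(res.lpd, gp.loo_conditional_loglik(theta), atol=1e-10)

    def test_close_to_exact_refit_loo(self, declarations):
        gp, std, model = self._small_fit(seed=2)
        settings = SamplerSettings(chains=2, iters=500, burn_in=200, thin=1)
        samples = run_mcmc(gp.log_posterior, gp.initial_log_params(), settings, seed=11)
        res = psis_loo(gp, samples)
        oracle = exact_loo(model, std, settings, seed=13)
        assert np.mean(np.abs(res.lpd - oracle)) < 0.1
        assert res.pareto_k.shape == res.lpd.shape

    def test_flagged_rows_exposed(self):
        gp, _, _ = self._small_fit()
        from addgp.selection import PointwiseDensities

        res = PointwiseDensities(lpd=np.zeros(3), pareto_k=np.array([0.1, 0.8, 0.2]))
        assert list(res.flagged) == [1]


class TestScv:
    def test_matches_dense_mixture_oracle(self):
        covs = [Covariate("id", kind="categorical")]
        df = pd.DataFrame({"id": list("aaabbb"), "y": [1.0, 1.2, 0.8, -1.0, -0.9, -1.3]})
        ds = LongitudinalDataset.from_frame(df, covs, target="y", subject="id")
        std, _ = ds.standardise()
        model = small_model({c.name: c for c in covs}, "id")
        res = scv(model, std)
        assert res.lpd.shape == (2,)
        # oracle: rebuild each fold's CCD and evaluate the joint block density
        # with dense conditional-Gaussian formulas
        from addgp.priors import assign_priors

        priors = assign_priors(model)
        for i, subject in enumerate(std.subjects):
            train, test = std.subject_partition(subject)
            sub = AdditiveGP(model, std, priors=priors, rows=train)
            design = ccd_fit(sub.log_posterior, sub.initial_log_params())
            parts = []
            builder = GramBuilder(model, std)
            for w, theta in zip(design.weights, design.thetas()):
                params = dict(zip(model.param_names, theta))
                Ktt = builder.model_gram(params, rows=train, cols=train, include_noise=False) + theta[-1] * np.eye(len(train))
                Kst = builder.model_gram(params, rows=test, cols=train, include_noise=False)
                Kss = builder.model_gram(params, rows=test, cols=test, include_noise=False) + theta[-1] * np.eye(len(test))
                mu = Kst @ np.linalg.solve(Ktt, std.y[train])
                cov = Kss - Kst @ np.linalg.solve(Ktt, Kst.T)
                parts.append(math.log(w) + multivariate_normal(mean=mu, cov=cov, allow_singular=True).logpdf(std.y[test]))
            assert res.lpd[i] == pytest.approx(logsumexp(parts), abs=1e-5)

    def test_masked_block_density_is_product_of_rows(self, declarations):
        # a component masked out at the held-out block leaves a diagonal
        # predictive covariance: joint density = sum of per-row densities
        df = toy_frame(n_subjects=4, n_visits=2, seed=1)
        ds = LongitudinalDataset.from_frame(df, declarations.values(), target="y", subject="id")
        std, _ = ds.standardise()
        model = small_model(declarations, "diseaseAge")
        control = [s for s in std.subjects if std.flag("diseaseAge")[std.subject_rows(s)].sum() == 0][0]
        train, test = std.subject_partition(control)
        gp = AdditiveGP(model, std, rows=train)
        theta = gp.params_vector({"diseaseAge.lengthscale": 1.0, "diseaseAge.magnitude": 4.0, "noise.variance": 2.0})
        joint = gp.log_predictive_density(theta, test)
        rows = sum(gp.log_predictive_density(theta, np.array([r])) for r in test)
        assert joint == pytest.approx(rows, abs=1e-8)

    def test_needs_two_subjects(self):
        covs = [Covariate("id", kind="categorical")]
        df = pd.DataFrame({"id": ["a", "a"], "y": [0.0, 1.0]})
        ds = LongitudinalDataset.from_frame(df, covs, target="y", subject="id")
        with pytest.raises(ValueError):
            scv(small_model({c.name: c for c in covs}, "id"), ds)


class TestSearchStructure:
    def test_candidate_space_has_32_members(self, declarations):
        df = toy_frame()
        ds = LongitudinalDataset.from_frame(df, [declarations[n] for n in
            ("id", "age", "diseaseAge", "group", "loc", "gender")], target="y", subject="id")
        config = SearchConfig(candidates=("age", "diseaseAge", "loc", "group", "gender"))
        models = candidate_model_space(ds, config)
        assert len(models) == 32
        assert len({m.formula for m in models}) == 32

    def test_extension_brings_allowed_interactions(self, declarations):
        df = toy_frame()
        ds = LongitudinalDataset.from_frame(df, declarations.values(), target="y", subject="id")
        base = small_model(declarations, "id")
        pairs = frozenset({frozenset(("id", "age")), frozenset(("loc", "age"))})
        extended = extend_model(base, "age", ds, pairs)
        assert extended.formula == "y ~ age + id*age + id"
        # diseaseAge never interacts
        ext2 = extend_model(extended, "diseaseAge", ds, pairs)
        assert ext2.covariates == frozenset({"id", "age", "diseaseAge"})
        assert all("diseaseAge" not in t.label or len(t.covariates) == 1 for t in ext2.terms)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            SearchConfig(loocvf_threshold=1.2)


def _search_setup(n_subjects=6, n_visits=5, noise=1.0, signal=True, seed=0):
    """Small dataset with a strong age effect (or pure noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        offset = rng.normal(0, 1.0)
        for v in range(n_visits):
            age = 36.0 * v / (n_visits - 1)
            mean = offset + (3.0 * np.sin(age / 8.0) if signal else 0.0)
            rows.append({"id": f"s{i}", "age": age, "y": mean + rng.normal(0, noise)})
    df = pd.DataFrame(rows)
    covs = [Covariate("id", kind="categorical"), Covariate("age", kind="continuous")]
    return LongitudinalDataset.from_frame(df, covs, target="y", subject="id")


FAST_SAMPLER = SamplerSettings(chains=2, iters=160, burn_in=80, thin=2)


class TestForwardSearch:
    def test_strong_signal_is_selected(self):
        ds = _search_setup(signal=True)
        cfg = SearchConfig(candidates=("age",), sampler=FAST_SAMPLER, seed=1)
        trace = forward_search(ds, cfg)
        assert "age" in trace.final_model.covariates
        assert trace.steps[0].accepted

    def test_pure_noise_keeps_base_model(self):
        ds = _search_setup(signal=False, seed=3)
        cfg = SearchConfig(candidates=("age",), sampler=FAST_SAMPLER, seed=2)
        trace = forward_search(ds, cfg)
        assert trace.final_model.covariates == frozenset({"id"})

    def test_deterministic_given_seed(self):
        ds = _search_setup(signal=True, n_subjects=4, n_visits=4)
        cfg = SearchConfig(candidates=("age",), sampler=FAST_SAMPLER, seed=5)
        t1 = forward_search(ds, cfg)
        t2 = forward_search(ds, cfg)
        assert t1.to_frame().equals(t2.to_frame())
        assert np.array_equal(t1.samples.draws, t2.samples.draws)
        assert t1.final_model == t2.final_model

    def test_accepted_steps_beat_threshold_in_trace(self):
        ds = _search_setup(signal=True, seed=4)
        cfg = SearchConfig(candidates=("age",), sampler=FAST_SAMPLER, seed=6)
        trace = forward_search(ds, cfg)
        for step in trace.steps:
            if step.accepted:
                assert step.factor > step.threshold

    def test_no_candidates_returns_base(self):
        ds = _search_setup()
        cfg = SearchConfig(candidates=(), sampler=FAST_SAMPLER, seed=0)
        trace = forward_search(ds, cfg)
        assert trace.final_model.covariates == frozenset({"id"})
        assert trace.steps == []

    def test_trace_report_round_trip(self):
        ds = _search_setup(signal=True, seed=8)
        cfg = SearchConfig(candidates=("age",), sampler=FAST_SAMPLER, seed=9)
        trace = forward_search(ds, cfg)
        frame = trace.to_frame()
        assert set(frame.columns) == {"step", "phase", "candidate", "rank_prob", "factor", "accepted"}
        text = trace.report()
        assert trace.final_model.formula in text
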