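"""Exact additive-GP likelihoods, posteriors and predictive decompositions.

Everything here works on a *standardised* dataset (zero-mean, unit-sd target
and continuous covariates); back-transformation to the original target scale
goes through the dataset's :class:`~addgp.data.StandardisationRecord`.

The evaluator is bound to one model, one dataset and one set of training
rows.  Parameters are handled in two representations: a natural-scale vector
aligned with ``model.param_names`` (kernel length-scales/magnitudes followed
by the noise variance), and its elementwise logarithm used by the samplers
(the log-posterior includes the exp-transform Jacobian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.linalg.lapack import dpotrf, dtrtrs

from .kernels import GramBuilder, ModelSpec, add_jitter_and_factor
from .priors import PriorSpec, assign_priors, log_prior, prior_mode

__all__ = ["AdditiveGP", "ComponentPrediction", "prior_mode_vector"]

_LOG2PI = math.log(2.0 * math.pi)
_LOG_BOUND = 30.0  # |log theta| beyond this is rejected outright


@dataclass
class ComponentPrediction:
    """Posterior-mixture predictions decomposed by additive component.

    All quantities are on the standardised target scale; per test row:
    component means/pointwise variances, their cumulative sum, the
    full-model predictive mean/variance, and the mixture-averaged noise
    variance.  The cumulative mean equals the full predictive mean by the
    linearity of the prediction equations.
    """

    labels: tuple[str, ...]
    component_means: np.ndarray  # (D, n*)
    component_vars: np.ndarray  # (D, n*)
    mean: np.ndarray  # (n*,)
    var: np.ndarray  # (n*,)
    noise_var: float

    @property
    def cumulative_mean(self) -> np.ndarray:
        return self.component_means.sum(axis=0)

    def to_table(self, record=None, row_ids=None):
        """Long-format table (row_id, component, mean, sd, cumulative_mean),
        back-transformed to the original target scale when a
        standardisation record is given."""
        import pandas as pd

        n = len(self.mean)
        rows = np.arange(n) if row_ids is None else np.asarray(row_ids)
        cmeans, cvars, cum = self.component_means, self.component_vars, self.cumulative_mean
        if record is not None:
            cmeans = record.inverse_component_mean(cmeans)
            cvars = record.inverse_variance(cvars)
            cum = record.inverse_target(cum)
        out = []
        for j, label in enumerate(self.labels):
            out.append(
                pd.DataFrame(
                    {
                        "row_id": rows,
                        "component": label,
                        "mean": cmeans[j],
                        "sd": np.sqrt(np.maximum(cvars[j], 0.0)),
                        "cumulative_mean": cum,
                    }
                )
            )
        return pd.concat(out, ignore_index=True)


def prior_mode_vector(priors: dict[str, PriorSpec], names) -> np.ndarray:
    """Log-scale prior modes in parameter order (sampler/optimiser inits)."""
    return np.array([prior_mode(priors[n], log_scale=True) for n in names])


class AdditiveGP:
    """Additive-GP evaluator for one model / dataset / training-row set.

    ``rows`` (default: all rows) selects the training block; prediction
    methods address *test* inputs by row indices into the same dataset,
    which covers in-sample decomposition and all cross-validation schemes.
    """

    def __init__(self, model: ModelSpec, dataset, priors: dict[str, PriorSpec] | None = None, rows=None):
        self.model = model
        self.ds = dataset
        self.builder = GramBuilder(model, dataset)
        self.rows = np.arange(dataset.n_rows) if rows is None else np.asarray(rows)
        self.y = dataset.y[self.rows]
        self.n = len(self.rows)
        self.names = model.param_names
        self.priors = priors if priors is not None else assign_priors(model)
        missing = set(self.names) - set(self.priors)
        if missing:
            raise KeyError(f"priors missing for parameters {sorted(missing)}")
        self._prior_list = [self.priors[n] for n in self.names]
        # parameter slots: per term (lengthscale index or None, magnitude index)
        self._slots: list[tuple[int | None, int]] = []
        pos = 0
        for term in model.terms:
            if term.continuous is not None:
                self._slots.append((pos, pos + 1))
                pos += 2
            else:
                self._slots.append((None, pos))
                pos += 1
        self._noise_idx = pos
        self.n_params = pos + 1
        # pre-sliced structure matrices for the training block
        ix = np.ix_(self.rows, self.rows)
        self._tbase = [self.builder._base[j][ix] for j in range(model.D)]
        self._tdist = [
            self.builder._dist[j][ix] if self.builder._dist[j] is not None else None
            for j in range(model.D)
        ]
        self._cache_key: list[tuple | None] = [None] * model.D
        self._cache_val: list[np.ndarray | None] = [None] * model.D
        self._prior_cache_x: np.ndarray | None = None
        self._prior_cache_terms: np.ndarray | None = None
        self._diag = np.diag_indices(self.n)

    # -- parameter plumbing ---------------------------------------------------

    def params_dict(self, theta) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(theta, dtype=float)))

    def params_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[n] for n in self.names], dtype=float)

    def initial_log_params(self) -> np.ndarray:
        return prior_mode_vector(self.priors, self.names)

    # -- likelihood and posterior ----------------------------------------------

    def _term_K(self, j: int, theta: np.ndarray) -> np.ndarray:
        ls_i, mag_i = self._slots[j]
        mag = theta[mag_i]
        key = (theta[ls_i] if ls_i is not None else None, mag)
        if self._cache_key[j] == key:
            return self._cache_val[j]
        term = self.model.terms[j]
        if ls_i is None:
            K = mag * self._tbase[j]
        else:
            ls = theta[ls_i]
            if term.cont_kind == "periodic":
                K = np.exp(-2.0 * np.sin(np.pi * self._tdist[j] / term.period) ** 2 / ls**2)
            else:
                K = np.exp(self._tdist[j] * (-0.5 / ls**2))
            K *= self._tbase[j]
            K *= mag
        self._cache_key[j] = key
        self._cache_val[j] = K
        return K

    def _K_y(self, theta: np.ndarray) -> np.ndarray:
        K = self._term_K(0, theta).copy()
        for j in range(1, self.model.D):
            K += self._term_K(j, theta)
        K[self._diag] += theta[self._noise_idx]
        return K

    def _lml(self, theta: np.ndarray) -> float:
        K = self._K_y(theta)
        # fast path: one shot of baseline jitter via raw LAPACK (the sampler's
        # hot loop); escalation only when that fails
        jitter = 1e-8 * float(np.trace(K)) / self.n
        K[self._diag] += jitter
        L, info = dpotrf(K, lower=1)
        if info != 0:
            K[self._diag] -= jitter
            L, _ = add_jitter_and_factor(K)
        alpha, _ = dtrtrs(L, self.y, lower=1)
        return float(-0.5 * alpha @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * self.n * _LOG2PI)

    def log_marginal_likelihood(self, theta) -> float:
        """log N(y; 0, sum_j K^(j) + sigma2_eps I) via Cholesky."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise ValueError("kernel parameters must be positive and finite")
        return self._lml(theta)

    def log_prior(self, theta) -> float:
        return float(sum(log_prior(v, s) for v, s in zip(theta, self._prior_list)))

    def _log_prior_jacobian(self, log_theta: np.ndarray, theta: np.ndarray) -> float:
        """Sum of per-coordinate prior log-densities plus exp Jacobians,
        recomputing only coordinates that changed since the last call (the
        slice sampler moves one coordinate at a time)."""
        if self._prior_cache_x is None:
            terms = np.array(
                [
                    0.0 if s.family == "fixed" else log_prior(v, s) + g
                    for v, g, s in zip(theta, log_theta, self._prior_list)
                ]
            )
        else:
            terms = self._prior_cache_terms.copy()
            for k in np.flatnonzero(log_theta != self._prior_cache_x):
                s = self._prior_list[k]
                terms[k] = 0.0 if s.family == "fixed" else log_prior(theta[k], s) + log_theta[k]
        self._prior_cache_x = log_theta.copy()
        self._prior_cache_terms = terms
        return float(terms.sum())

    def log_posterior(self, log_theta) -> float:
        """Unnormalised log posterior of the *log* parameters (marginal
        likelihood + priors + exp-transform Jacobian)."""
        log_theta = np.asarray(log_theta, dtype=float)
        if not np.all(np.isfinite(log_theta)) or np.any(np.abs(log_theta) > _LOG_BOUND):
            return -math.inf
        theta = np.exp(log_theta)
        lp = self._log_prior_jacobian(log_theta, theta)
        if not np.isfinite(lp):
            return -math.inf
        try:
            return lp + self._lml(theta)
        except np.linalg.LinAlgError:
            return -math.inf

    # -- prediction --------------------------------------------------------------

    def _chol_alpha(self, theta: np.ndarray):
        L, _ = add_jitter_and_factor(self._K_y(theta))
        alpha = cho_solve((L, True), self.y, check_finite=False)
        return L, alpha

    def predict(self, theta, test_rows, full_cov: bool = True):
        """Full-model predictive mean and covariance (noise-free f*) at the
        given dataset rows."""
        theta = np.asarray(theta, dtype=float)
        params = self.params_dict(theta)
        test_rows = np.asarray(test_rows)
        L, alpha = self._chol_alpha(theta)
        Kxs = self.builder.model_gram(params, rows=test_rows, cols=self.rows, include_noise=False)
        mu = Kxs @ alpha
        V = cho_solve((L, True), Kxs.T, check_finite=False)
        Kss = self.builder.model_gram(params, rows=test_rows, cols=test_rows, include_noise=False)
        if full_cov:
            return mu, Kss - Kxs @ V
        return mu, np.diag(Kss) - np.einsum("ij,ji->i", Kxs, V)

    def predict_component(self, j: int, theta, test_rows, full_cov: bool = True):
        """Predictive mean/covariance of component ``j`` (Gram replaced by
        the component's cross-covariances; weights K_y^{-1} y shared)."""
        if not 0 <= j < self.model.D:
            raise IndexError(f"component index {j} out of range")
        theta = np.asarray(theta, dtype=float)
        params = self.params_dict(theta)
        test_rows = np.asarray(test_rows)
        L, alpha = self._chol_alpha(theta)
        Kxs_j = self.builder.term_gram(j, params, rows=test_rows, cols=self.rows)
        mu_j = Kxs_j @ alpha
        V = cho_solve((L, True), Kxs_j.T, check_finite=False)
        Kss_j = self.builder.term_gram(j, params, rows=test_rows, cols=test_rows)
        if full_cov:
            return mu_j, Kss_j - Kxs_j @ V
        return mu_j, np.diag(Kss_j) - np.einsum("ij,ji->i", Kxs_j, V)

    def _all_components(self, theta: np.ndarray, test_rows: np.ndarray):
        """Per-component means and pointwise variances plus the full-model
        mean/variance, sharing one factorisation."""
        params = self.params_dict(theta)
        L, alpha = self._chol_alpha(theta)
        D = self.model.D
        n_star = len(test_rows)
        cmeans = np.empty((D, n_star))
        cvars = np.empty((D, n_star))
        Kxs_total = np.zeros((n_star, self.n))
        for j in range(D):
            Kxs_j = self.builder.term_gram(j, params, rows=test_rows, cols=self.rows)
            Kxs_total += Kxs_j
            cmeans[j] = Kxs_j @ alpha
            Vj = cho_solve((L, True), Kxs_j.T, check_finite=False)
            dKss = np.einsum("ii->i", self.builder.term_gram(j, params, rows=test_rows, cols=test_rows))
            cvars[j] = dKss - np.einsum("ij,ji->i", Kxs_j, Vj)
        mu = Kxs_total @ alpha
        V = cho_solve((L, True), Kxs_total.T, check_finite=False)
        dKss_tot = np.einsum("ii->i", self.builder.model_gram(params, rows=test_rows, cols=test_rows, include_noise=False))
        var = dKss_tot - np.einsum("ij,ji->i", Kxs_total, V)
        return cmeans, cvars, mu, var

    def log_predictive_density(self, theta, test_rows) -> float:
        """Joint log density of the observed targets at ``test_rows`` under
        the single-parameter-setting predictive (noise included)."""
        theta = np.asarray(theta, dtype=float)
        test_rows = np.asarray(test_rows)
        mu, Sigma = self.predict(theta, test_rows, full_cov=True)
        Sigma = Sigma + theta[self._noise_idx] * np.eye(len(test_rows))
        resid = self.ds.y[test_rows] - mu
        L, _ = add_jitter_and_factor(Sigma)
        z = solve_triangular(L, resid, lower=True, check_finite=False)
        return float(-0.5 * z @ z - np.sum(np.log(np.diag(L))) - 0.5 * len(test_rows) * _LOG2PI)

    def loo_conditional_loglik(self, theta) -> np.ndarray:
        """Closed-form per-row leave-one-out predictive log densities
        log p(y_i | y_{-i}, theta) from one factorisation of K_y."""
        theta = np.asarray(theta, dtype=float)
        L, _ = add_jitter_and_factor(self._K_y(theta))
        A = cho_solve((L, True), np.eye(self.n), check_finite=False)
        alpha = A @ self.y
        a_ii = np.diag(A)
        return -0.5 * np.log(2.0 * np.pi / a_ii) - 0.5 * alpha**2 / a_ii

    # -- mixtures -----------------------------------------------------------------

    def predictive_mixture(self, thetas, test_rows, weights=None) -> ComponentPrediction:
        """Mixture-of-Gaussians predictive over parameter draws/design points.

        ``thetas`` are natural-scale parameter vectors (S, p); ``weights``
        default to uniform (MCMC) or come from a CCD design.  Pointwise mean
        and variance follow the law of total variance.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        test_rows = np.asarray(test_rows)
        S = thetas.shape[0]
        if S == 0:
            raise ValueError("predictive mixture needs at least one parameter draw")
        if weights is None:
            weights = np.full(S, 1.0 / S)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (S,) or np.any(weights < 0):
            raise ValueError("weights must be non-negative, one per draw")
        weights = weights / weights.sum()
        D, n_star = self.model.D, len(test_rows)
        cm = np.zeros((D, n_star))
        cm2 = np.zeros((D, n_star))
        cv = np.zeros((D, n_star))
        fm = np.zeros(n_star)
        fm2 = np.zeros(n_star)
        fv = np.zeros(n_star)
        noise = 0.0
        for w, theta in zip(weights, thetas):
            cmeans, cvars, mu, var = self._all_components(theta, test_rows)
            cm += w * cmeans
            cm2 += w * cmeans**2
            cv += w * cvars
            fm += w * mu
            fm2 += w * mu**2
            fv += w * var
            noise += w * theta[self._noise_idx]
        return ComponentPrediction(
            labels=tuple(t.label for t in self.model.terms),
            component_means=cm,
            component_vars=np.maximum(cv + cm2 - cm**2, 0.0),
            mean=fm,
            var=np.maximum(fv + fm2 - fm**2, 0.0),
            noise_var=float(noise),
        )

    def explained_variance(self, thetas, weights=None) -> dict[str, float]:
        """Fraction of modelled variation per component.

        Variance (over training rows) of each component's mixture-mean
        prediction, normalised by the sum over components plus the
        mixture-mean noise variance, so fractions lie in [0, 1].
        """
        pred = self.predictive_mixture(thetas, self.rows, weights)
        comp_var = pred.component_means.var(axis=1)
        total = float(comp_var.sum() + pred.noise_var)
        if total <= 0:
            return {label: 0.0 for label in pred.labels}
        return {label: float(v / total) for label, v in zip(pred.labels, comp_var)}
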