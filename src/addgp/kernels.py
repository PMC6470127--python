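"""Covariance functions and Gram-matrix assembly for additive GP models.

The additive model is a sum of independent GP components, each touching a
small set of covariates.  Every component is represented in a normal form:

    (product of discrete kernels) x (optional continuous kernel) x (masks)

* a discrete-only component is categorical/binary kernel times a constant
  kernel, so it carries exactly one magnitude parameter;
* a component with a continuous covariate uses the squared-exponential (se),
  periodic, or input-warped non-stationary se kernel, carrying a
  length-scale and a magnitude;
* every covariate a component touches contributes a binary *mask* kernel
  built from its missingness flags, so any entry involving a missing value
  is exactly zero and the component's contribution to the target vanishes
  there.

Continuous covariates are assumed standardised (the non-stationary kernel's
sigmoid warp is applied to the raw time-from-event in months *before*
standardisation; see :mod:`addgp.data`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "se_kernel",
    "periodic_kernel",
    "constant_kernel",
    "categorical_kernel",
    "binary_kernel",
    "sigmoid_warp",
    "ns_kernel",
    "KernelTerm",
    "ModelSpec",
    "make_term",
    "parse_formula",
    "GramBuilder",
    "DEFAULT_WARP",
]

#: default sigmoid warp constants (a, b, c): effective window ~ +/-12 months
#: around the event, saturation at +/-40.
DEFAULT_WARP = (0.5, 0.0, 40.0)


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"kernel parameter {name} must be positive, got {value}")


def se_kernel(x1, x2, lengthscale: float, magnitude: float):
    """Squared-exponential covariance sigma^2 exp(-(x1-x2)^2 / (2 l^2))."""
    _check_positive(lengthscale=lengthscale, magnitude=magnitude)
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    return magnitude * np.exp(-0.5 * (d / lengthscale) ** 2)


def periodic_kernel(x1, x2, lengthscale: float, magnitude: float, period: float):
    """Periodic covariance sigma^2 exp(-2 sin^2(pi (x1-x2)/period) / l^2)."""
    _check_positive(lengthscale=lengthscale, magnitude=magnitude, period=period)
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    return magnitude * np.exp(-2.0 * np.sin(np.pi * d / period) ** 2 / lengthscale**2)


def constant_kernel(magnitude: float):
    _check_positive(magnitude=magnitude)
    return magnitude


def categorical_kernel(x1, x2):
    """1 where the levels agree, 0 otherwise."""
    return (np.asarray(x1) == np.asarray(x2)).astype(float)


def binary_kernel(x1, x2):
    """1 where both arguments are 1, 0 otherwise (also the mask kernel)."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if not (np.isin(a, (0.0, 1.0)).all() and np.isin(b, (0.0, 1.0)).all()):
        raise ValueError("binary kernel inputs must be 0 or 1")
    return a * b


def sigmoid_warp(t, a: float = DEFAULT_WARP[0], b: float = DEFAULT_WARP[1], c: float = DEFAULT_WARP[2]):
    """Bijective warp (-inf, inf) -> (-c, c): 2c(-1/2 + 1/(1+exp(-a(t-b)))).

    ``a`` sets the width of the effective window around the event time ``b``;
    ``c`` the saturation range.  Strictly increasing, with omega(b) = 0.
    """
    _check_positive(a=a, c=c)
    t = np.asarray(t, dtype=float)
    from scipy.special import expit

    return 2.0 * c * (expit(a * (t - b)) - 0.5)


def ns_kernel(t1, t2, lengthscale: float, magnitude: float, warp=DEFAULT_WARP):
    """Non-stationary se kernel: the se kernel on sigmoid-warped time."""
    a, b, c = warp
    return se_kernel(sigmoid_warp(t1, a, b, c), sigmoid_warp(t2, a, b, c), lengthscale, magnitude)


# --------------------------------------------------------------------------
# Kernel terms and model specifications


@dataclass(frozen=True)
class KernelTerm:
    """One additive component in normal form.

    ``covariates`` is the ordered tuple of declared covariates the term
    touches; ``continuous`` names the (at most one) continuous covariate and
    ``cont_kind`` its kernel ('se', 'periodic' or 'ns'); the remaining
    covariates are discrete factors.  Free parameters are
    ``<label>.magnitude`` and, when a continuous covariate is present,
    ``<label>.lengthscale``.
    """

    covariates: tuple[str, ...]
    continuous: str | None = None
    cont_kind: str = "se"
    period: float | None = None

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("a kernel term needs at least one covariate")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates within a term must be distinct")
        if self.continuous is not None and self.continuous not in self.covariates:
            raise ValueError("continuous covariate must be listed in covariates")
        if self.cont_kind == "periodic" and self.continuous is not None and not (self.period and self.period > 0):
            raise ValueError("periodic kernel requires a positive period")

    @property
    def label(self) -> str:
        return "*".join(self.covariates)

    @property
    def discretes(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c != self.continuous)

    @property
    def is_interaction(self) -> bool:
        return len(self.covariates) >= 2

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.continuous is not None:
            return (f"{self.label}.lengthscale", f"{self.label}.magnitude")
        return (f"{self.label}.magnitude",)

    def formula_token(self) -> str:
        if self.continuous is not None and self.cont_kind != "se":
            parts = [c if c != self.continuous else f"{c}({self.cont_kind})" for c in self.covariates]
            return "*".join(parts)
        return self.label


def make_term(covariates, declarations) -> KernelTerm:
    """Build a term from covariate names given their declarations.

    ``declarations`` maps name -> object with ``kind`` ('continuous', 'binary'
    or 'categorical'), ``kernel`` ('se', 'periodic', 'ns', 'bi', 'ca') and
    ``period``.  At most one continuous covariate is allowed per term.
    """
    names = tuple(covariates)
    cont = [n for n in names if declarations[n].kind == "continuous"]
    if len(cont) > 1:
        raise ValueError(f"term {names} has more than one continuous covariate")
    if cont:
        decl = declarations[cont[0]]
        return KernelTerm(names, continuous=cont[0], cont_kind=decl.kernel, period=decl.period)
    return KernelTerm(names)


def _term_sort_key(term: KernelTerm):
    # canonical ordering: shared continuous, then interactions, then
    # discrete-alone terms last
    if term.continuous is not None and not term.is_interaction:
        rank = 0
    elif term.is_interaction:
        rank = 1
    else:
        rank = 2
    return (rank, term.label)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate additive model: an ordered tuple of kernel terms.

    The noise variance parameter ``noise.variance`` is implicit.  Terms are
    kept in canonical order so the formula string round-trips.
    """

    terms: tuple[KernelTerm, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a model needs at least one term (D >= 1)")
        object.__setattr__(self, "terms", tuple(sorted(self.terms, key=_term_sort_key)))
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate kernel terms in model")

    @property
    def D(self) -> int:
        return len(self.terms)

    @property
    def covariates(self) -> frozenset[str]:
        return frozenset(c for t in self.terms for c in t.covariates)

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for term in self.terms:
            names.extend(term.param_names)
        names.append("noise.variance")
        return tuple(names)

    @property
    def formula(self) -> str:
        return "y ~ " + " + ".join(t.formula_token() for t in self.terms)

    def with_terms(self, extra) -> "ModelSpec":
        return ModelSpec(self.terms + tuple(extra))


_TOKEN_RE = re.compile(r"^([A-Za-z_]\w*)(?:\((\w+)\))?$")


def parse_formula(formula: str, declarations) -> ModelSpec:
    """Parse ``y ~ id + age + id*age + diseaseAge(ns)`` into a ModelSpec.

    Kernel annotations in parentheses are checked against the covariate
    declarations (which are authoritative).
    """
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    terms = []
    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        names = []
        for factor in chunk.split("*"):
            m = _TOKEN_RE.match(factor.strip())
            if m is None:
                raise ValueError(f"cannot parse term {chunk!r}")
            name, kind = m.groups()
            if name not in declarations:
                raise KeyError(f"covariate {name!r} not declared")
            if kind is not None and declarations[name].kernel != kind:
                raise ValueError(
                    f"term {chunk!r} annotates {name} as {kind} but it is declared {declarations[name].kernel}"
                )
            names.append(name)
        terms.append(make_term(names, declarations))
    return ModelSpec(tuple(terms))


# --------------------------------------------------------------------------
# Gram assembly


class GramBuilder:
    """Precomputes per-term structure matrices for one dataset and evaluates
    term and model Gram matrices (including cross-covariances).

    For each term the parameter-free part (discrete indicator kernels times
    the missingness masks of every covariate the term touches) is a fixed
    N x N matrix; the parameter-dependent continuous factor reuses a
    precomputed squared-distance (or lag) matrix.  Missing covariate values
    are replaced by zero before distances are formed — harmless because the
    mask already zeroes those rows and columns.
    """

    def __init__(self, model: ModelSpec, dataset) -> None:
        self.model = model
        self.ds = dataset
        n = dataset.n_rows
        self._base: list[np.ndarray] = []
        self._dist: list[np.ndarray | None] = []
        for term in model.terms:
            base = np.ones((n, n))
            for name in term.discretes:
                col = dataset.column(name)
                vals = np.nan_to_num(col, nan=-1.0)
                if dataset.declaration(name).kind == "binary":
                    base *= np.outer(vals == 1.0, vals == 1.0)
                else:
                    base *= vals[:, None] == vals[None, :]
            for name in term.covariates:  # mask kernels, every covariate
                flag = dataset.flag(name)
                base *= np.outer(flag, flag)
            self._base.append(base)
            if term.continuous is not None:
                x = np.nan_to_num(dataset.column(term.continuous), nan=0.0)
                d = x[:, None] - x[None, :]
                self._dist.append(d if term.cont_kind == "periodic" else d**2)
            else:
                self._dist.append(None)

    def term_gram(self, j: int, params: dict[str, float], rows=None, cols=None) -> np.ndarray:
        """Gram (or cross-covariance) matrix of component ``j``."""
        term = self.model.terms[j]
        base = self._base[j]
        dist = self._dist[j]
        if rows is not None or cols is not None:
            idx = np.ix_(
                rows if rows is not None else np.arange(base.shape[0]),
                cols if cols is not None else np.arange(base.shape[0]),
            )
            base = base[idx]
            dist = dist[idx] if dist is not None else None
        mag = params[f"{term.label}.magnitude"]
        _check_positive(magnitude=mag)
        if term.continuous is None:
            return mag * base
        ls = params[f"{term.label}.lengthscale"]
        _check_positive(lengthscale=ls)
        if term.cont_kind == "periodic":
            k = np.exp(-2.0 * np.sin(np.pi * dist / term.period) ** 2 / ls**2)
        else:
            k = np.exp(dist * (-0.5 / ls**2))
        return mag * k * base

    def model_gram(self, params: dict[str, float], rows=None, cols=None, include_noise: bool | None = None) -> np.ndarray:
        """Sum of component Grams; adds sigma2_eps I only on the square
        training block (rows identical to cols)."""
        total = None
        for j in range(self.model.D):
            k = self.term_gram(j, params, rows, cols)
            total = k if total is None else total + k
        same = (rows is None and cols is None) or (
            rows is not None and cols is not None and np.array_equal(rows, cols)
        )
        if include_noise is None:
            include_noise = same
        if include_noise:
            if not same:
                raise ValueError("noise can only be added on the square training block")
            total = total + params["noise.variance"] * np.eye(total.shape[0])
        return total


def add_jitter_and_factor(K: np.ndarray, max_rel: float = 1e-4):
    """Cholesky with escalating diagonal jitter.

    Starts at 1e-8 x mean(diag), escalating tenfold up to ``max_rel`` x
    mean(diag); raises ``np.linalg.LinAlgError`` if factorisation still
    fails.  Returns (lower-triangular factor, jitter used).
    """
    scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        scale = 1.0
    jitter = 1e-8 * scale
    eye = np.eye(K.shape[0])
    for _ in range(5):
        try:
            return np.linalg.cholesky(K + jitter * eye), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > max_rel * scale * 10.0:
                break
    raise np.linalg.LinAlgError(
        f"covariance matrix not positive definite even with jitter {jitter:.2e}"
    )
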