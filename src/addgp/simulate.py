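"""Synthetic longitudinal data from known additive-GP generators.

Five generative models of increasing complexity over a case-control
longitudinal design, used to verify that the forward search recovers the
generating covariates:

* ``agpm1``: per-subject random offsets only (id)
* ``agpm2``: + a shared nonlinear age trend and subject-specific age trends
  (age, id x age)
* ``agpm3``: + a location offset and a location-specific age trend
  (loc, loc x age)
* ``agpm4``: agpm2 + a non-stationary disease-age effect localised around a
  subject-specific onset (cases only; controls have diseaseAge missing)
* ``agpm5``: agpm3 + the disease-age effect

Default design: 40 subjects (20 cases / 20 controls where disease is
present), visits every 3 months from 0 to 36 months (13 per subject),
shared component variances 4, interaction variances 4, noise variance 3;
length-scales 1 (shared) and 0.8 (interaction) on standardised covariates.
Onset times are uniform on (0, 36) months; location and gender are
per-subject Bernoulli(1/2); group is the case indicator and, like gender,
carries no effect in any generator — they act as irrelevant covariates for
specificity checks.  Components are drawn exactly from their multivariate
normals on the standardised covariates, so the generator matches the
modelling-side kernel conventions (including the sigmoid warp of
diseaseAge applied before standardisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Covariate, LongitudinalDataset
from .inference import derive_seed
from .kernels import GramBuilder, ModelSpec, make_term
from .selection import SearchConfig, forward_search

logger = logging.getLogger("addgp")

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "standard_covariates",
    "table1_interaction_pairs",
    "simulate_covariates",
    "generating_model",
    "draw_components",
    "simulate_agpm",
    "classify_covariate_set",
    "run_table1_experiment",
    "AGPM_MODELS",
]

AGPM_MODELS = ("agpm1", "agpm2", "agpm3", "agpm4", "agpm5")

_MODEL_COVARIATES = {
    "agpm1": (),
    "agpm2": ("age",),
    "agpm3": ("age", "loc"),
    "agpm4": ("age", "diseaseAge"),
    "agpm5": ("age", "loc", "diseaseAge"),
}


def standard_covariates() -> list[Covariate]:
    """Covariate declarations for the simulated case-control design."""
    return [
        Covariate("id", kind="categorical"),
        Covariate("age", kind="continuous", kernel="se"),
        Covariate("diseaseAge", kind="continuous", kernel="ns", interactions="forbidden"),
        Covariate("group", kind="binary"),
        Covariate("loc", kind="binary"),
        Covariate("gender", kind="binary"),
    ]


def table1_interaction_pairs() -> frozenset[frozenset[str]]:
    """Interactions offered in the simulation study: every discrete covariate
    may interact with age; diseaseAge never interacts."""
    return frozenset(frozenset((d, "age")) for d in ("id", "loc", "group", "gender"))


@dataclass(frozen=True)
class SimulationDesign:
    """Design parameters of one synthetic study."""

    model: str = "agpm2"
    n_cases: int = 20
    n_controls: int = 20
    t_start: float = 0.0
    t_end: float = 36.0
    interval: float = 3.0
    noise_var: float = 3.0
    shared_var: float = 4.0
    interaction_var: float = 4.0
    shared_lengthscale: float = 1.0
    interaction_lengthscale: float = 0.8
    onset_range: tuple[float, float] = (0.0, 36.0)

    def __post_init__(self):
        if self.model not in AGPM_MODELS:
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one subject")
        if "diseaseAge" in _MODEL_COVARIATES[self.model] and (self.n_cases < 1 or self.n_controls < 1):
            raise ValueError("disease-effect models need at least one case and one control")
        span = self.t_end - self.t_start
        if self.interval <= 0 or abs(span / self.interval - round(span / self.interval)) > 1e-9:
            raise ValueError("the visit interval must divide the follow-up span")

    @property
    def ages(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.interval)) + 1
        return self.t_start + self.interval * np.arange(n)

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class SimulatedDataset:
    """A simulated table plus its ground truth."""

    frame: pd.DataFrame  # raw covariates (months) + target
    dataset: LongitudinalDataset
    components: dict[str, np.ndarray]  # per-component latent values per row
    noise: np.ndarray
    true_model: ModelSpec
    design: SimulationDesign
    seed: int

    def component_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"row": np.arange(len(self.noise))})
        for label, values in self.components.items():
            out[label] = values
        out["noise"] = self.noise
        return out


def simulate_covariates(design: SimulationDesign, seed: int) -> pd.DataFrame:
    """Raw covariate table (no target): regular age grid per subject, group =
    case indicator, onsets uniform over the follow-up for group-1 subjects,
    diseaseAge = age - onset (missing for group-0 subjects), loc and gender
    i.i.d. Bernoulli(1/2) per subject."""
    rng = np.random.default_rng(seed)
    ages = design.ages
    rows = []
    onset_lo, onset_hi = design.onset_range
    for i in range(design.n_subjects):
        case = i < design.n_cases
        onset = rng.uniform(onset_lo, onset_hi) if case else np.nan
        loc = int(rng.random() < 0.5)
        gender = int(rng.random() < 0.5)
        for t in ages:
            rows.append(
                {
                    "id": f"s{i + 1:02d}",
                    "age": t,
                    "diseaseAge": t - onset if case else np.nan,
                    "group": int(case),
                    "loc": loc,
                    "gender": gender,
                }
            )
    return pd.DataFrame(rows)


def generating_model(model: str) -> ModelSpec:
    """True additive structure of one generator (id base plus the model's
    shared and interaction terms)."""
    decls = {c.name: c for c in standard_covariates()}
    terms = [make_term(["id"], decls)]
    covs = _MODEL_COVARIATES[model]
    if "age" in covs:
        terms.append(make_term(["age"], decls))
        terms.append(make_term(["id", "age"], decls))
    if "loc" in covs:
        terms.append(make_term(["loc"], decls))
        terms.append(make_term(["loc", "age"], decls))
    if "diseaseAge" in covs:
        terms.append(make_term(["diseaseAge"], decls))
    return ModelSpec(tuple(terms))


def _generator_params(model: ModelSpec, design: SimulationDesign) -> dict[str, float]:
    params: dict[str, float] = {"noise.variance": design.noise_var}
    for term in model.terms:
        mag = design.interaction_var if term.is_interaction else design.shared_var
        params[f"{term.label}.magnitude"] = mag
        if term.continuous is not None:
            ls = design.interaction_lengthscale if term.is_interaction else design.shared_lengthscale
            params[f"{term.label}.lengthscale"] = ls
    return params


def draw_components(builder: GramBuilder, params: dict[str, float], rng) -> dict[str, np.ndarray]:
    """Sample each additive component exactly from N(0, K_j).

    Components are drawn on their active rows (mask diagonal > 0) with the
    jitter policy and are exactly zero elsewhere.
    """
    n = builder.ds.n_rows
    components: dict[str, np.ndarray] = {}
    for j, term in enumerate(builder.model.terms):
        K = builder.term_gram(j, params)
        active = np.flatnonzero(np.diag(K) > 0)
        f = np.zeros(n)
        if active.size:
            Ka = K[np.ix_(active, active)]
            La = np.linalg.cholesky(Ka + 1e-8 * float(np.mean(np.diag(Ka))) * np.eye(len(active)))
            f[active] = La @ rng.standard_normal(len(active))
        components[term.label] = f
    return components


def simulate_agpm(design: SimulationDesign, seed: int) -> SimulatedDataset:
    """Draw one dataset: each latent component exactly from its multivariate
    normal on the standardised covariates, plus Gaussian noise.

    Components are sampled on their *active* rows (mask diagonal 1) with the
    jitter policy, and are exactly zero on masked rows — in particular the
    disease-age component vanishes on every control row.
    """
    frame = simulate_covariates(design, derive_seed(seed, "covariates"))
    covs = standard_covariates()
    frame = frame.assign(y=0.0)
    ds0 = LongitudinalDataset.from_frame(frame, covs, target="y", subject="id")
    std0, _ = ds0.standardise(include_target=False)
    model = generating_model(design.model)
    params = _generator_params(model, design)
    builder = GramBuilder(model, std0)
    rng = np.random.default_rng(derive_seed(seed, "components"))
    n = std0.n_rows
    components = draw_components(builder, params, rng)
    total = np.sum(list(components.values()), axis=0)
    noise = (
        np.sqrt(design.noise_var) * rng.standard_normal(n)
        if design.noise_var > 0
        else np.zeros(n)
    )
    y = total + noise
    frame = frame.assign(y=y)
    dataset = LongitudinalDataset.from_frame(frame, covs, target="y", subject="id")
    return SimulatedDataset(
        frame=frame, dataset=dataset, components=components, noise=noise,
        true_model=model, design=design, seed=seed,
    )


def classify_covariate_set(selected) -> str:
    """Map a selected optional-covariate set to its generating-model label
    ('Others' for the 27 remaining subsets)."""
    key = frozenset(set(selected) - {"id"})
    table = {frozenset(v): k for k, v in _MODEL_COVARIATES.items()}
    return table.get(key, "Others").replace("agpm", "AGPM")


def run_table1_experiment(
    reps: int,
    seed: int,
    models=AGPM_MODELS,
    design: SimulationDesign | None = None,
    search: SearchConfig | None = None,
) -> pd.DataFrame:
    """Repeat simulate -> forward search and tabulate which model wins.

    One row per generating model; columns count the selected model (AGPM1-5
    or Others) and whether diseaseAge entered the final model.  Individual
    run failures are recorded under 'failed' rather than raised.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    base_design = design or SimulationDesign()
    base_search = search or SearchConfig(
        candidates=("age", "diseaseAge", "loc", "group", "gender"),
        interaction_pairs=table1_interaction_pairs(),
    )
    labels = [m.replace("agpm", "AGPM") for m in AGPM_MODELS] + ["Others"]
    rows = []
    for model in models:
        counts = {label: 0 for label in labels}
        counts.update({"diseaseAge_included": 0, "diseaseAge_not_included": 0, "failed": 0})
        for rep in range(reps):
            run_seed = derive_seed(seed, f"table1:{model}:{rep}")
            sim = simulate_agpm(
                SimulationDesign(**{**base_design.__dict__, "model": model}), run_seed
            )
            cfg_fields = {**base_search.__dict__, "seed": run_seed}
            try:
                trace = forward_search(sim.dataset, SearchConfig(**cfg_fields))
            except Exception as exc:
                logger.warning("search failed for %s rep %d: %s", model, rep, exc)
                counts["failed"] += 1
                continue
            selected = trace.final_model.covariates
            counts[classify_covariate_set(selected)] += 1
            if "diseaseAge" in selected:
                counts["diseaseAge_included"] += 1
            else:
                counts["diseaseAge_not_included"] += 1
        rows.append({"generating": model.replace("agpm", "AGPM"), **counts})
    return pd.DataFrame(rows).set_index("generating")
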