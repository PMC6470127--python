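# addgp

Additive Gaussian-process regression and covariate selection for
longitudinal biomedical data.

## The problem

Longitudinal studies measure subjects repeatedly over time and ask which
covariates — age, group, sex, location, time from a disease event — are
associated with an outcome such as a protein level or a microbial pathway
abundance. Linear mixed-effect models are the standard tool but struggle
with nonlinear trends, correlated within-subject outcomes, time-varying
covariates and, especially, *non-stationary* effects that concentrate
around a subject-specific event such as disease onset.

`addgp` models the outcome as a sum of interpretable GP components,

    y = f_se(age) + f_ca×se(id × age) + f_ns(diseaseAge)
      + f_bi(group) + f_bi×se(group × age) + f_ca(id) + ε,

where each component uses a kernel suited to its covariate type: squared
exponential for smooth trends, periodic for seasonality, categorical/binary
times a constant kernel for group offsets and subject-level random effects,
products for interactions, and a sigmoid-input-warped squared exponential
for disease-event effects that change fastest near the event. Missing
covariate values (e.g. `diseaseAge` for controls) are handled by binary
mask kernels that zero a component's contribution exactly — no imputation.

Inference is fully Bayesian: slice-sampling MCMC (or a fast deterministic
central-composite-design approximation) over the kernel hyperparameters
with weakly informative priors on the standardised scale. Covariates are
selected by a greedy forward search driven by out-of-sample predictive
density: Pareto-smoothed importance-sampling leave-one-out CV for
continuous covariates (accept when the Bayesian-bootstrap probability that
the extension predicts better, the LOOCVF, exceeds 0.8) and
leave-one-subject-out stratified CV for discrete covariates (SCVF > 0.95).
Components explaining under 1% of the modelled variance are pruned.

Intended users: statisticians and computational biologists analysing
longitudinal -omics or clinical biomarker panels, one target variable at a
time.

## Worked example

Simulate a dataset from a known additive structure (per-subject offsets +
a shared nonlinear age trend + subject-specific age deviations, variances
4/4/4, noise 3) and let the search recover it:

```python
from addgp import (SamplerSettings, SearchConfig, SimulationDesign,
                   forward_search, simulate_agpm)
from addgp.simulate import table1_interaction_pairs

sim = simulate_agpm(SimulationDesign(model="agpm2", n_cases=4, n_controls=4,
                                     interval=6.0, noise_var=3.0), seed=5)
config = SearchConfig(candidates=("age", "diseaseAge", "loc", "group", "gender"),
                      interaction_pairs=table1_interaction_pairs(),
                      sampler=SamplerSettings(chains=2, iters=400, burn_in=200),
                      seed=7)
trace = forward_search(sim.dataset, config)
print(trace.report())
```

prints (abridged):

```
forward search trace
=====================
step 0 [continuous] winner=age factor=1.000 (threshold 0.8) -> accepted
    candidate diseaseAge: rank prob 0.001
    candidate age: rank prob 1.000
step 1 [continuous] winner=diseaseAge factor=0.550 (threshold 0.8) -> rejected
step 2 [discrete] winner=gender factor=0.893 (threshold 0.95) -> rejected
final model: y ~ age + id*age + id
explained variance: age=0.1460, id*age=0.5491, id=0.0464
```

Step 0: among the continuous candidates, `age` (with its allowed `id*age`
interaction) ranks first and its LOOCVF of 1.000 over the base `id`-only
model clears the 0.8 threshold — every bootstrap reweighting of the
leave-one-out densities favours it. Step 1: `diseaseAge` (irrelevant here)
reaches LOOCVF 0.550 and is rejected. Step 2: the best discrete candidate
reaches SCVF 0.893 < 0.95, so the search stops at the generating structure.
The explained-variance line decomposes the fit: the subject-specific age
trends carry ~55% of the modelled variation, the shared age trend ~15%, the
remainder being noise — all components stay above the 1% pruning threshold.

The same workflow is available from the shell:

```
addgp simulate --model agpm2 --pairs 20 --seed 1 --out sim/
addgp select config.yaml --out results/     # YAML: data path, covariate
                                            # types/kernels, thresholds,
                                            # sampler settings, seed, and
                                            # optional per-parameter priors
addgp table1 --reps 100 --seed 1            # full repeated-selection study
```

`addgp select` writes the selection trace, the final model formula, the
per-component explained variances, a posterior parameter summary, and a
per-component prediction table (mean, sd, cumulative mean per row) on the
original target scale.

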