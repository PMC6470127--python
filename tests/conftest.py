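import numpy as np
import pandas as pd
import pytest

from addgp.data import Covariate, LongitudinalDataset
from addgp.kernels import ModelSpec, make_term


@pytest.fixture
def declarations():
    covs = [
        Covariate("id", kind="categorical"),
        Covariate("age", kind="continuous", kernel="se"),
        Covariate("diseaseAge", kind="continuous", kernel="ns", interactions="forbidden"),
        Covariate("group", kind="binary"),
        Covariate("loc", kind="binary"),
        Covariate("gender", kind="binary"),
        Covariate("season", kind="continuous", kernel="periodic", period=12.0,
                  interactions="forbidden"),
    ]
    return {c.name: c for c in covs}


def toy_frame(n_subjects=3, n_visits=4, seed=0, with_missing=True):
    """Small longitudinal table: regular visits, half the subjects cases."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        case = i % 2 == 0
        onset = rng.uniform(0, 36) if case else np.nan
        loc = int(rng.random() < 0.5)
        for v in range(n_visits):
            age = 36.0 * v / max(n_visits - 1, 1)
            rows.append(
                {
                    "id": f"s{i}",
                    "age": age,
                    "diseaseAge": age - onset if case and with_missing else (np.nan if with_missing else age),
                    "group": int(case),
                    "loc": loc,
                    "gender": i % 2,
                    "season": age % 12,
                    "y": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_dataset(declarations):
    df = toy_frame()
    return LongitudinalDataset.from_frame(df, declarations.values(), target="y", subject="id")


@pytest.fixture
def toy_std(toy_dataset):
    ds, record = toy_dataset.standardise()
    return ds, record


def small_model(declarations, *term_names):
    terms = tuple(make_term(names.split("*"), declarations) for names in term_names)
    return ModelSpec(terms)
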