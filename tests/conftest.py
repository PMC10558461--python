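"""Shared fixtures: small synthetic populations and toy matched datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyfrac import (
    AnalysisDataset,
    PopulationConfig,
    build_design,
    build_cohort,
    default_maps,
    derive_covariates,
    generate_study_data,
)

try:  # keep hypothesis reproducible under plain pytest runs
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


MAPS = default_maps()


@pytest.fixture(scope="session")
def synth_data():
    """A mid-size generated claims bundle (shared, read-only)."""
    return generate_study_data(PopulationConfig(n_patients=2000, seed=3))


@pytest.fixture(scope="session")
def study_dataset(synth_data):
    """Matched analysis dataset derived end to end from `synth_data`."""
    cfg = PopulationConfig(n_patients=2000, seed=3)
    cohort = build_cohort(
        synth_data.patients, synth_data.diagnoses, window=cfg.study_window, seed=3
    )
    frame = cohort.to_frame()
    cov = derive_covariates(frame, synth_data.diagnoses, synth_data.prescriptions, MAPS)
    return build_design(frame, cov, MAPS)


def toy_dataset(
    n_pairs: int = 200,
    beta_count: float = 0.0,
    beta_rx: float = 0.0,
    n_cm: int = 3,
    n_rx: int = 4,
    seed: int = 0,
) -> AnalysisDataset:
    """Small matched dataset with optional signal in the count and in the
    first medication flag; covariates are exchangeable between roles when
    all betas are zero."""
    rng = np.random.default_rng(seed)
    variables = ["med_count"] + [f"cm_c{i}" for i in range(n_cm)] + [
        f"rx{i + 1:02d}" for i in range(n_rx)
    ]
    p = len(variables)

    def draw(n):
        X = np.zeros((n, p))
        X[:, 0] = rng.poisson(5.0, n)
        X[:, 1:] = rng.random((n, p - 1)) < 0.3
        return X

    X1, X2 = draw(n_pairs), draw(n_pairs)
    beta = np.zeros(p)
    beta[0] = beta_count
    beta[1 + n_cm] = beta_rx
    from scipy.special import expit

    first_is_case = rng.random(n_pairs) < expit((X1 - X2) @ beta)
    Xcase = np.where(first_is_case[:, None], X1, X2)
    Xctrl = np.where(first_is_case[:, None], X2, X1)

    ages = rng.integers(65, 96, n_pairs)
    sexes = np.where(rng.random(n_pairs) < 0.7, "female", "male")
    rows = []
    for role, X in (("case", Xcase), ("control", Xctrl)):
        df = pd.DataFrame(X, columns=variables)
        df.insert(0, "pair_id", np.arange(1, n_pairs + 1))
        df.insert(1, "role", role)
        df.insert(2, "patient_id", [f"{role[:2]}{i}" for i in range(n_pairs)])
        df.insert(3, "stratum", np.where(ages < 75, "early", "late"))
        df.insert(4, "age_at_index", ages)
        df.insert(5, "sex", sexes)
        rows.append(df)
    data = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["pair_id", "role"])
        .reset_index(drop=True)
    )
    return AnalysisDataset(data, variables, {v: v for v in variables})
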