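import numpy as np
import pytest

from behavmeta.synthetic import (
    CaptureModel,
    TruthConfig,
    assemble_covariances,
    simulate_multiyear,
    study_like_config,
)


def make_balanced_config(
    n: int = 200,
    reps: int = 4,
    repeatability=(0.5, 0.5, 0.5),
    r_ind=None,
    r_e=None,
    total_sd=(1.0, 1.0, 1.0),
    mu=(0.0, 20.0, 20.0),
    date_slopes=(0.0, 0.0, 0.0),
    seed: int = 0,
) -> TruthConfig:
    """One year, everyone captured, fixed replicate count, no censoring.

    Trait means sit far from the assay floors and the ceiling is pushed out
    of reach, so the observation model is exactly the homoscedastic
    mixed model the samplers assume.
    """
    sigma_ind, sigma_e = assemble_covariances(
        total_sd, repeatability, r_ind or {}, r_e or {}
    )
    return TruthConfig(
        years=(2001,),
        n_individuals_per_year=n,
        repeats_distribution={reps: 1.0},
        mu=mu,
        sigma_ind=sigma_ind,
        sigma_e=sigma_e,
        date_slopes=date_slopes,
        censor_threshold=1e9,
        capture_model=CaptureModel(intercept=np.inf),
        seed=seed,
    )


@pytest.fixture(scope="session")
def balanced_table():
    """n=200 x 4 repeats, R=0.5 all traits, r_ind=0.6 / r_e=0.1 on NA-AG."""
    cfg = make_balanced_config(
        n=200, reps=4, r_ind={"NA-AG": 0.6}, r_e={"NA-AG": 0.1}, seed=3
    )
    return simulate_multiyear(cfg), cfg


@pytest.fixture(scope="session")
def study_table():
    """The study-like default design (8 years, capture bias, censoring)."""
    cfg = study_like_config(seed=42)
    return simulate_multiyear(cfg), cfg
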