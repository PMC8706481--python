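import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from adept.config import GeneratorConfig, smoke_config
from adept.episode_builder import build_labeled_episodes
from adept.pipeline import run_pipeline
from adept.synthetic_claims import generate_cohort, generate_truth_model


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(n_patients=1000, seed=5)


@pytest.fixture(scope="session")
def truth(gen_config):
    return generate_truth_model(gen_config, seed=gen_config.seed)


@pytest.fixture(scope="session")
def cohort(truth, gen_config):
    """(patients, prescriptions, encounters, intent) for a 1,000-patient cohort."""
    return generate_cohort(truth, gen_config.n_patients, seed=7)


@pytest.fixture(scope="session")
def labeled(cohort, gen_config):
    patients, rx, enc, _ = cohort
    return build_labeled_episodes(
        patients, rx, enc, covariate_names=gen_config.covariate_names
    )


@pytest.fixture(scope="session")
def smoke_dir(tmp_path_factory):
    """Artifacts of a full smoke-profile pipeline run (2,000 patients)."""
    out = tmp_path_factory.mktemp("smoke")
    run_pipeline(smoke_config(n_patients=2000, seed=0), out)
    return out


def make_logistic_data(n, k, seed, beta_scale=1.0):
    """Synthetic binary-outcome data with a known logistic truth."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    beta = beta_scale * rng.normal(size=k) / np.sqrt(k)
    p = expit(X @ beta)
    y = (rng.random(n) < p).astype(float)
    cols = [f"x{i}" for i in range(k)]
    return pd.DataFrame(X, columns=cols), y, p
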