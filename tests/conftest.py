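"""Shared fixtures: small and full-size synthetic studies."""

import pandas as pd
import pytest
from hypothesis import settings

from gazebias.bias import add_bias_columns
from gazebias.preprocessing import compute_metrics_table, validity_filter
from gazebias.synthetic import calibrated_params, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_params(seed: int = 3, n_trials: int = 4, n_per_cell: int = 2):
    p = calibrated_params(seed=seed)
    return p.replace(
        n_participants={
            ("child", "aggressive"): n_per_cell,
            ("child", "non_aggressive"): n_per_cell,
            ("adolescent", "aggressive"): n_per_cell,
            ("adolescent", "non_aggressive"): n_per_cell,
        },
        n_trials=n_trials,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """2 participants per cell x 4 trials: fast end-to-end fixture."""
    return simulate_study(small_params())


@pytest.fixture(scope="session")
def full_study():
    """The full calibrated design (119 participants x 16 trials)."""
    return simulate_study(calibrated_params(seed=11))


@pytest.fixture(scope="session")
def full_metrics(full_study) -> pd.DataFrame:
    return compute_metrics_table(
        full_study.samples, full_study.geometry, full_study.roster_frame()
    )


@pytest.fixture(scope="session")
def full_trial_table(full_metrics) -> pd.DataFrame:
    valid, _ = validity_filter(full_metrics)
    return add_bias_columns(valid)
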