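"""Shared fixtures: a reference clone, constants, and generated runs."""

import numpy as np
import pytest

from mckm import (
    CampaignSpec,
    CultureState,
    KineticParameters,
    ModelConstants,
    ParameterBounds,
    TABLE5_MABA_MEAN,
    generate_run,
    growth_rate,
)


def clipped_reference_parameters() -> KineticParameters:
    """Campaign-mean parameter vector clipped into the default bounds.

    The published campaign mean for Y_X_gln sits above the literature
    upper bound used for regression, so tests that need a ground truth
    recoverable by the bounded fit clip it to the bound.
    """
    bounds = ParameterBounds.default()
    values = dict(TABLE5_MABA_MEAN)
    arr = KineticParameters.from_dict(values).as_array()
    return KineticParameters.from_array(bounds.clip(arr))


@pytest.fixture(scope="session")
def theta_ref() -> KineticParameters:
    return clipped_reference_parameters()


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def clean_spec() -> CampaignSpec:
    """Noise-free, missingness-free campaign configuration."""
    return CampaignSpec(n_clones=1, passages=1, noise_cv={}, missing_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def initial_state(theta_ref, clean_spec) -> CultureState:
    values = dict(clean_spec.initial_state)
    values["mu_est"] = growth_rate(theta_ref, values["glc"])
    return CultureState(**values)


@pytest.fixture(scope="session")
def clean_run(theta_ref, clean_spec):
    """One noise-free synthetic run generated from the reference clone."""
    rng = np.random.default_rng(0)
    return generate_run(theta_ref, clean_spec, rng)


@pytest.fixture(scope="session")
def noisy_run(theta_ref):
    """One run with 2% multiplicative noise on every measured variable."""
    cv = {k: 0.02 for k in ("Xv", "P", "glc", "gln", "glu", "amm", "lac")}
    spec = CampaignSpec(n_clones=1, passages=1, noise_cv=cv, missing_rate=0.0, seed=3)
    rng = np.random.default_rng(3)
    return generate_run(theta_ref, spec, rng)
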