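import pytest
from hypothesis import settings

from flashbci import FitConfig, IntegrationSpec, ModelParams

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return IntegrationSpec()


@pytest.fixture(scope="session")
def fast_spec():
    """Coarser grid for tests that exercise structure, not accuracy."""
    return IntegrationSpec(n_nodes_per_axis=31)


@pytest.fixture(scope="session")
def fit_spec():
    """Grid used by the fitting-heavy tests."""
    return IntegrationSpec(n_nodes_per_axis=61)


@pytest.fixture(scope="session")
def table3_params():
    """Parameter magnitudes typical of sighted observers in this paradigm."""
    return ModelParams(p_common=0.8, sigma_v=0.35, sigma_a=0.2, sigma_p=1.64, mu_p=1.5)


@pytest.fixture(scope="session")
def param_grid():
    """Five observer parameter sets spanning weak to strong integration."""
    return [
        ModelParams(p_common=p, sigma_v=sv, sigma_a=0.2, sigma_p=sp, mu_p=1.5)
        for p, sv, sp in [
            (0.5, 0.35, 1.5),
            (0.7, 0.5, 1.0),
            (0.8, 0.35, 1.64),
            (0.9, 0.25, 2.5),
            (1.0, 0.4, 1.5),
        ]
    ]


def fast_fit_config(seed=0, n_restarts=3, n_nodes=61, **kw):
    return FitConfig(
        n_restarts=n_restarts,
        seed=seed,
        integration=IntegrationSpec(n_nodes_per_axis=n_nodes),
        **kw,
    )
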