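import warnings

import pytest

import senslex as sl


@pytest.fixture(scope="session")
def default_wheel():
    return sl.load_default_wheel()


@pytest.fixture(scope="session")
def small_panel():
    """A reproducible 6-product, 15-assessor panel with 2 cm placement noise."""
    scenario = sl.PanelScenario(
        n_products=6, n_assessors=15, assessor_noise_sd=2.0, seed=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sheets = sl.gen_mapping(scenario)
    return scenario, sheets


@pytest.fixture(scope="session")
def fitted_mfa(small_panel):
    _, sheets = small_panel
    return sl.fit_mfa(sheets)


@pytest.fixture(scope="session")
def null_citations(default_wheel):
    """Uniform-propensity citations: the pure-chance selection model."""
    scenario = sl.PanelScenario(n_products=6, n_assessors=15, seed=7)
    return sl.gen_citations(scenario, default_wheel)
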