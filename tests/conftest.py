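import pytest
from hypothesis import HealthCheck, settings

from stillage_mcfa.cashflow import DCFEngine
from stillage_mcfa.reactor import ReactorPerformanceModel
from stillage_mcfa.scenario import FinancialConfig, ScenarioConfig
from stillage_mcfa.simulate import SyntheticReactorConfig, generate_reactor_series

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fin() -> FinancialConfig:
    return FinancialConfig()


@pytest.fixture(scope="session")
def engine(fin) -> DCFEngine:
    """Calibrated DCF engine, shared across tests (calibration is pure)."""
    return DCFEngine(fin)


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def noiseless_series():
    return generate_reactor_series(SyntheticReactorConfig(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_series():
    return generate_reactor_series(SyntheticReactorConfig(noise_cv=0.02, seed=42))


@pytest.fixture(scope="session")
def noiseless_results(noiseless_series):
    return ReactorPerformanceModel(noiseless_series).fit()
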