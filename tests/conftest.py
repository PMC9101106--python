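import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

from enzisfet import (
    CarbarylRegression,
    SimParams,
    TrainConfig,
    fit_reference_model,
    generate_blanks,
    generate_dataset,
)
from enzisfet.simulate import DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def noiseless_params() -> SimParams:
    """Generator with every noise source off; temperature drift kept on."""
    return SimParams(ref_sd=0.0, signal_noise_sd=0.0, temp_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_log(noiseless_params):
    return generate_dataset(
        DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, 3, "buffer", noiseless_params
    )


@pytest.fixture(scope="session")
def noiseless_results(noiseless_log):
    """Concentration model trained to convergence on the noiseless campaign."""
    model = CarbarylRegression(
        noiseless_log,
        augment_factor=1,
        signal_noise_sd=0.0,
        temp_noise_sd=0.0,
        train_fraction=0.8,
        stratify_by_temperature=False,
        seed=0,
    )
    return model.fit(TrainConfig(learning_rate=0.05, max_epochs=20000, patience=200, seed=0))


@pytest.fixture(scope="session")
def noiseless_reference_model(noiseless_params):
    """Reference model trained to convergence (tight threshold) on
    noiseless blanks so its predictions sit within 0.1 mV of the truth."""
    blanks = generate_blanks(DEFAULT_TEMPERATURES, 25, noiseless_params)
    cfg = TrainConfig(
        learning_rate=0.05, max_epochs=10000, patience=10000, mse_stop_threshold=1e-7, seed=0
    )
    return fit_reference_model(blanks, cfg)
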