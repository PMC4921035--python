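import pytest

from spikeqc import (
    AnomalySpec,
    ArraySimConfig,
    RnaseqSimConfig,
    apply_exclusions,
    load_design,
    simulate_microarray,
    simulate_rnaseq,
)


@pytest.fixture(scope="session")
def design():
    return load_design()


@pytest.fixture(scope="session")
def analysis_design(design):
    return apply_exclusions(design)


@pytest.fixture(scope="session")
def clean_array_signals(design):
    """Noisy but anomaly-free array simulation at the default parameters."""
    return simulate_microarray(design, ArraySimConfig(seed=7), AnomalySpec())


@pytest.fixture(scope="session")
def noiseless_array_signals(design):
    return simulate_microarray(design, ArraySimConfig(noise_sd=0.0, seed=0), AnomalySpec())


@pytest.fixture(scope="session")
def deep_rnaseq_signals(design):
    """High-depth sequencing simulation: essentially every control detected."""
    return simulate_rnaseq(design, RnaseqSimConfig(depth=1e7, seed=7), AnomalySpec())
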