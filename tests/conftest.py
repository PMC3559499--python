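import numpy as np
import pytest

from repairkinetics import (
    CONTROL,
    DSB_ARREST,
    CompartmentState,
    RateConstants,
    StrandBreakRepairModel,
    generate_dataset,
    reference_config,
)


@pytest.fixture(scope="session")
def ref_rates() -> RateConstants:
    return RateConstants.tied_rates(k_s=0.21, k_d=0.74)


@pytest.fixture(scope="session")
def ref_init() -> CompartmentState:
    return CompartmentState(S=0.0, L=0.05, LSSB=0.95, CSSB=0.0)


@pytest.fixture(scope="session")
def all_lssb() -> CompartmentState:
    return CompartmentState(LSSB=1.0)


@pytest.fixture(scope="session")
def noiseless_table():
    """Exact two-condition observables at the reference parameters."""
    return generate_dataset(reference_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_table):
    """Tied-model multistart fit to the noiseless reference dataset."""
    model = StrandBreakRepairModel(noiseless_table, tie_rates=True)
    return model.fit(n_starts=20, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenarios():
    return {"control": CONTROL, "NU7441": DSB_ARREST}
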