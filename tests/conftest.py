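import numpy as np
import pytest

from hepamre.liverkin import (
    ProteomeProfile,
    build_reference_model,
    capacities,
    instantiate,
    load_characteristic,
)


@pytest.fixture(scope="session")
def model():
    return build_reference_model()


@pytest.fixture(scope="session")
def reference_profile(model):
    return ProteomeProfile("ref", {r.enzyme: 1.0 for r in model.reactions})


@pytest.fixture(scope="session")
def reference_load(model, reference_profile):
    return load_characteristic(instantiate(model, reference_profile))


@pytest.fixture(scope="session")
def reference_capacities(model, reference_load):
    return capacities(reference_load, spec=model, sample_id="ref")


@pytest.fixture(scope="session")
def table1():
    from hepamre.io import load_table1

    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
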