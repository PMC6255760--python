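import numpy as np
import pytest

from cardfil import (
    DEFAULT_PARAMS,
    MicrographSpec,
    SyntheticMonomerSpec,
    build_filament,
    make_synthetic_monomer,
    render_micrograph,
)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def monomer():
    return make_synthetic_monomer(SyntheticMonomerSpec(seed=1))


@pytest.fixture(scope="session")
def filament12(monomer, params):
    return build_filament(monomer, params, 12)


@pytest.fixture(scope="session")
def filament30(monomer, params):
    return build_filament(monomer, params, 30)


@pytest.fixture(scope="session")
def noiseless_image(filament30):
    return render_micrograph(filament30, MicrographSpec(seed=3, noise_sigma=0.0))
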