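import numpy as np
import pytest

from pamix import (
    AugmentationConfig,
    GasMixture,
    InstrumentModel,
    WavelengthGrid,
    build_reference_set,
    default_voc_library,
    normalize_by_power,
    pa_signal,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def library(grid):
    return default_voc_library(seed=0, grid=grid)


@pytest.fixture(scope="session")
def component_names(library):
    return [m.component_name for m in library]


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def singles(library, grid, instrument):
    """Power-normalized single-component spectra at the 100 ppm base level."""
    out = []
    for m in library:
        mix = GasMixture({m.component_name: 100.0})
        raw = pa_signal(instrument, library, mix, grid)
        out.append(normalize_by_power(raw, instrument))
    return out


@pytest.fixture(scope="session")
def clean_ref(singles, component_names):
    """The 4096-row factorial reference set, noiseless."""
    cfg = AugmentationConfig(noise_fraction=0.0)
    return build_reference_set(singles, cfg, component_names)


@pytest.fixture(scope="session")
def noisy_ref(singles, component_names):
    """The 4096-row reference set with 10% independent per-row noise."""
    cfg = AugmentationConfig(noise_fraction=0.10, seed=0)
    return build_reference_set(singles, cfg, component_names)
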