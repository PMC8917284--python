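import numpy as np
import pytest

import paformat as pf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def linear_device():
    return pf.build_linear_array(8, 0.3e-3)


def make_complete_padata(n_detectors=4, n_samples=32, n_wavelengths=2,
                         n_measurements=1, seed=7):
    """A small, fully coherent dataset that passes all QC checks."""
    rng = np.random.default_rng(seed)
    device = pf.build_linear_array(n_detectors, 0.3e-3)
    values = rng.normal(size=(n_detectors, n_samples, n_wavelengths,
                              n_measurements))
    data = pf.PAData(tensor=values, device=device)
    data.acquisition["uuid"] = rng.bytes(16).hex()
    data.acquisition["compression"] = "none"
    data.acquisition["encoding"] = "raw"
    data.acquisition["ad_sampling_rate"] = 40e6
    data.acquisition["acquisition_wavelengths"] = np.linspace(
        700e-9, 800e-9, n_wavelengths)
    data.acquisition["field_of_view"] = np.asarray(device.field_of_view)
    data.acquisition["speed_of_sound"] = 1500.0
    data.acquisition["scanning_method"] = "full_scan"
    data.acquisition["measurements_per_image"] = 1
    data.acquisition["device_reference_uuid"] = device.uuid
    return data


@pytest.fixture
def complete_padata():
    return make_complete_padata()


@pytest.fixture
def padata_factory():
    return make_complete_padata
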