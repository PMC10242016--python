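import numpy as np
import pytest

from ctistim import cti_recon, phantom

# A small phantom shared across test modules (pristine; copy before
# attaching electrodes).
SMALL = dict(
    outer_radius_mm=40.0,
    layer_thicknesses={"scalp": 4.0, "skull": 4.0, "CSF": 3.0, "GM": 4.0},
    voxel_size_mm=2.5,
)


@pytest.fixture(scope="session")
def small_labels():
    return phantom.make_layered_sphere_phantom(**SMALL)


@pytest.fixture(scope="session")
def small_maps(small_labels):
    return phantom.make_microstructure_maps(small_labels, fiber_model="radial")


@pytest.fixture(scope="session")
def small_truth(small_maps):
    """(D_e^w, C) ground-truth tensor maps for the small phantom."""
    return phantom.ground_truth_tensors(small_maps)


@pytest.fixture(scope="session")
def small_dwi(small_maps, small_truth):
    D_true, _ = small_truth
    return phantom.simulate_dwi(small_maps, D_true)


@pytest.fixture(scope="session")
def small_fit(small_dwi):
    return cti_recon.fit_two_compartment(small_dwi)
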