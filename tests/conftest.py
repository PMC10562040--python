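"""Shared fixtures: tissue library, calibration products, small phantoms."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spectral_spr.spectral_calibration import (
    evaluate_all_pairs,
    find_optimal_pairs,
    sect_calibrate,
)
from spectral_spr.tissue_library import (
    BetheConstants,
    TissueSurrogate,
    load_gammex_library,
)
from spectral_spr.vm_forward_model import (
    DEFAULT_VM_ENERGIES,
    pediatric_phantom_spec,
    rasterize_phantom,
    simulate_sect_hu,
    vm_means_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def constants() -> BetheConstants:
    return BetheConstants()


@pytest.fixture(scope="session")
def library() -> list[TissueSurrogate]:
    return load_gammex_library()


@pytest.fixture(scope="session")
def by_name(library) -> dict[str, TissueSurrogate]:
    return {t.name: t for t in library}


@pytest.fixture(scope="session")
def water() -> TissueSurrogate:
    return TissueSurrogate(
        name="water",
        elemental_fractions={"H": 0.1119, "O": 0.8881},
        mass_density=1.0,
        reference_red=1.0,
        reference_spr=1.0,
        group="soft",
    )


@pytest.fixture(scope="session")
def vm_means(library):
    return vm_means_table(library, DEFAULT_VM_ENERGIES)


@pytest.fixture(scope="session")
def pair_models(library, vm_means):
    return evaluate_all_pairs(vm_means, library)


@pytest.fixture(scope="session")
def anchors(library):
    return {t.name: simulate_sect_hu(t) for t in library}


@pytest.fixture(scope="session")
def lut(pair_models, library, anchors):
    return find_optimal_pairs(pair_models, library, anchors)


@pytest.fixture(scope="session")
def sect_cal(library, anchors):
    return sect_calibrate(
        [anchors[t.name] for t in library],
        [t.reference_spr for t in library],
        [t.group for t in library],
    )


@pytest.fixture(scope="session")
def noiseless_phantom(library):
    """Small noiseless four-region thorax phantom with a short energy list."""
    spec = pediatric_phantom_spec(
        grid_shape=(48, 48, 24), spacing=(4.0, 4.0, 4.0), noise_sd=0.0, seed=0
    )
    return rasterize_phantom(spec, library, DEFAULT_VM_ENERGIES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
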