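"""Shared fixtures: study conditions and one expensive synthetic study."""

from dataclasses import replace

import numpy as np
import pytest

import aptafield as af

#: standard study conditions: 0.1 M 1:1 salt, 300 K, water
@pytest.fixture(scope="session")
def electrolyte():
    return af.ElectrolyteModel()


@pytest.fixture(scope="session")
def point_ion_electrolyte():
    """Point-ion (nu = 0) electrolyte for Gouy-Chapman limits."""
    return af.ElectrolyteModel(ion_radius=0.0)


@pytest.fixture(scope="session")
def layer():
    """Default 1 + 14 + 1.6 nm film at sigma = 1e12 cm^-2, ions excluded."""
    return af.LayerModel()


@pytest.fixture(scope="session")
def sparse_layer(layer):
    return replace(layer, grafting_density=1e11)


@pytest.fixture(scope="session")
def bare_interface(layer):
    """No fixed charge, ions everywhere: the classic double-layer limit."""
    return replace(layer, grafting_density=0.0, exclude_ions=False)


@pytest.fixture(scope="session")
def settings():
    return af.SolverSettings()


@pytest.fixture(scope="session")
def coarse_settings():
    """2x coarser grid for tests that only need qualitative structure."""
    return af.SolverSettings(grid_spacing=0.01)


# ---- synthetic umbrella-sampling study (shared; expensive to regenerate) ----

@pytest.fixture(scope="session")
def true_pmf():
    """Double-well binding PMF, deep well 20 kBT at 1.6 nm, plateau at 0."""
    return af.TruePMF.double_well()


@pytest.fixture(scope="session")
def study_windows(true_pmf):
    """42 windows x 5000 samples, k = 1000 kJ/mol/nm^2, fixed seed."""
    return af.generate_windows(true_pmf, af.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def wham_result(study_windows):
    return af.wham_solve(study_windows, n_bins=100, temperature=300.0)


BOUND_REGION = (1.2, 2.0)
UNBOUND_REGION = (3.2, 4.0)


@pytest.fixture(scope="session")
def regions():
    return BOUND_REGION, UNBOUND_REGION


def pmf_vs_true_rmse_kBT(pmf: af.PMFProfile, true: af.TruePMF,
                         min_count: float = 100.0) -> float:
    """RMSE (kBT) between a recovered and the true PMF on well-occupied bins,
    after referencing both to their unbound-plateau mean."""
    kT = af.kBT(300.0)
    mask = pmf.occupied & (pmf.counts > min_count)
    plat = mask & (pmf.bin_centers >= UNBOUND_REGION[0]) \
                & (pmf.bin_centers <= UNBOUND_REGION[1])
    est = pmf.pmf - np.mean(pmf.pmf[plat])
    ref = true(pmf.bin_centers) - np.mean(true(pmf.bin_centers)[plat])
    return float(np.sqrt(np.mean((est[mask] - ref[mask]) ** 2)) / kT)
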