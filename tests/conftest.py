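"""Shared fixtures: one small synthetic head reused across the suite."""

import numpy as np
import pytest

from megbayes import (
    build_synthetic_head,
    compute_leadfield,
    green_smoother,
    msp_library,
    select_patch_centers,
)
from megbayes.reduction import reduce_model, spatial_projector, temporal_projector
from megbayes.simulator import SimulationSpec, select_dipole_locations, simulate


@pytest.fixture(scope="session")
def small_head():
    """642-vertex wrinkled head with 60 sensors (seconds to build)."""
    mesh, sensors = build_synthetic_head(
        n_vertices=642, n_sensors=60, cortex_radius_mm=71.0,
        conductor_radius_mm=95.0, seed=7)
    return mesh, sensors


@pytest.fixture(scope="session")
def small_leadfield(small_head):
    mesh, sensors = small_head
    return compute_leadfield(mesh, sensors)


@pytest.fixture(scope="session")
def small_centers(small_head):
    mesh, _ = small_head
    return select_patch_centers(mesh, 24, seed=1)


@pytest.fixture(scope="session")
def small_smoother(small_head, small_centers):
    mesh, _ = small_head
    return green_smoother(mesh, 0.6, columns=small_centers)


@pytest.fixture(scope="session")
def small_library(small_head, small_smoother, small_centers):
    mesh, _ = small_head
    return msp_library(small_smoother, small_centers, include_bilateral=False,
                       mesh=mesh)


@pytest.fixture(scope="session")
def small_locations(small_leadfield, small_centers):
    return select_dipole_locations(small_leadfield, small_centers,
                                   n_locations=16, n_candidate_sets=500,
                                   seed=2)


@pytest.fixture(scope="session")
def small_projector(small_leadfield):
    return spatial_projector(small_leadfield)


def make_model(mesh, L, centers, locations, U, snr_db=0.0, seed=0,
               n_trials=50, **spec_kw):
    """Simulate one dataset and reduce it (helper, not a fixture)."""
    spec = SimulationSpec(snr_db=snr_db, seed=seed, n_trials=n_trials,
                          **spec_kw)
    ds = simulate(spec, mesh, L, centers, locations=locations)
    T = temporal_projector(np.einsum("un,tns->tus", U, ds.epochs))
    model = reduce_model(ds.epochs, U, T, L, fs_hz=spec.fs_hz)
    return ds, model
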