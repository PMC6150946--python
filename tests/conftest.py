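"""Shared fixtures: default geometry, lead fields, and small cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

import opmlat as o


@pytest.fixture(scope="session")
def array() -> o.SensorArray:
    return o.default_sensor_array()


@pytest.fixture(scope="session")
def sphere(array) -> o.ConductorSphere:
    return o.fit_conductor_sphere(array.positions[array.scalp_indices])


@pytest.fixture(scope="session")
def grid(sphere) -> o.SourceGrid:
    roi = o.ROISpec("IFG_left", np.array(o.DEFAULT_SOURCE_MM), 20.0)
    return o.build_source_grid(sphere, 10.0, roi_specs=[roi, roi.mirrored("IFG_right")])


@pytest.fixture(scope="session")
def leadfields(array, grid, sphere) -> o.LeadFieldSet:
    return o.compute_leadfields(array, grid, sphere)


@pytest.fixture(scope="session")
def coarse_grid(sphere) -> o.SourceGrid:
    """<= 100 points, for brute-force oracle comparisons."""
    roi = o.ROISpec("IFG_left", np.array(o.DEFAULT_SOURCE_MM), 25.0)
    g = o.build_source_grid(sphere, 25.0, roi_specs=[roi, roi.mirrored("IFG_right")])
    assert g.n_points <= 100
    return g


@pytest.fixture(scope="session")
def coarse_leadfields(array, coarse_grid, sphere) -> o.LeadFieldSet:
    return o.compute_leadfields(array, coarse_grid, sphere)


def _simulate(leadfields, return_components=False, **kwargs):
    defaults = dict(n_trials=20, seed=7)
    defaults.update(kwargs)
    truth = o.SimulationTruth(**defaults)
    return o.simulate_dataset(
        truth, leadfields.array, leadfields, return_components=return_components
    )


@pytest.fixture(scope="session")
def small_dataset(leadfields) -> o.TrialDataset:
    """20 trials, default depth-0.4 left-IFG source."""
    return _simulate(leadfields)


@pytest.fixture(scope="session")
def small_clean(small_dataset) -> o.TrialDataset:
    ds = o.downsample_and_filter(small_dataset)
    ds, _ = o.synthetic_gradiometry(ds)
    return ds


@pytest.fixture(scope="session")
def small_filtered(small_clean) -> o.TrialDataset:
    return o.band_filter(small_clean)


@pytest.fixture(scope="session")
def simulate_factory(leadfields):
    """Callable fixture for one-off simulation variants.

    Pass ``return_components=True`` to also get the stored brain /
    interference / noise components for oracle recomputation.
    """

    def factory(**kwargs):
        return _simulate(leadfields, **kwargs)

    return factory
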