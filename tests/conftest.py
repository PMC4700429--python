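"""Shared fixtures: the toy genome study conditions and reusable ensembles.

Heavy Monte Carlo fixtures are session-scoped so the expensive computations
(calibration, the 50-structure constraint-suite ensemble, the anchored
pipeline ensemble) run once per test session.
"""

import numpy as np
import pytest

import pombe3d as p3
from pombe3d.contacts import contacts_from_records
from pombe3d.synthetic import SyntheticConfig, make_contacts, make_genome


@pytest.fixture(scope="session")
def cfg():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def genome(cfg):
    return make_genome(cfg)


@pytest.fixture(scope="session")
def partition(genome):
    return p3.build_partition(genome)


@pytest.fixture(scope="session")
def geometry():
    return p3.NuclearGeometry()


@pytest.fixture(scope="session")
def anchors(genome, partition):
    return p3.build_anchors(genome, partition)


@pytest.fixture(scope="session")
def contact_set(genome, cfg, partition):
    return contacts_from_records(make_contacts(genome, cfg), partition)


@pytest.fixture(scope="session")
def fast_params():
    """Short anneal for unit tests of mechanics (not of converged physics)."""
    return p3.EnergyParams(n_temps=8, sweeps_per_temp=20)


@pytest.fixture(scope="session")
def small_ensemble(partition, geometry, anchors, contact_set, fast_params):
    """8 anchored contact-restrained structures, quick schedule."""
    return p3.generate_ensemble(
        8, partition, geometry, anchors, contact_set,
        p3.SubsetSpec(fraction=0.02, seed=3), fast_params,
        master_seed=3, enforce_coverage=False,
    )


@pytest.fixture(scope="session")
def calibration(contact_set, geometry):
    """Calibrated subset fraction against the 650 nm compaction target."""
    fraction, history = p3.calibrate_fraction(
        contact_set, 650.0, geometry=geometry, n_structures=20, seed=1,
        full_output=True,
    )
    return fraction, history


@pytest.fixture(scope="session")
def pipeline_ensemble(partition, geometry, anchors, contact_set, calibration):
    """Anchored production-style ensemble at the calibrated fraction."""
    fraction, _ = calibration
    return p3.generate_ensemble(
        30, partition, geometry, anchors, contact_set,
        p3.SubsetSpec(fraction=fraction, seed=1), p3.EnergyParams(),
        master_seed=11, enforce_coverage=False,
    )
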