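"""Conformation initialization, energy terms, Monte Carlo and ensembles."""

import numpy as np
import pytest

import pombe3d as p3
from pombe3d.exceptions import ConfigurationError, InitializationError
from pombe3d.genome import AnchorSet, ChromosomeSpec, NuclearGeometry, build_partition
from pombe3d.sampler import (
    EnergyParams,
    check_invariants,
    init_conformation,
    mc_optimize,
    radius_of_gyration,
    total_energy,
)


@pytest.fixture(scope="module")
def chain10():
    c = ChromosomeSpec("c", 35_000, (14_000, 17_500), ((0, 3500), (31_500, 35_000)))
    return build_partition([c], 3500)  # 10 granules


def test_init_feasible_and_deterministic(chain10, geometry):
    a = init_conformation(chain10, geometry, seed=5)
    b = init_conformation(chain10, geometry, seed=5)
    assert np.array_equal(a.coords, b.coords)
    assert all(v == 0 for v in check_invariants(a, chain10, geometry).values())
    # bonds exactly one granule diameter at initialization
    blen = np.linalg.norm(a.coords[1:] - a.coords[:-1], axis=1)
    assert np.allclose(blen, 30.0)


def test_init_infeasible_geometry(chain10):
    geom = NuclearGeometry(nucleolus_radius=1280.0)
    with pytest.raises(InitializationError):
        init_conformation(chain10, geom, seed=0)


def test_total_energy_ground_state_terms(chain10, geometry):
    """A straight chain at rest bond length inside the nucleus has zero bond,
    bending and contact energy."""
    coords = np.zeros((10, 3))
    coords[:, 0] = np.arange(10) * 30.0 + 200.0  # along +x, inside nucleus
    e = total_energy(
        coords, EnergyParams(), np.array([[0, 5]]), AnchorSet.empty(), geometry, chain10
    )
    assert e.bond == 0.0
    assert e.bending == pytest.approx(0.0, abs=1e-12)
    assert e.confinement == 0.0
    # contact pair 0-5 at distance 150 > rest 45
    k = EnergyParams().k_contact
    assert e.contact == pytest.approx(0.5 * k * (150.0 - 45.0) ** 2)


def test_total_energy_confinement_quadratic(chain10, geometry):
    params = EnergyParams()
    c = ChromosomeSpec("c", 3000, (1000, 2000), ((0, 100), (2900, 3000)))
    part1 = build_partition([c], 3500)  # single granule
    delta = 50.0
    coords = np.array([[0.0, 0.0, geometry.nuclear_radius - geometry.granule_radius + delta]])
    e = total_energy(coords, params, None, AnchorSet.empty(), geometry, part1)
    assert e.confinement == pytest.approx(0.5 * params.k_confinement * delta**2)
    inside = np.array([[0.0, 0.0, 500.0]])
    e2 = total_energy(inside, params, None, AnchorSet.empty(), geometry, part1)
    assert e2.confinement == 0.0
    # nucleolar exclusion
    at_nucleolus = np.array([geometry.nucleolus_center])
    e3 = total_energy(at_nucleolus, params, None, AnchorSet.empty(), geometry, part1)
    pen = geometry.nucleolus_radius + geometry.granule_radius
    assert e3.nucleolus == pytest.approx(0.5 * params.k_confinement * pen**2)


def test_zero_sweeps_returns_input(chain10, geometry):
    conf = init_conformation(chain10, geometry, seed=2)
    params = EnergyParams(sweeps_per_temp=0)
    out = mc_optimize(conf, params, None, AnchorSet.empty(), geometry, chain10, seed=9)
    assert np.array_equal(out.coords, conf.coords)


def test_mc_energy_not_increased(chain10, geometry):
    """Annealing a chain with substantial restraint energy does not end
    above its initial energy."""
    empty = AnchorSet.empty()
    params = EnergyParams(k_contact=0.01, n_temps=8, sweeps_per_temp=20)
    pairs = np.array([[0, 7], [2, 9]])
    for seed in range(5):
        conf = init_conformation(chain10, geometry, seed=seed)
        e0 = total_energy(conf, params, pairs, empty, geometry, chain10).total
        out = mc_optimize(conf, params, pairs, empty, geometry, chain10, seed=seed + 50)
        assert out.energy <= e0 + 1e-9


def test_tether_descent_two_granules(geometry):
    """A two-granule chromosome tethered to the SPB zone ends inside it."""
    c = ChromosomeSpec("c", 7000, (3000, 3500), ((0, 100), (6900, 7000)))
    part = build_partition([c], 3500)
    anch = AnchorSet.from_tuples([(0, "SPB_zone", 0.05)])
    conf = init_conformation(part, geometry, seed=1, anchors=anch)
    out = mc_optimize(conf, EnergyParams(), None, anch, geometry, part, seed=2)
    d_spb = np.linalg.norm(out.coords[0] - geometry.spb_position)
    assert d_spb <= geometry.spb_zone_radius * 1.05


def test_contact_closure_high_spring(chain10, geometry):
    """A single strong contact spring pulls the pair to its rest length."""
    params = EnergyParams(k_contact=0.01)
    pairs = np.array([[1, 8]])
    conf = init_conformation(chain10, geometry, seed=3)
    out = mc_optimize(conf, params, pairs, AnchorSet.empty(), geometry, chain10, seed=4)
    d = np.linalg.norm(out.coords[1] - out.coords[8])
    assert d <= params.contact_rest * 1.1


def test_free_diffusion_detailed_balance(chain10, geometry):
    """With all energy scales zero and hard constraints off, every move is
    accepted and granules diffuse (MSD grows with sweeps)."""
    free = dict(
        k_bond=0, persistence=0, k_excluded=0, k_confinement=0, k_contact=0,
        hard_constraints=False, n_temps=1, t_start=1.0, crank_prob=0.0,
        pivot_prob=0.0,
    )
    conf = init_conformation(chain10, geometry, seed=6)
    msds = []
    for sweeps in (10, 80):
        params = EnergyParams(sweeps_per_temp=sweeps, **free)
        out = mc_optimize(conf, params, None, AnchorSet.empty(), geometry, chain10, seed=7)
        assert out.acceptance == 1.0
        msds.append(np.mean(np.sum((out.coords - conf.coords) ** 2, axis=1)))
    assert msds[1] > msds[0] > 0


def test_radius_of_gyration_closed_forms():
    assert radius_of_gyration(np.zeros((4, 3))) == 0.0
    two = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    assert radius_of_gyration(two) == pytest.approx(5.0)
    a = 2.0
    corners = np.array(
        [[x, y, z] for x in (0, a) for y in (0, a) for z in (0, a)], dtype=float
    )
    assert radius_of_gyration(corners) == pytest.approx(a * np.sqrt(3) / 2)
    with pytest.raises(ConfigurationError):
        radius_of_gyration(np.empty((0, 3)))


def test_generate_ensemble_reproducible(partition, geometry, anchors, contact_set, fast_params):
    kw = dict(
        n_structures=2, partition=partition, geometry=geometry, anchors=anchors,
        contact_set=contact_set, spec=p3.SubsetSpec(fraction=0.02, seed=5),
        params=fast_params, master_seed=99,
    )
    a = p3.generate_ensemble(**kw)
    b = p3.generate_ensemble(**kw)
    assert np.array_equal(a.coords, b.coords)
    assert len({s.seed for s in a.structures}) == 2


def test_contact_model_more_compact_than_random(
    partition, geometry, anchors, contact_set, fast_params
):
    contact = p3.generate_ensemble(
        5, partition, geometry, anchors, contact_set,
        p3.SubsetSpec(fraction=0.10, seed=2), fast_params, master_seed=21,
    )
    rand = p3.generate_ensemble(
        5, partition, geometry, None, None, None, fast_params,
        master_seed=21, model_kind="random",
    )
    assert rand.model_kind == "random" and len(rand.anchors) == 0
    assert np.mean(contact.radii_of_gyration()) < np.mean(rand.radii_of_gyration())


def test_rabl_configuration(small_ensemble, genome, partition):
    """With anchors active, SPB-centromere distances are stochastically
    smaller than SPB-telomere distances."""
    from pombe3d.density import spb_distance_distribution

    cen = [
        partition.bp_to_granule(c.name, (c.centromere[0] + c.centromere[1]) // 2)
        for c in genome
    ]
    tel = [partition.bp_to_granule(c.name, 0) for c in genome] + [
        partition.bp_to_granule(c.name, c.length - 1) for c in genome
    ]
    d_cen = np.concatenate([spb_distance_distribution(small_ensemble, g) for g in cen])
    d_tel = np.concatenate([spb_distance_distribution(small_ensemble, g) for g in tel])
    assert np.median(d_cen) < np.median(d_tel)
    assert d_cen.mean() < d_tel.mean()


def test_small_ensemble_invariants(small_ensemble, partition, geometry):
    for s in small_ensemble.structures:
        assert all(v == 0 for v in check_invariants(s, partition, geometry).values())


def test_ensemble_hdf5_and_xyz_roundtrip(small_ensemble, partition, geometry, tmp_path):
    path = tmp_path / "ens.h5"
    small_ensemble.to_hdf5(path)
    back = p3.Ensemble.from_hdf5(path, partition, geometry)
    assert np.allclose(back.coords, small_ensemble.coords)
    assert back.model_kind == small_ensemble.model_kind
    xyz = tmp_path / "ens.xyz"
    small_ensemble.to_xyz(xyz)
    text = xyz.read_text().splitlines()
    assert text[0] == str(partition.n_granules)
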