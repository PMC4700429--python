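"""Rotational projection, kernel density grids, contours, differences, impact."""

import numpy as np
import pytest

from pombe3d.density import (
    DEFAULT_DEMPF,
    DensityGrid,
    RelativeDensityMap,
    compare_distance_distributions,
    density_map,
    difference_map,
    granule_impact,
    project,
    relative_density,
    spb_distance_distribution,
    top_signal_contour,
)
from pombe3d.exceptions import ConfigurationError
from pombe3d.genome import NuclearGeometry
from pombe3d.sampler import Conformation, Ensemble
from pombe3d.genome import AnchorSet


GEOM = NuclearGeometry()
R = GEOM.nuclear_radius


def test_project_examples():
    coords = np.array(
        [
            [0.0, 0.0, 0.0],      # nuclear centre
            [0.0, 0.0, R],        # at the SPB
            [300.0, 400.0, 250.0],
        ]
    )
    z, r = project(coords, GEOM)
    assert z[0] == 0 and r[0] == 0
    assert z[1] == pytest.approx(R) and r[1] == 0
    assert z[2] == pytest.approx(250.0)
    assert r[2] == pytest.approx(500.0)  # 3-4-5 triangle


def _ens(coords_list, geometry=GEOM):
    structures = [
        Conformation(coords=np.asarray(c, dtype=float), seed=i)
        for i, c in enumerate(coords_list)
    ]
    part = None
    ens = Ensemble.__new__(Ensemble)
    ens.structures = structures
    ens.partition = part
    ens.geometry = geometry
    ens.anchors = AnchorSet.empty()
    ens.model_kind = "synthetic"
    ens.subsets = []
    ens.provenance = {}
    return ens


def test_single_granule_gaussian_peak():
    """One granule at a pixel centre: that pixel reads ~1 and neighbours decay
    by the Gaussian factor."""
    grid0 = density_map(_ens([np.zeros((1, 3))]), npix=266)
    iz = np.argmin(np.abs(grid0.z_centers))
    ir = 0
    zc, rc = grid0.z_centers[iz], grid0.r_centers[ir]
    conf = np.array([[0.0, rc, zc]])  # r = rc exactly, z = zc exactly
    grid = density_map(_ens([conf]), npix=266, sigma=15.0)
    assert grid.values[iz, ir] == pytest.approx(1.0)
    dz = grid.delta_z
    expected = np.exp(-(dz**2) / (2 * 15.0**2))
    assert grid.values[iz + 1, ir] == pytest.approx(expected, rel=1e-9)


def test_density_zero_weights_and_averaging():
    conf = np.array([[100.0, 50.0, -200.0], [0.0, 300.0, 400.0]])
    zeros = density_map(_ens([conf]), weights=np.zeros(2))
    assert np.all(zeros.values == 0)
    one = density_map(_ens([conf]))
    two = density_map(_ens([conf, conf.copy()]))
    assert np.allclose(one.values, two.values)  # normalised by N_structures
    assert two.n_structures == 2


def test_density_weight_length_mismatch():
    conf = np.zeros((2, 3))
    with pytest.raises(Exception):
        density_map(_ens([conf]), weights=np.ones(3))


def test_kernel_linearity_exact():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-700, 700, size=(12, 3))
    w1 = rng.random(12)
    w2 = rng.random(12)
    ens = _ens([coords])
    m12 = density_map(ens, w1 + w2)
    m1 = density_map(ens, w1)
    m2 = density_map(ens, w2)
    assert np.allclose(m12.values, m1.values + m2.values, rtol=1e-9, atol=1e-12)


def test_mass_conservation_against_untruncated():
    """Pixel sum x pixel area matches n_granules x 2*pi*sigma^2 for interior
    granules, and truncation at 4 sigma changes the mass by < 0.1%."""
    rng = np.random.default_rng(1)
    n = 40
    z = rng.uniform(-1100, 1100, size=n)
    r = rng.uniform(100, 1100, size=n)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    coords = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    ens = _ens([coords])
    sigma = 15.0
    trunc = density_map(ens, sigma=sigma, truncate=4.0)
    full = density_map(ens, sigma=sigma, truncate=None)
    area = trunc.delta_z * trunc.delta_r
    mass_t = trunc.values.sum() * area
    mass_f = full.values.sum() * area
    assert abs(mass_t - mass_f) / mass_f < 1e-3
    assert mass_f == pytest.approx(n * 2 * np.pi * sigma**2, rel=5e-3)


def test_rotational_invariance():
    rng = np.random.default_rng(2)
    coords = rng.uniform(-600, 600, size=(15, 3))
    theta = 1.1
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ]
    )
    a = density_map(_ens([coords]))
    b = density_map(_ens([coords @ rot.T]))
    assert np.allclose(a.values, b.values, atol=1e-9)


def test_relative_density_arithmetic():
    elem = DensityGrid(values=np.full((4, 4), 2.0), nuclear_radius=R)
    total = DensityGrid(values=np.full((4, 4), 4.0), nuclear_radius=R)
    rel = relative_density(elem, total, dempf=1.33)
    assert np.allclose(rel.values, 2.0 / 5.33)
    ident = relative_density(total, total, dempf=0.0)
    assert np.allclose(ident.values, 1.0)
    zero = relative_density(
        DensityGrid(values=np.zeros((4, 4)), nuclear_radius=R), total, dempf=1.33
    )
    assert np.all(zero.values == 0)


def test_relative_density_shape_mismatch():
    a = DensityGrid(values=np.zeros((4, 4)), nuclear_radius=R)
    b = DensityGrid(values=np.zeros((5, 5)), nuclear_radius=R)
    with pytest.raises(ConfigurationError):
        relative_density(a, b)


def _rdm(values):
    return RelativeDensityMap(values=np.asarray(values, dtype=float), nuclear_radius=R)


def test_contour_uniform_map():
    m = _rdm(np.ones((20, 20)))
    cm = top_signal_contour(m, 0.15)
    assert abs(cm.n_pixels - 60) <= 1  # 15% of 400 pixels
    assert cm.enclosed_fraction >= 0.15


def test_contour_single_hot_pixel():
    v = np.ones((10, 10))
    v[3, 4] = 25.0  # 25 / 124 ~ 20% of the signal, above the 15% cut
    cm = top_signal_contour(_rdm(v), 0.15)
    assert cm.n_pixels == 1
    assert cm.mask[3, 4]


def test_contour_nesting_and_zero_map():
    rng = np.random.default_rng(3)
    m = _rdm(rng.random((30, 30)))
    inner = top_signal_contour(m, 0.10)
    outer = top_signal_contour(m, 0.15)
    assert np.all(outer.mask[inner.mask])  # nesting
    with pytest.warns(UserWarning):
        empty = top_signal_contour(_rdm(np.zeros((5, 5))), 0.15)
    assert empty.n_pixels == 0


def test_difference_map_properties():
    a = _rdm(np.full((3, 3), 0.30))
    b = _rdm(np.full((3, 3), 0.20))
    d = difference_map(a, b)
    assert np.allclose(d, 10.0)  # percentage points
    assert np.allclose(difference_map(b, a), -d)  # antisymmetry
    assert np.allclose(difference_map(a, a), 0.0)


def test_granule_impact_identical_ensembles_zero():
    rng = np.random.default_rng(4)
    coords = [rng.uniform(-600, 600, size=(6, 3)) for _ in range(3)]
    a = _ens(coords)
    b = _ens([c.copy() for c in coords])
    w = np.ones(6)
    with pytest.warns(UserWarning):  # no pixel changes sign -> empty selection
        prof = granule_impact(a, b, w, GEOM, npix=64)
    assert np.all(prof.values == 0)


def test_per_granule_decomposition_linearity():
    """Summing single-granule density maps reproduces the all-ones map."""
    rng = np.random.default_rng(5)
    coords = [rng.uniform(-500, 500, size=(7, 3)) for _ in range(2)]
    ens = _ens(coords)
    total = density_map(ens, npix=64)
    acc = np.zeros_like(total.values)
    for g in range(7):
        w = np.zeros(7)
        w[g] = 1.0
        acc += density_map(ens, w, npix=64).values
    assert np.allclose(acc, total.values, rtol=1e-9, atol=1e-12)


def test_spb_distance_distribution():
    conf = np.zeros((2, 3))  # both granules at the nuclear centre
    ens = _ens([conf])
    d = spb_distance_distribution(ens, 0)
    assert d.shape == (1,)
    assert d[0] == pytest.approx(R)
    with pytest.raises(ConfigurationError):
        spb_distance_distribution(ens, 5)


def test_compare_distance_distributions():
    rng = np.random.default_rng(6)
    a = rng.normal(500, 50, 400)
    out = compare_distance_distributions(a, a + 0.0)
    assert out["ks_statistic"] < 0.05
    assert out["overlap_coefficient"] > 0.9
    far = compare_distance_distributions(a, a + 500)
    assert far["overlap_coefficient"] < 0.2
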