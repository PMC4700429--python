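"""Rotational-projection density maps, contours, difference maps and impact profiles.

Interphase fission-yeast nuclei are approximately rotationally symmetric
about the SPB-nucleolus axis, so an ensemble of 3D structures is summarised
by projecting every granule onto the (z, r) half-plane — z the signed
position along the axis (SPB side positive), r the distance from the axis —
and accumulating a Gaussian kernel density on a 266 x 266 pixel grid.
Element densities are normalised by total chromatin density (with the small
additive regulariser Dempf) to remove global compaction effects; contour
masks collect the highest-valued pixels holding a fixed fraction of the
total signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .exceptions import ConfigurationError, FeatureError
from .genome import NuclearGeometry

__all__ = [
    "ProjectedGranule",
    "DensityGrid",
    "RelativeDensityMap",
    "ContourMask",
    "ImpactProfile",
    "project",
    "density_map",
    "relative_density",
    "top_signal_contour",
    "difference_map",
    "granule_impact",
    "spb_distance_distribution",
    "compare_distance_distributions",
    "DEFAULT_NPIX",
    "DEFAULT_SIGMA",
    "DEFAULT_DEMPF",
    "DEFAULT_CONTOUR_FRACTION",
    "DEFAULT_IMPACT_RADIUS",
]

DEFAULT_NPIX = 266
DEFAULT_SIGMA = 15.0  # nm; the granule radius
DEFAULT_DEMPF = 1.33  # density of one granule at the nuclear periphery
DEFAULT_CONTOUR_FRACTION = 0.15
DEFAULT_IMPACT_RADIUS = 670.0  # nm from the SPB-nucleolus axis


@dataclass(frozen=True)
class ProjectedGranule:
    """Cylindrical projection of one granule: z along the axis, r from it (nm)."""

    z: float
    r: float


def project(conf, geometry: NuclearGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Project granule centres onto (z, r): z = x . axis, r = |x - z axis|.

    Accepts a Conformation or a raw (n, 3) array; returns (z, r) arrays.
    """
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf, dtype=float)
    axis = geometry.axis
    z = coords @ axis
    perp = coords - np.outer(z, axis)
    r = np.linalg.norm(perp, axis=1)
    return z, r


@dataclass
class DensityGrid:
    """Ensemble-averaged kernel density on the (z, r) grid.

    ``values[iz, ir]`` covers z in [-R, R] and r in [0, R] with pixel sizes
    ``delta_z = 2R/npix`` and ``delta_r = R/npix``; the kernel is an isotropic
    2D Gaussian of width ``sigma`` evaluated at pixel centres and truncated at
    ``truncate`` sigma (untruncated when None).
    """

    values: np.ndarray
    nuclear_radius: float
    sigma: float = DEFAULT_SIGMA
    n_structures: int = 1
    truncate: float | None = 4.0

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ConfigurationError("density grid must be square")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ConfigurationError("density values must be finite and >= 0")

    @property
    def npix(self) -> int:
        return self.values.shape[0]

    @property
    def delta_z(self) -> float:
        return 2.0 * self.nuclear_radius / self.npix

    @property
    def delta_r(self) -> float:
        return self.nuclear_radius / self.npix

    @property
    def z_centers(self) -> np.ndarray:
        return -self.nuclear_radius + (np.arange(self.npix) + 0.5) * self.delta_z

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.npix) + 0.5) * self.delta_r

    def congruent_with(self, other: "DensityGrid") -> bool:
        return (
            self.npix == other.npix
            and np.isclose(self.nuclear_radius, other.nuclear_radius)
        )


def _accumulate_kernel(grid, z_centers, r_centers, z, r, w, sigma, truncate):
    """Add w * Gaussian(z - zc, r - rc) for one granule occurrence."""
    if truncate is None:
        gz = np.exp(-((z_centers - z) ** 2) / (2 * sigma**2))
        gr = np.exp(-((r_centers - r) ** 2) / (2 * sigma**2))
        grid += w * np.outer(gz, gr)
        return
    cut = truncate * sigma
    npix = len(z_centers)
    dz = z_centers[1] - z_centers[0]
    dr = r_centers[1] - r_centers[0]
    iz0 = max(0, int(np.floor((z - cut - z_centers[0]) / dz)))
    iz1 = min(npix, int(np.ceil((z + cut - z_centers[0]) / dz)) + 1)
    ir0 = max(0, int(np.floor((r - cut - r_centers[0]) / dr)))
    ir1 = min(npix, int(np.ceil((r + cut - r_centers[0]) / dr)) + 1)
    if iz0 >= iz1 or ir0 >= ir1:
        return
    gz = np.exp(-((z_centers[iz0:iz1] - z) ** 2) / (2 * sigma**2))
    gr = np.exp(-((r_centers[ir0:ir1] - r) ** 2) / (2 * sigma**2))
    gz[np.abs(z_centers[iz0:iz1] - z) > cut] = 0.0
    gr_mask = np.abs(r_centers[ir0:ir1] - r) > cut
    gr[gr_mask] = 0.0
    grid[iz0:iz1, ir0:ir1] += w * np.outer(gz, gr)


def density_map(
    ensemble,
    weights=None,
    geometry: NuclearGeometry | None = None,
    npix: int = DEFAULT_NPIX,
    sigma: float = DEFAULT_SIGMA,
    truncate: float | None = 4.0,
) -> DensityGrid:
    """Ensemble-averaged projected density of weighted granules.

    ``D(pixel) = (1/N_structures) * sum_structures sum_granules
    w_g * exp(-((z_g - z_p)^2 + (r_g - r_p)^2) / (2 sigma^2))``.

    ``weights`` is one number per granule (a GranuleSignal, an array, or None
    for all-ones); one isolated granule therefore contributes a peak density
    of ~1 per structure it appears in.  ``ensemble`` may be an Ensemble, a
    list of conformations, or an (S, n, 3) coordinate array.
    """
    if geometry is None:
        geometry = ensemble.geometry
    structures = getattr(ensemble, "structures", ensemble)
    coords_list = [
        s.coords if hasattr(s, "coords") else np.asarray(s, dtype=float)
        for s in structures
    ]
    n_granules = coords_list[0].shape[0]
    if weights is None:
        w = np.ones(n_granules)
    else:
        w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if len(w) != n_granules:
        raise FeatureError(
            f"weights length {len(w)} != number of granules {n_granules}"
        )
    R = geometry.nuclear_radius
    grid = np.zeros((npix, npix))
    zc = -R + (np.arange(npix) + 0.5) * (2 * R / npix)
    rc = (np.arange(npix) + 0.5) * (R / npix)
    nz = np.flatnonzero(w != 0)
    for coords in coords_list:
        z, r = project(coords, geometry)
        for g in nz:
            _accumulate_kernel(grid, zc, rc, z[g], r[g], w[g], sigma, truncate)
    grid /= len(coords_list)
    return DensityGrid(
        values=grid, nuclear_radius=R, sigma=sigma,
        n_structures=len(coords_list), truncate=truncate,
    )


@dataclass
class RelativeDensityMap:
    """Element density / (total density + Dempf), pixel-wise."""

    values: np.ndarray
    nuclear_radius: float
    dempf: float = DEFAULT_DEMPF

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ConfigurationError("relative density must be finite and >= 0")

    @property
    def npix(self) -> int:
        return self.values.shape[0]

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.npix) + 0.5) * self.nuclear_radius / self.npix

    @property
    def z_centers(self) -> np.ndarray:
        n = self.npix
        return -self.nuclear_radius + (np.arange(n) + 0.5) * 2 * self.nuclear_radius / n


def relative_density(
    elem: DensityGrid, total: DensityGrid, dempf: float = DEFAULT_DEMPF
) -> RelativeDensityMap:
    """Normalise an element density by total chromatin density plus Dempf.

    Dempf regularises pixels of low absolute density (e.g. the nuclear
    periphery); where the total density is zero the value is elem/Dempf,
    which stays finite.
    """
    if not elem.congruent_with(total):
        raise ConfigurationError("element and total grids are not congruent")
    if dempf < 0:
        raise ConfigurationError("dempf must be >= 0")
    if dempf == 0 and np.any((total.values == 0) & (elem.values > 0)):
        raise ConfigurationError("dempf=0 with zero total density under element signal")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = elem.values / (total.values + dempf)
    vals = np.nan_to_num(vals, nan=0.0)
    return RelativeDensityMap(values=vals, nuclear_radius=elem.nuclear_radius, dempf=dempf)


@dataclass
class ContourMask:
    """Boolean raster of the highest-valued pixels holding >= ``fraction`` of signal."""

    mask: np.ndarray
    fraction: float
    enclosed_fraction: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def top_signal_contour(
    rdmap: RelativeDensityMap, fraction: float = DEFAULT_CONTOUR_FRACTION
) -> ContourMask:
    """Smallest prefix of descending-value pixels enclosing ``fraction`` of signal.

    Ties at the cut are included in stable pixel-index order, so the enclosed
    share exceeds the target by at most one pixel's share.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    flat = rdmap.values.ravel()
    total = flat.sum()
    if total <= 0:
        warnings.warn("top_signal_contour: all-zero map, returning empty mask")
        return ContourMask(
            mask=np.zeros_like(rdmap.values, dtype=bool),
            fraction=fraction, enclosed_fraction=0.0,
        )
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, fraction * total)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return ContourMask(
        mask=mask.reshape(rdmap.values.shape),
        fraction=fraction,
        enclosed_fraction=float(csum[k - 1] / total),
    )


def difference_map(a: RelativeDensityMap, b: RelativeDensityMap) -> np.ndarray:
    """Percentage-point change per pixel: 100 * (a - b).  Antisymmetric."""
    if a.values.shape != b.values.shape:
        raise ConfigurationError("difference_map: maps are not congruent")
    return 100.0 * (a.values - b.values)


@dataclass
class ImpactProfile:
    """Per-granule mean % density change within the region of interest."""

    values: np.ndarray  # one value per granule
    region_radius: float
    sign: str  # "increased" or "decreased"
    n_selected_pixels: int

    def __post_init__(self):
        if np.any(~np.isfinite(self.values)):
            raise ConfigurationError("impact profile must be finite")


def _per_granule_density(projections, g, R, npix, sigma, truncate):
    grid = np.zeros((npix, npix))
    zc = -R + (np.arange(npix) + 0.5) * (2 * R / npix)
    rc = (np.arange(npix) + 0.5) * (R / npix)
    for z, r in projections:
        _accumulate_kernel(grid, zc, rc, z[g], r[g], 1.0, sigma, truncate)
    grid /= len(projections)
    return grid


def granule_impact(
    ens_a,
    ens_b,
    weights,
    geometry: NuclearGeometry | None = None,
    region_radius: float = DEFAULT_IMPACT_RADIUS,
    sign: str = "decreased",
    npix: int = DEFAULT_NPIX,
    sigma: float = DEFAULT_SIGMA,
    dempf: float = DEFAULT_DEMPF,
    truncate: float | None = 4.0,
) -> ImpactProfile:
    """Mean per-granule relative-density change over selected pixels near the axis.

    Pixels are selected once from the aggregate element difference map
    (ensemble A minus ensemble B, weights = the element of interest): those
    within ``region_radius`` of the SPB-nucleolus axis whose aggregate change
    has the requested sign.  Each granule's impact is then the mean of its own
    per-granule difference map over those pixels.
    """
    if sign not in ("increased", "decreased"):
        raise ConfigurationError("sign must be 'increased' or 'decreased'")
    if geometry is None:
        geometry = ens_a.geometry
    kw = dict(geometry=geometry, npix=npix, sigma=sigma, truncate=truncate)
    total_a = density_map(ens_a, None, **kw)
    total_b = density_map(ens_b, None, **kw)
    rel_a = relative_density(density_map(ens_a, weights, **kw), total_a, dempf)
    rel_b = relative_density(density_map(ens_b, weights, **kw), total_b, dempf)
    agg = difference_map(rel_a, rel_b)

    region = total_a.r_centers[None, :] <= region_radius
    region = np.broadcast_to(region, agg.shape)
    sel = region & ((agg > 0) if sign == "increased" else (agg < 0))
    n_granules = ens_a.structures[0].n_granules

    if not sel.any():
        warnings.warn("granule_impact: empty selected-pixel set, profile is zero")
        return ImpactProfile(
            values=np.zeros(n_granules), region_radius=region_radius,
            sign=sign, n_selected_pixels=0,
        )

    proj_a = [project(s, geometry) for s in ens_a.structures]
    proj_b = [project(s, geometry) for s in ens_b.structures]
    R = geometry.nuclear_radius
    denom_a = total_a.values + dempf
    denom_b = total_b.values + dempf
    values = np.empty(n_granules)
    for g in range(n_granules):
        da = _per_granule_density(proj_a, g, R, npix, sigma, truncate) / denom_a
        db = _per_granule_density(proj_b, g, R, npix, sigma, truncate) / denom_b
        values[g] = float(np.mean(100.0 * (da - db)[sel]))
    return ImpactProfile(
        values=values, region_radius=region_radius,
        sign=sign, n_selected_pixels=int(sel.sum()),
    )


def spb_distance_distribution(ensemble, locus: int) -> np.ndarray:
    """Distance from a locus (granule index) to the SPB, one value per structure."""
    geometry = ensemble.geometry
    n = ensemble.structures[0].n_granules
    if not 0 <= locus < n:
        raise ConfigurationError(f"locus {locus} outside partition of {n} granules")
    spb = geometry.spb_position
    return np.array(
        [float(np.linalg.norm(s.coords[locus] - spb)) for s in ensemble.structures]
    )


def compare_distance_distributions(
    sample: np.ndarray, reference: np.ndarray, bins: int = 20
) -> dict:
    """Two-sample comparison: KS statistic plus histogram overlap coefficient."""
    ks = ks_2samp(sample, reference)
    lo = min(sample.min(), reference.min())
    hi = max(sample.max(), reference.max())
    edges = np.linspace(lo, hi, bins + 1)
    h1, _ = np.histogram(sample, bins=edges, density=False)
    h2, _ = np.histogram(reference, bins=edges, density=False)
    ovl = float(np.sum(np.minimum(h1 / h1.sum(), h2 / h2.sum())))
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "overlap_coefficient": ovl,
        "mean": float(np.mean(sample)),
        "sd": float(np.std(sample, ddof=1)) if len(sample) > 1 else 0.0,
    }
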