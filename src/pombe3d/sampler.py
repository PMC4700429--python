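"""Ensemble generation by Metropolis Monte Carlo under polymer restraints.

Each conformation is a set of 3D granule positions satisfying, by
construction, the hard constraints of the model: every granule inside the
nuclear envelope, outside the nucleolus, consecutive granules within the
bond-length window [0.8, 1.2] x granule diameter, and no non-bonded pair
closer than one granule diameter (1% tolerance).  Soft terms — harmonic
bonds, a Kratky-Porod bending term, flat-bottomed tether wells and
flat-bottomed contact springs — are annealed with a geometric cooling
schedule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _mc
from .exceptions import ConfigurationError, InitializationError, Pombe3dError
from .genome import AnchorSet, GranulePartition, NuclearGeometry
from .contacts import GranuleContactSet, SubsetSpec, assign_subsets, sample_subset

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyParams",
    "Conformation",
    "Ensemble",
    "init_conformation",
    "total_energy",
    "EnergyBreakdown",
    "mc_optimize",
    "generate_ensemble",
    "radius_of_gyration",
    "check_invariants",
]


@dataclass(frozen=True)
class EnergyParams:
    """Energy functional constants and Monte Carlo schedule.

    Energies are in units of kT at temperature 1; lengths in nm.

    - ``k_bond``: harmonic bond constant about the 30 nm rest length.
    - ``persistence``: Kratky-Porod stiffness in granule units (default 3
      granules ~ 90 nm, an order-of-magnitude chromatin persistence length).
    - ``k_excluded`` / ``k_confinement``: soft-core penalty scales backing
      the hard constraints (zero on the feasible set).
    - ``k_contact`` / ``contact_rest``: flat-bottomed contact springs, zero
      inside 45 nm (1.5 granule diameters); the default stiffness is soft
      (a few kT over a nuclear diameter) so the restraint *count*, not any
      single spring, controls ensemble compaction.
    - cooling: geometric, T_k = t_start * cooling^k over ``n_temps`` levels
      with ``sweeps_per_temp`` sweeps (one attempted move per granule each).
    """

    k_bond: float = 0.2
    persistence: float = 3.0
    k_excluded: float = 1.0
    k_confinement: float = 1.0
    k_contact: float = 1e-5
    contact_rest: float = 45.0
    t_start: float = 8.0
    cooling: float = 0.88
    n_temps: int = 16
    sweeps_per_temp: int = 60
    step_nm: float = 8.0
    crank_prob: float = 0.45
    crank_max: int = 8
    crank_amp: float = float(np.pi)
    pivot_prob: float = 0.05
    pivot_amp: float = 0.6
    init_persistence: float = 0.85
    hard_constraints: bool = True
    ev_tolerance: float = 0.01

    def __post_init__(self):
        for name in ("k_bond", "persistence", "k_excluded", "k_confinement", "k_contact"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sweeps_per_temp < 0 or self.n_temps < 1:
            raise ConfigurationError("schedule must have n_temps >= 1, sweeps >= 0")
        if not 0 < self.cooling <= 1:
            raise ConfigurationError("cooling factor must be in (0, 1]")

    @property
    def temperatures(self) -> np.ndarray:
        return self.t_start * self.cooling ** np.arange(self.n_temps)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class Conformation:
    """One optimized 3D genome structure."""

    coords: np.ndarray  # (n_granules, 3) nm
    seed: int
    subset_id: int = -1
    energy: float = float("nan")
    acceptance: float = float("nan")

    @property
    def n_granules(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """A set of independently optimized conformations sharing one model setup."""

    structures: list[Conformation]
    partition: GranulePartition
    geometry: NuclearGeometry
    anchors: AnchorSet
    model_kind: str = "contact_restrained"  # or "random"
    subsets: list[np.ndarray] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seeds = [s.seed for s in self.structures]
        if len(set(seeds)) != len(seeds):
            raise ConfigurationError("structure seeds must be distinct")

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def coords(self) -> np.ndarray:
        """(n_structures, n_granules, 3) stacked coordinates."""
        return np.stack([s.coords for s in self.structures])

    def radii_of_gyration(self) -> np.ndarray:
        return np.array([radius_of_gyration(s) for s in self.structures])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("seeds", data=np.array([s.seed for s in self.structures]))
            f.create_dataset("energies", data=np.array([s.energy for s in self.structures]))
            f.attrs["model_kind"] = self.model_kind
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path, partition, geometry, anchors=None) -> "Ensemble":
        import h5py

        with h5py.File(path, "r") as f:
            coords = f["coords"][...]
            seeds = f["seeds"][...]
            energies = f["energies"][...]
            kind = f.attrs["model_kind"]
            prov = json.loads(f.attrs["provenance"])
        structures = [
            Conformation(coords=c, seed=int(s), energy=float(e))
            for c, s, e in zip(coords, seeds, energies)
        ]
        return cls(
            structures, partition, geometry, anchors or AnchorSet.empty(),
            model_kind=str(kind), provenance=prov,
        )

    def to_xyz(self, path) -> None:
        """Plain-text XYZ export (one frame per structure) for visualization."""
        names = np.asarray(self.partition.granule_chrom)
        with open(path, "w") as fh:
            for s in self.structures:
                fh.write(f"{s.n_granules}\nseed={s.seed}\n")
                for ci, (x, y, z) in zip(names, s.coords):
                    fh.write(f"C{ci} {x:.2f} {y:.2f} {z:.2f}\n")


def radius_of_gyration(conf) -> float:
    """Root-mean-square distance of granule centres from their centroid (nm)."""
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ConfigurationError("radius_of_gyration needs >= 1 granule")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c * c, axis=1))))


def _kernel_geometry(geometry: NuclearGeometry):
    return (
        geometry.nuclear_radius,
        geometry.granule_radius,
        float(geometry.nucleolus_center[2]),
        geometry.nucleolus_radius,
        geometry.spb_zone_radius,
        geometry.periphery_floor,
        geometry.nucleolar_surface_tol,
    )


def init_conformation(
    partition: GranulePartition,
    geometry: NuclearGeometry,
    seed: int,
    anchors: AnchorSet | None = None,
    persistence: float = 0.85,
) -> Conformation:
    """Self-avoiding worm-like walk, one chain per chromosome.

    Bond lengths equal the granule diameter exactly; step directions carry
    the configured correlation with the previous step so the starting coil
    is expanded at roughly the model's persistence length; anchored granules
    are started inside their target regions via steered growth.
    Deterministic for a fixed seed.
    """
    anchors = anchors or AnchorSet.empty()
    anchors.validate(partition)
    n = partition.n_granules
    anch_type, _anch_k = anchors.per_granule(n)
    chain_start = partition.chain_start

    # next anchored bead at or after each bead, within the same chain
    next_anchor = np.full(n, -1, dtype=np.int64)
    nxt = -1
    for i in range(n - 1, -1, -1):
        if chain_start[i + 1] if i + 1 < n else True:
            nxt = -1
        if anch_type[i] >= 0:
            nxt = i
        next_anchor[i] = nxt
        if chain_start[i]:
            nxt = -1

    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol = _kernel_geometry(geometry)
    if nrad + 2 * grad >= R:
        raise InitializationError(
            "nucleolus leaves no room for granules inside the nucleus"
        )
    coords, status = _mc.grow_conformation(
        n, chain_start, anch_type, next_anchor,
        R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
        geometry.granule_diameter, persistence, 60, int(seed) % 2**31,
    )
    if status != 0:
        raise InitializationError(
            "chain placement failed after retry budget; geometry too crowded"
        )
    return Conformation(coords=coords, seed=int(seed))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies; ``total`` is their sum."""

    bond: float
    bending: float
    excluded: float
    confinement: float
    nucleolus: float
    anchor: float
    contact: float

    @property
    def total(self) -> float:
        return (
            self.bond + self.bending + self.excluded
            + self.confinement + self.nucleolus + self.anchor + self.contact
        )


def total_energy(
    conf,
    params: EnergyParams,
    pairs: np.ndarray | None,
    anchors: AnchorSet,
    geometry: NuclearGeometry,
    partition: GranulePartition,
) -> EnergyBreakdown:
    """Vectorised reference evaluation of the full energy, term by term.

    ``pairs`` is a (k, 2) array of contact granule pairs (may be empty/None).
    """
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf, dtype=float)
    n = coords.shape[0]
    bonded = partition.bonded_prev
    b0 = geometry.granule_diameter
    grad = geometry.granule_radius
    R = geometry.nuclear_radius

    vec = coords[1:] - coords[:-1]
    blen = np.linalg.norm(vec, axis=1)
    mask = bonded[1:]
    e_bond = 0.5 * params.k_bond * np.sum((blen[mask] - b0) ** 2)

    # bending at vertices with both flanking bonds
    vmask = bonded[1:-1] & bonded[2:]
    if np.any(vmask):
        u = vec[:-1][vmask]
        w = vec[1:][vmask]
        cosang = np.sum(u * w, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        e_bend = params.persistence * np.sum(1.0 - cosang)
    else:
        e_bend = 0.0

    d = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=1)
    nb = ~((ju - iu == 1) & bonded[ju])
    dd = d[iu[nb], ju[nb]]
    dmin = 2.0 * grad
    e_ev = 0.5 * params.k_excluded * np.sum(np.maximum(dmin - dd, 0.0) ** 2)

    r = np.linalg.norm(coords, axis=1)
    e_conf = 0.5 * params.k_confinement * np.sum(np.maximum(r - (R - grad), 0.0) ** 2)

    e_nucl = 0.0
    if geometry.nucleolus_radius > 0:
        dn = np.linalg.norm(coords - geometry.nucleolus_center, axis=1)
        pen = np.maximum((geometry.nucleolus_radius + grad) - dn, 0.0)
        e_nucl = 0.5 * params.k_confinement * np.sum(pen**2)

    e_anchor = 0.0
    if len(anchors):
        dn = np.linalg.norm(coords - geometry.nucleolus_center, axis=1)
        dspb = np.linalg.norm(coords - geometry.spb_position, axis=1)
        for g, reg, k in zip(anchors.granules, anchors.regions, anchors.spring_constants):
            if reg == 0:
                ex = max(dspb[g] - geometry.spb_zone_radius, 0.0)
            elif reg == 1:
                ex = max(geometry.periphery_floor - r[g], 0.0)
            else:
                dev = abs(dn[g] - (geometry.nucleolus_radius + grad))
                ex = max(dev - geometry.nucleolar_surface_tol, 0.0)
            e_anchor += 0.5 * k * ex**2

    e_contact = 0.0
    if pairs is not None and len(pairs):
        pairs = np.asarray(pairs)
        dc = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        e_contact = 0.5 * params.k_contact * np.sum(
            np.maximum(dc - params.contact_rest, 0.0) ** 2
        )

    return EnergyBreakdown(
        bond=float(e_bond), bending=float(e_bend), excluded=float(e_ev),
        confinement=float(e_conf), nucleolus=float(e_nucl),
        anchor=float(e_anchor), contact=float(e_contact),
    )


def check_invariants(
    conf, partition: GranulePartition, geometry: NuclearGeometry, ev_tolerance: float = 0.01
) -> dict[str, int]:
    """Count hard-constraint violations of a conformation (all zero when valid)."""
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf, dtype=float)
    n = coords.shape[0]
    grad = geometry.granule_radius
    b0 = geometry.granule_diameter
    bonded = partition.bonded_prev
    tol = 1e-6

    r = np.linalg.norm(coords, axis=1)
    confinement = int(np.sum(r > geometry.nuclear_radius - grad + tol))

    nucleolus = 0
    if geometry.nucleolus_radius > 0:
        dn = np.linalg.norm(coords - geometry.nucleolus_center, axis=1)
        nucleolus = int(np.sum(dn < geometry.nucleolus_radius + grad - tol))

    blen = np.linalg.norm(coords[1:] - coords[:-1], axis=1)[bonded[1:]]
    bond_window = int(np.sum((blen < 0.8 * b0 - tol) | (blen > 1.2 * b0 + tol)))

    d = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=1)
    nb = ~((ju - iu == 1) & bonded[ju])
    overlap = int(np.sum(d[iu[nb], ju[nb]] < b0 * (1 - ev_tolerance) - tol))

    return {
        "confinement": confinement,
        "nucleolus": nucleolus,
        "bond_window": bond_window,
        "overlap": overlap,
    }


def _contact_csr(pairs: np.ndarray | None, n: int):
    """Adjacency (CSR) of contact pairs; each edge appears in both rows."""
    if pairs is None or len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    pairs = np.asarray(pairs, dtype=np.int64)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    off = np.zeros(n + 1, dtype=np.int64)
    np.add.at(off[1:], src, 1)
    off = np.cumsum(off)
    return off, dst


def mc_optimize(
    conf: Conformation,
    params: EnergyParams,
    pairs: np.ndarray | None,
    anchors: AnchorSet,
    geometry: NuclearGeometry,
    partition: GranulePartition,
    seed: int,
) -> Conformation:
    """Anneal one conformation; returns a new optimized :class:`Conformation`.

    With ``sweeps_per_temp == 0`` the input is returned unchanged (energy
    evaluated).  When hard constraints are enabled the output satisfies every
    Conformation invariant; a violation would be an internal error.
    """
    anchors = anchors or AnchorSet.empty()
    anchors.validate(partition)
    n = partition.n_granules
    if pairs is not None and len(pairs):
        pairs = np.asarray(pairs, dtype=np.int64)
        if pairs.min() < 0 or pairs.max() >= n:
            raise ConfigurationError("contact pair references an invalid granule")
    coords = np.array(conf.coords, dtype=np.float64)
    anch_type, anch_k = anchors.per_granule(n)
    c_off, c_nbr = _contact_csr(pairs, n)
    R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol = _kernel_geometry(geometry)

    acceptance = float("nan")
    if params.sweeps_per_temp > 0:
        accepted, attempted = _mc.run_mc(
            coords, partition.bonded_prev, anch_type, anch_k, c_off, c_nbr,
            R, grad, ncz, nrad, zone_r, shell_lo, nsurf_tol,
            params.k_bond, geometry.granule_diameter, params.persistence,
            params.k_excluded, params.k_confinement, params.k_contact,
            params.contact_rest,
            params.temperatures, params.sweeps_per_temp, params.step_nm,
            params.crank_prob, params.crank_max, params.crank_amp,
            params.pivot_prob, params.pivot_amp,
            params.hard_constraints, params.ev_tolerance, int(seed) % 2**31,
        )
        acceptance = accepted / max(attempted, 1)

    energy = total_energy(coords, params, pairs, anchors, geometry, partition).total
    out = Conformation(
        coords=coords, seed=int(seed), subset_id=conf.subset_id,
        energy=energy, acceptance=acceptance,
    )
    if params.hard_constraints and params.sweeps_per_temp > 0:
        viol = check_invariants(out, partition, geometry, params.ev_tolerance)
        if any(viol.values()):
            raise Pombe3dError(
                f"internal error: optimized structure violates hard constraints {viol}"
            )
    return out


def generate_ensemble(
    n_structures: int,
    partition: GranulePartition,
    geometry: NuclearGeometry,
    anchors: AnchorSet | None,
    contact_set: GranuleContactSet | None,
    spec: SubsetSpec | None,
    params: EnergyParams,
    master_seed: int,
    model_kind: str = "contact_restrained",
    enforce_coverage: bool = True,
) -> Ensemble:
    """Generate ``n_structures`` independently optimized structures.

    Contact-restrained models draw an independent contact subset per
    structure; with ``enforce_coverage`` (the default) never-selected pairs
    are force-assigned round-robin so every captured interaction appears in
    at least one model.  Calibration runs disable the forcing so the subset
    fraction alone sets the restraint load.  The random model uses an empty
    contact set and empty anchor set, retaining only the spatial confinement
    constraints.
    """
    if n_structures < 1:
        raise ConfigurationError("n_structures must be >= 1")
    if model_kind == "random":
        anchors = AnchorSet.empty()
        subsets = [None] * n_structures
    elif contact_set is None or contact_set.total == 0:
        subsets = [None] * n_structures
    else:
        if spec is None:
            raise ConfigurationError("contact-restrained ensemble needs a SubsetSpec")
        if enforce_coverage:
            subsets = assign_subsets(contact_set, spec, n_structures)
        else:
            ss0 = np.random.SeedSequence(spec.seed)
            subsets = [
                sample_subset(contact_set, SubsetSpec(spec.fraction, int(c.generate_state(1)[0] % 2**31)))
                for c in ss0.spawn(n_structures)
            ]
    anchors = anchors or AnchorSet.empty()

    ss = np.random.SeedSequence(int(master_seed))
    seeds = [int(s) for s in ss.generate_state(2 * n_structures) % np.uint32(2**31)]
    # guarantee distinct per-structure seeds
    seen, uniq = set(), []
    for s in seeds:
        while s in seen:
            s = (s + 1) % 2**31
        seen.add(s)
        uniq.append(s)
    init_seeds, mc_seeds = uniq[:n_structures], uniq[n_structures:]

    structures = []
    pair_arrays = []
    for sidx in range(n_structures):
        idx = subsets[sidx]
        pairs = contact_set.pairs(idx) if idx is not None else None
        pair_arrays.append(pairs if pairs is not None else np.empty((0, 2), dtype=np.int64))
        conf0 = init_conformation(
            partition, geometry, init_seeds[sidx], anchors,
            persistence=params.init_persistence,
        )
        conf0.subset_id = sidx
        structures.append(
            mc_optimize(conf0, params, pairs, anchors, geometry, partition, mc_seeds[sidx])
        )
    prov = {
        "master_seed": int(master_seed),
        "config_hash": params.config_hash(),
        "fraction": spec.fraction if (spec is not None and model_kind != "random") else None,
    }
    ens = Ensemble(
        structures, partition, geometry, anchors,
        model_kind=model_kind, subsets=pair_arrays, provenance=prov,
    )
    logger.info(
        "ensemble: %d structures (%s), mean Rg %.1f nm, mean acceptance %.2f",
        n_structures, model_kind, float(np.mean(ens.radii_of_gyration())),
        float(np.nanmean([s.acceptance for s in structures])),
    )
    return ens
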