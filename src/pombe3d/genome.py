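"""Genome representation: chromosomes, granule partition, nuclear geometry, anchors.

The genome is coarse-grained into *granules*, beads of fixed genomic span
(default 3.5 kb) and fixed physical diameter (default 30 nm), strung into one
polymer chain per chromosome.  All genomic coordinates are 0-based, half-open
``[start, end)``; BED input therefore maps onto granules without any shift.

The nuclear frame is fixed: the nuclear centre is the origin, the spindle pole
body (SPB) sits on the envelope at ``(0, 0, +R)`` and the nucleolus is centred
on the negative z axis, tangent to the envelope at the opposite pole.  The
SPB--nucleolus axis is the z axis, which is also the axis used for the
rotational projection of structures onto (z, r) density maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import CoordinateError, GeometryError

__all__ = [
    "ChromosomeSpec",
    "GranulePartition",
    "NuclearGeometry",
    "AnchorSet",
    "build_partition",
    "bp_to_granule",
    "build_geometry",
    "build_anchors",
    "read_genome_yaml",
    "ANCHOR_REGIONS",
]

#: Anchor target regions, encoded as small integers for the MC kernel.
ANCHOR_REGIONS = {"SPB_zone": 0, "periphery": 1, "nucleolar_surface": 2}


def _check_interval(iv, length, what, name):
    s, e = int(iv[0]), int(iv[1])
    if not (0 <= s < e <= length):
        raise CoordinateError(
            f"{what} interval {iv} of chromosome {name!r} outside [0, {length})"
        )
    return (s, e)


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: name, length and landmark intervals (bp, half-open)."""

    name: str
    length: int
    centromere: tuple[int, int]
    telomeres: tuple[tuple[int, int], tuple[int, int]]
    rdna: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.length <= 0:
            raise CoordinateError(f"chromosome {self.name!r}: length must be > 0")
        cen = _check_interval(self.centromere, self.length, "centromere", self.name)
        object.__setattr__(self, "centromere", cen)
        tels = tuple(
            _check_interval(t, self.length, "telomere", self.name)
            for t in self.telomeres
        )
        object.__setattr__(self, "telomeres", tels)
        object.__setattr__(
            self,
            "rdna",
            tuple(_check_interval(r, self.length, "rDNA", self.name) for r in self.rdna),
        )
        for t in tels:
            if cen[0] < t[1] and t[0] < cen[1]:
                raise CoordinateError(
                    f"chromosome {self.name!r}: centromere overlaps a telomere"
                )


@dataclass(frozen=True)
class GranulePartition:
    """Mapping between linear genome coordinates and polymer granules.

    Granules within a chromosome are contiguous, non-overlapping and cover it
    exactly; every granule except possibly the last of each chromosome spans
    ``granule_bp``.  Granule indices are global and consecutive in chromosome
    order.
    """

    granule_bp: int
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    offsets: tuple[int, ...]  # global index of each chromosome's first granule
    n_granules: int

    # derived arrays (not part of equality/hash; filled in __post_init__)
    granule_chrom: np.ndarray = field(default=None, repr=False, compare=False)
    granule_start: np.ndarray = field(default=None, repr=False, compare=False)
    granule_end: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        chrom = np.empty(self.n_granules, dtype=np.int64)
        start = np.empty(self.n_granules, dtype=np.int64)
        end = np.empty(self.n_granules, dtype=np.int64)
        for ci, (L, off) in enumerate(zip(self.chrom_lengths, self.offsets)):
            n = self._n_granules_of(L)
            idx = np.arange(n)
            chrom[off : off + n] = ci
            start[off : off + n] = idx * self.granule_bp
            end[off : off + n] = np.minimum((idx + 1) * self.granule_bp, L)
        object.__setattr__(self, "granule_chrom", chrom)
        object.__setattr__(self, "granule_start", start)
        object.__setattr__(self, "granule_end", end)

    def _n_granules_of(self, length: int) -> int:
        return -(-length // self.granule_bp)  # ceil division

    @property
    def chain_start(self) -> np.ndarray:
        """Boolean mask: True where a granule begins a new chromosome chain."""
        m = np.zeros(self.n_granules, dtype=bool)
        m[list(self.offsets)] = True
        return m

    @property
    def bonded_prev(self) -> np.ndarray:
        """Boolean mask: True where granule i is chained to granule i-1."""
        return ~self.chain_start

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def bp_to_granule(self, chrom: str, pos: int) -> int:
        """Global index of the granule whose [start, end) interval contains pos."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise CoordinateError(
                f"position {pos} outside chromosome {chrom!r} "
                f"[0, {self.chrom_lengths[ci]})"
            )
        return self.offsets[ci] + int(pos) // self.granule_bp

    def granule_interval(self, g: int) -> tuple[str, int, int]:
        """(chromosome name, start bp, end bp) of granule g."""
        ci = int(self.granule_chrom[g])
        return self.chrom_names[ci], int(self.granule_start[g]), int(self.granule_end[g])

    def granules(self):
        """Iterate (chromosome, start, end, global index)."""
        for g in range(self.n_granules):
            c, s, e = self.granule_interval(g)
            yield (c, s, e, g)

    def overlapping_granules(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of granules overlapped by [start, end) (any overlap)."""
        ci = self.chrom_index(chrom)
        L = self.chrom_lengths[ci]
        if not (0 <= start < end <= L):
            raise CoordinateError(
                f"interval [{start}, {end}) outside chromosome {chrom!r} [0, {L})"
            )
        g0 = start // self.granule_bp
        g1 = (end - 1) // self.granule_bp
        return self.offsets[ci] + np.arange(g0, g1 + 1)

    @property
    def genome_position(self) -> np.ndarray:
        """Midpoint of every granule on the concatenated-genome bp axis."""
        cum = np.concatenate([[0], np.cumsum(self.chrom_lengths)])
        return cum[self.granule_chrom] + 0.5 * (self.granule_start + self.granule_end)


def build_partition(chroms: list[ChromosomeSpec], granule_bp: int = 3500) -> GranulePartition:
    """Partition chromosomes into granules of ``granule_bp`` (ceiling rule).

    The last granule of each chromosome may span fewer base pairs.  The total
    granule count is ``sum(ceil(length / granule_bp))``.
    """
    if granule_bp <= 0:
        raise CoordinateError("granule_bp must be > 0")
    if not chroms:
        raise CoordinateError("at least one chromosome required")
    names, lengths, offsets = [], [], []
    off = 0
    for c in chroms:
        if c.length <= 0:
            raise CoordinateError(f"chromosome {c.name!r}: length must be > 0")
        names.append(c.name)
        lengths.append(c.length)
        offsets.append(off)
        off += -(-c.length // granule_bp)
    return GranulePartition(
        granule_bp=int(granule_bp),
        chrom_names=tuple(names),
        chrom_lengths=tuple(lengths),
        offsets=tuple(offsets),
        n_granules=off,
    )


def bp_to_granule(partition: GranulePartition, chrom: str, pos: int) -> int:
    """Functional alias of :meth:`GranulePartition.bp_to_granule`."""
    return partition.bp_to_granule(chrom, pos)


@dataclass(frozen=True)
class NuclearGeometry:
    """Nuclear envelope, SPB, nucleolus and anchor-zone geometry (nm).

    The SPB sits at ``(0, 0, +nuclear_radius)``; the nucleolus is a sphere of
    ``nucleolus_radius`` centred on the negative z axis tangent to the envelope
    (unless ``nucleolus_center_distance`` overrides the centre distance).  The
    ``axis`` property is the unit vector from the nuclear centre toward the
    SPB; projections onto it are positive on the SPB side.
    """

    nuclear_radius: float = 1300.0
    granule_diameter: float = 30.0
    nucleolus_radius: float = 500.0
    nucleolus_center_distance: float | None = None
    spb_zone_radius: float = 300.0
    periphery_width: float = 150.0
    nucleolar_surface_tol: float = 150.0

    def __post_init__(self):
        R = self.nuclear_radius
        if R <= 0 or self.granule_diameter <= 0:
            raise GeometryError("radii and granule diameter must be positive")
        if self.granule_diameter >= R:
            raise GeometryError("granule diameter must be smaller than the nucleus")
        if self.nucleolus_radius < 0:
            raise GeometryError("nucleolus radius must be >= 0")
        d = self.nucleolus_center_offset
        if d + self.nucleolus_radius > R + 1e-9:
            raise GeometryError(
                f"nucleolus (centre distance {d}, radius {self.nucleolus_radius}) "
                f"protrudes outside the nucleus (radius {R})"
            )

    @property
    def nucleolus_center_offset(self) -> float:
        """Distance of the nucleolus centre from the nuclear centre."""
        if self.nucleolus_center_distance is not None:
            return float(self.nucleolus_center_distance)
        return self.nuclear_radius - self.nucleolus_radius

    @property
    def granule_radius(self) -> float:
        return 0.5 * self.granule_diameter

    @property
    def spb_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.nuclear_radius])

    @property
    def nucleolus_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.nucleolus_center_offset])

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from nuclear centre toward the SPB (projection axis)."""
        return np.array([0.0, 0.0, 1.0])

    @property
    def periphery_floor(self) -> float:
        """Inner boundary (distance from centre) of the peripheral anchor shell."""
        return self.nuclear_radius - self.granule_radius - self.periphery_width


def build_geometry(config: dict | None = None, **kwargs) -> NuclearGeometry:
    """Build a :class:`NuclearGeometry` from a config mapping and/or keywords."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    return NuclearGeometry(**cfg)


@dataclass
class AnchorSet:
    """Tethering restraints: (granule, target region, spring constant).

    Regions are flat-bottomed harmonic wells: the energy is zero while the
    granule is inside the target region and grows quadratically with the
    distance outside it.
    """

    granules: np.ndarray
    regions: np.ndarray
    spring_constants: np.ndarray

    @classmethod
    def from_tuples(cls, anchors: list[tuple[int, str, float]]) -> "AnchorSet":
        g = np.array([a[0] for a in anchors], dtype=np.int64)
        r = np.array([ANCHOR_REGIONS[a[1]] for a in anchors], dtype=np.int64)
        k = np.array([a[2] for a in anchors], dtype=np.float64)
        if np.any(k <= 0):
            raise GeometryError("anchor spring constants must be > 0")
        return cls(g, r, k)

    @classmethod
    def empty(cls) -> "AnchorSet":
        return cls(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
        )

    def __len__(self):
        return len(self.granules)

    def validate(self, partition: GranulePartition) -> None:
        if len(self.granules) and (
            self.granules.min() < 0 or self.granules.max() >= partition.n_granules
        ):
            raise CoordinateError("anchor references a granule outside the partition")

    def per_granule(self, n_granules: int) -> tuple[np.ndarray, np.ndarray]:
        """Dense per-granule (region code, spring constant); region -1 = unanchored.

        If a granule carries several anchors the last one listed wins (the
        default builder never produces duplicates).
        """
        t = np.full(n_granules, -1, dtype=np.int64)
        k = np.zeros(n_granules, dtype=np.float64)
        t[self.granules] = self.regions
        k[self.granules] = self.spring_constants
        return t, k


def build_anchors(
    chroms: list[ChromosomeSpec],
    partition: GranulePartition,
    spring_constant: float = 0.01,
) -> AnchorSet:
    """Standard fission-yeast tethering set (interphase Rabl configuration).

    Centromere-overlapping granules are tethered to the SPB zone, telomeric
    granules to the nuclear periphery and rDNA granules to the nucleolar
    surface.
    """
    tuples: list[tuple[int, str, float]] = []
    seen: set[int] = set()

    def add(granule_indices, region):
        for g in granule_indices:
            g = int(g)
            if g not in seen:
                seen.add(g)
                tuples.append((g, region, spring_constant))

    for c in chroms:
        add(partition.overlapping_granules(c.name, *c.centromere), "SPB_zone")
        for t in c.telomeres:
            add(partition.overlapping_granules(c.name, *t), "periphery")
        for r in c.rdna:
            add(partition.overlapping_granules(c.name, *r), "nucleolar_surface")
    if not tuples:
        return AnchorSet.empty()
    return AnchorSet.from_tuples(tuples)


def read_genome_yaml(path) -> list[ChromosomeSpec]:
    """Read a genome description from YAML.

    Expected layout::

        chromosomes:
          - name: I
            length: 350000
            centromere: [171500, 178500]
            telomeres: [[0, 7000], [343000, 350000]]
            rdna: []            # optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    chroms = []
    for entry in doc["chromosomes"]:
        chroms.append(
            ChromosomeSpec(
                name=str(entry["name"]),
                length=int(entry["length"]),
                centromere=tuple(entry["centromere"]),
                telomeres=tuple(tuple(t) for t in entry["telomeres"]),
                rdna=tuple(tuple(r) for r in entry.get("rdna", []) or []),
            )
        )
    return chroms
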