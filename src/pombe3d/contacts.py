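"""Chromosomal contact handling: reading, granule aggregation, subsampling, calibration.

Proximity-ligation assays (GCC, Hi-C) report population-averaged pairwise
contacts.  Because any single nucleus realises only a fraction of the
population's contacts, each model structure is restrained by a random subset
of granule pairs drawn with probability proportional to detection frequency;
the subset size (as a fraction of the distinct pairs) is calibrated so that
the ensemble-mean radius of gyration matches a target compaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    ContactParseError,
    CoordinateError,
)
from .genome import GranulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "GranuleContactSet",
    "SubsetSpec",
    "read_contacts",
    "contacts_from_records",
    "sample_subset",
    "assign_subsets",
    "calibrate_fraction",
]


@dataclass(frozen=True)
class ContactRecord:
    """One captured contact between two genomic positions, with its read count."""

    chromA: str
    posA: int
    chromB: str
    posB: int
    frequency: int

    def __post_init__(self):
        if self.frequency < 1:
            raise ContactParseError(f"frequency must be >= 1, got {self.frequency}")


@dataclass
class GranuleContactSet:
    """Distinct granule pairs with summed detection frequencies.

    Invariants: ``i < j``; pairs on the same chromosome are non-adjacent
    (``j - i > 1``); weights >= 1; no duplicate pairs.
    """

    i: np.ndarray
    j: np.ndarray
    weight: np.ndarray
    partition: GranulePartition

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if np.any(self.i >= self.j):
            raise ConfigurationError("contact pairs must satisfy i < j")
        chrom = self.partition.granule_chrom
        same = chrom[self.i] == chrom[self.j]
        if np.any(same & (self.j - self.i <= 1)):
            raise ConfigurationError("same-chromosome adjacent pairs are forbidden")
        if np.any(self.weight < 1):
            raise ConfigurationError("contact weights must be >= 1")
        keys = self.i * self.partition.n_granules + self.j
        if len(np.unique(keys)) != len(keys):
            raise ConfigurationError("duplicate contact pairs")

    @property
    def total(self) -> int:
        """Number of distinct granule pairs."""
        return len(self.i)

    def pairs(self, idx=None) -> np.ndarray:
        """(k, 2) array of granule pairs, optionally restricted to indices idx."""
        if idx is None:
            return np.column_stack([self.i, self.j])
        idx = np.asarray(idx, dtype=np.int64)
        return np.column_stack([self.i[idx], self.j[idx]])


@dataclass(frozen=True)
class SubsetSpec:
    """Per-structure subset size as a fraction of distinct contact pairs.

    The GCC-derived models of the study use fraction 0.10; Hi-C-derived models
    use much smaller fractions.  Both assays are abstracted to this single
    parameter.
    """

    fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ConfigurationError(f"fraction must be in (0, 1], got {self.fraction}")


def contacts_from_records(
    records: list[ContactRecord], partition: GranulePartition
) -> GranuleContactSet:
    """Aggregate bp-level contact records onto distinct granule pairs.

    Records mapping to the same (unordered) granule pair are merged by summing
    frequency; self pairs and same-chromosome adjacent pairs are dropped (only
    non-adjacent captured interactions restrain the models).
    """
    merged: dict[tuple[int, int], float] = {}
    n_self = n_adjacent = 0
    chrom = partition.granule_chrom
    for rec in records:
        a = partition.bp_to_granule(rec.chromA, rec.posA)
        b = partition.bp_to_granule(rec.chromB, rec.posB)
        if a == b:
            n_self += 1
            continue
        i, j = (a, b) if a < b else (b, a)
        if chrom[i] == chrom[j] and j - i <= 1:
            n_adjacent += 1
            continue
        merged[(i, j)] = merged.get((i, j), 0.0) + rec.frequency
    logger.info(
        "contacts: %d records -> %d distinct granule pairs "
        "(%d self dropped, %d adjacent dropped)",
        len(records), len(merged), n_self, n_adjacent,
    )
    if merged:
        keys = sorted(merged)
        i = np.array([k[0] for k in keys])
        j = np.array([k[1] for k in keys])
        w = np.array([merged[k] for k in keys])
    else:
        i = j = np.empty(0, dtype=np.int64)
        w = np.empty(0, dtype=np.float64)
    return GranuleContactSet(i, j, w, partition)


def read_contacts(path, partition: GranulePartition) -> GranuleContactSet:
    """Read a contact TSV (``chromA posA chromB posB count``) onto granule pairs.

    A header line and ``#`` comments are tolerated.  Malformed lines raise
    :class:`ContactParseError` with the 1-based line number.
    """
    records: list[ContactRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ContactParseError(
                    f"expected 5 tab-separated fields, got {len(fields)}", ln
                )
            try:
                rec = ContactRecord(
                    chromA=fields[0],
                    posA=int(fields[1]),
                    chromB=fields[2],
                    posB=int(fields[3]),
                    frequency=int(fields[4]),
                )
            except ValueError as exc:
                if ln == 1:  # optional header
                    continue
                raise ContactParseError(str(exc), ln) from None
            try:
                records.append(rec)
                # validate coordinates eagerly so the line number is reported
                partition.bp_to_granule(rec.chromA, rec.posA)
                partition.bp_to_granule(rec.chromB, rec.posB)
            except CoordinateError as exc:
                raise ContactParseError(str(exc), ln) from None
    return contacts_from_records(records, partition)


def _subset_size(fraction: float, total: int) -> int:
    k = int(np.floor(fraction * total + 0.5))  # round half up
    if k < 1:
        raise ConfigurationError(
            f"fraction * total = {fraction * total:.3g} < 1: no pairs would be drawn"
        )
    return min(k, total)


def sample_subset(cset: GranuleContactSet, spec: SubsetSpec) -> np.ndarray:
    """Draw ``round(fraction * total)`` distinct pairs, weighted without replacement.

    Successive draws with renormalisation: at each step a remaining pair is
    selected with probability proportional to its summed detection frequency.
    Returns pair indices into ``cset``; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    return _weighted_without_replacement(rng, cset.weight, _subset_size(spec.fraction, cset.total))


def _weighted_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    w = np.array(weights, dtype=np.float64)
    out = np.empty(k, dtype=np.int64)
    for t in range(k):
        p = w / w.sum()
        c = rng.choice(len(w), p=p)
        out[t] = c
        w[c] = 0.0
    return out


def assign_subsets(
    cset: GranuleContactSet, spec: SubsetSpec, n_structures: int
) -> list[np.ndarray]:
    """Independent subset per structure, plus forced coverage of every pair.

    After the independent weighted draws, any pair never selected is appended
    round-robin across structures so that every captured interaction is
    present in at least one model.
    """
    if n_structures < 1:
        raise ConfigurationError("n_structures must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n_structures)
    k = _subset_size(spec.fraction, cset.total)
    subsets = [
        _weighted_without_replacement(np.random.default_rng(c), cset.weight, k)
        for c in children
    ]
    covered = np.zeros(cset.total, dtype=bool)
    for s in subsets:
        covered[s] = True
    missing = np.flatnonzero(~covered)
    if len(missing):
        logger.info(
            "assign_subsets: force-assigning %d never-selected pairs round-robin",
            len(missing),
        )
        for pos, m in enumerate(missing):
            tgt = pos % n_structures
            subsets[tgt] = np.append(subsets[tgt], m)
    return subsets


def calibrate_fraction(
    cset: GranuleContactSet,
    target_rg: float,
    *,
    geometry,
    anchors=None,
    params=None,
    n_structures: int = 20,
    tolerance: float = 0.05,
    seed: int = 0,
    max_iter: int = 12,
    full_output: bool = False,
):
    """Bisection of the subset fraction against a target radius of gyration.

    For each candidate fraction a small calibration ensemble is generated
    (same master seed throughout, i.e. common random numbers) and its mean
    radius of gyration compared with ``target_rg``.  Calibration ensembles
    draw pure weighted subsets without the ensemble-level coverage forcing,
    so the fraction alone controls the restraint load; at production scale
    (many structures) forcing is negligible and the two procedures coincide.  The search assumes that
    more contacts make the genome more compact; the assumption is checked on
    the evaluated history and a warning is logged if it is violated.

    Calibration ensembles carry no tethering anchors unless explicitly
    provided: the fraction->0 limit is then the random (confinement-only)
    model, whose expanded mean Rg brackets the compaction target from above,
    and the contact load alone moves the ensemble along the compaction curve.

    Returns the calibrated fraction, or ``(fraction, history)`` with
    ``history`` a list of ``(fraction, mean_rg)`` when ``full_output=True``.
    Raises :class:`CalibrationError` when no fraction in (0, 1] reaches the
    target within tolerance, reporting the bracketing mean-Rg values.
    """
    from .genome import AnchorSet
    from .sampler import EnergyParams, generate_ensemble

    anchors = anchors if anchors is not None else AnchorSet.empty()
    if target_rg >= geometry.nuclear_radius:
        raise ConfigurationError("target_rg must be smaller than the nuclear radius")
    if cset.total < 1:
        raise ConfigurationError("empty contact set cannot be calibrated")
    params = params or EnergyParams()

    history: list[tuple[float, float]] = []

    def mean_rg(fraction: float) -> float:
        ens = generate_ensemble(
            n_structures,
            cset.partition,
            geometry,
            anchors,
            cset,
            SubsetSpec(fraction=fraction, seed=seed),
            params,
            master_seed=seed,
            enforce_coverage=False,
        )
        rg = float(np.mean(ens.radii_of_gyration()))
        history.append((fraction, rg))
        logger.info("calibrate: fraction %.5f -> mean Rg %.1f nm", fraction, rg)
        return rg

    lo_tol, hi_tol = (1 - tolerance) * target_rg, (1 + tolerance) * target_rg

    def done(rg):
        return lo_tol <= rg <= hi_tol

    f_lo = 1.0 / cset.total  # sparsest admissible subset (expanded arm)
    rg_lo = mean_rg(f_lo)
    if done(rg_lo):
        return (f_lo, history) if full_output else f_lo
    if rg_lo < lo_tol:
        raise CalibrationError(
            f"even the minimal subset (fraction {f_lo:.3g}) is too compact: "
            f"mean Rg {rg_lo:.1f} nm < target {target_rg:.1f} nm"
        )
    f_hi = 1.0
    rg_hi = mean_rg(f_hi)
    if done(rg_hi):
        return (f_hi, history) if full_output else f_hi
    if rg_hi > hi_tol:
        raise CalibrationError(
            f"even the full contact set is too expanded: mean Rg {rg_hi:.1f} nm "
            f"> target {target_rg:.1f} nm (bracket Rg: {rg_lo:.1f}, {rg_hi:.1f})"
        )
    for _ in range(max_iter):
        f_mid = float(np.sqrt(f_lo * f_hi))  # bisect in log space
        rg_mid = mean_rg(f_mid)
        if done(rg_mid):
            _check_monotone(history)
            return (f_mid, history) if full_output else f_mid
        if rg_mid > target_rg:
            f_lo, rg_lo = f_mid, rg_mid
        else:
            f_hi, rg_hi = f_mid, rg_mid
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations; bracket "
        f"fractions ({f_lo:.4g}, {f_hi:.4g}) with mean Rg ({rg_lo:.1f}, {rg_hi:.1f}) nm "
        f"around target {target_rg:.1f} nm"
    )


def _check_monotone(history):
    by_f = sorted(history)
    rgs = [rg for _, rg in by_f]
    if any(b > a + 1e-9 for a, b in zip(rgs, rgs[1:])):
        logger.warning(
            "calibrate: mean Rg not monotone in fraction over evaluated points %s "
            "(stochastic calibration noise)", by_f,
        )
    else:
        logger.info("calibrate: monotonicity assumption held on evaluated points")
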