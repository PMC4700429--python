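"""Synthetic genomes, contact sets, ChIP tracks and origin annotations.

The generator emulates the statistical structure of the experimental inputs
the analysis pipeline consumes, at desk scale, so every stage is testable
with known ground truth and no downloads:

- a toy three-chromosome genome (350 / 280 / 175 kb -> 100 + 80 + 50 = 230
  granules at 3.5 kb) with interior centromeres and terminal telomeres;
- pairwise contacts with power-law distance decay within chromosomes, a low
  uniform inter-chromosomal background, planted centromere-centromere and
  telomere-telomere clustering, and overdispersed (gamma-Poisson) detection
  frequencies that grow with pair weight;
- 300 bp probe-sized ChIP records with log-normal signals whose strongest
  peaks are placed into heterochromatic (pericentromeric + subtelomeric) or
  euchromatic territory according to a compartment bias;
- replication origins whose timing/efficiency classes correlate with the
  planted compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .contacts import ContactRecord
from .features import FeatureTrack
from .genome import ChromosomeSpec, GranulePartition, build_partition

__all__ = [
    "SyntheticConfig",
    "make_genome",
    "make_contacts",
    "make_chip_track",
    "make_origins",
    "het_intervals",
    "het_granule_mask",
    "contacts_to_tsv",
    "track_to_bed",
    "origins_to_bed",
]


def _default_class_counts() -> dict[str, int]:
    return {
        "early_high": 10, "early_medium": 6, "early_low": 4,
        "late_high": 4, "late_medium": 6, "late_low": 10,
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic inputs (all lengths in bp)."""

    chromosome_lengths: tuple[int, ...] = (350_000, 280_000, 175_000)
    granule_bp: int = 3500
    centromere_bp: int = 7000
    telomere_bp: int = 7000
    pericentromere_bp: int = 10_500  # heterochromatic flank each side of the centromere
    subtelomere_bp: int = 14_000  # heterochromatic extension inward of each telomere

    # contacts
    n_pairs: int = 1200
    decay_alpha: float = 1.0
    inter_weight: float = 0.1
    cen_boost: float = 20.0
    tel_boost: float = 10.0
    freq_mean: float = 3.0
    freq_dispersion: float = 1.5

    # ChIP tracks
    n_peaks: int = 1000
    probe_bp: int = 300
    signal_sigma: float = 1.0
    zone_enrichment: float = 8.0
    chip_bias: float = 0.8

    # origins
    class_counts: dict = field(default_factory=_default_class_counts)
    origin_bias: float = 0.8

    seed: int = 0

    def __post_init__(self):
        if any(L < self.granule_bp for L in self.chromosome_lengths):
            raise ConfigurationError("chromosome lengths must be >= granule_bp")
        if self.n_pairs < 0 or self.n_peaks < 0:
            raise ConfigurationError("counts must be >= 0")
        if not 0 <= self.chip_bias <= 1 or not 0 <= self.origin_bias <= 1:
            raise ConfigurationError("biases must be in [0, 1]")


def make_genome(cfg: SyntheticConfig) -> list[ChromosomeSpec]:
    """Toy chromosomes with centred centromeres and terminal telomeres."""
    chroms = []
    for idx, L in enumerate(cfg.chromosome_lengths):
        cen_mid = L // 2
        cen = (cen_mid - cfg.centromere_bp // 2, cen_mid + cfg.centromere_bp // 2)
        chroms.append(
            ChromosomeSpec(
                name=f"chr{'I' * (idx + 1)}",
                length=L,
                centromere=cen,
                telomeres=((0, cfg.telomere_bp), (L - cfg.telomere_bp, L)),
            )
        )
    return chroms


def het_intervals(genome: list[ChromosomeSpec], cfg: SyntheticConfig):
    """Heterochromatic territory: pericentromeres + (sub)telomeric ends."""
    out = []
    for c in genome:
        s = max(0, c.centromere[0] - cfg.pericentromere_bp)
        e = min(c.length, c.centromere[1] + cfg.pericentromere_bp)
        out.append((c.name, s, e))
        for t in c.telomeres:
            if t[0] == 0:
                out.append((c.name, 0, min(c.length, t[1] + cfg.subtelomere_bp)))
            else:
                out.append((c.name, max(0, t[0] - cfg.subtelomere_bp), c.length))
    return out


def het_granule_mask(
    genome: list[ChromosomeSpec], partition: GranulePartition, cfg: SyntheticConfig
) -> np.ndarray:
    """Boolean per-granule mask of the planted heterochromatic territory."""
    mask = np.zeros(partition.n_granules, dtype=bool)
    for chrom, s, e in het_intervals(genome, cfg):
        mask[partition.overlapping_granules(chrom, s, e)] = True
    return mask


def _zone_masks(genome, partition, cfg):
    cen = np.zeros(partition.n_granules, dtype=bool)
    tel = np.zeros(partition.n_granules, dtype=bool)
    for c in genome:
        s = max(0, c.centromere[0] - cfg.pericentromere_bp)
        e = min(c.length, c.centromere[1] + cfg.pericentromere_bp)
        cen[partition.overlapping_granules(c.name, s, e)] = True
        for t in c.telomeres:
            tel[partition.overlapping_granules(c.name, *t)] = True
    return cen, tel


def make_contacts(
    genome: list[ChromosomeSpec], cfg: SyntheticConfig
) -> list[ContactRecord]:
    """Sample distinct granule-pair contacts and overdispersed frequencies.

    Intra-chromosomal candidate pairs carry weight ``|i - j| ** -alpha``,
    inter-chromosomal pairs a flat ``inter_weight``; centromere-centromere
    and telomere-telomere pairs are up-weighted by the configured boosts.
    ``n_pairs`` distinct pairs are drawn with probability proportional to
    weight, and each receives a frequency ``1 + Poisson(Gamma)`` whose mean
    scales with its weight (frequent contacts are both more likely to be
    sampled and more deeply covered).  Record positions are uniform within
    their granules, so the output round-trips through contact reading.
    """
    rng = np.random.default_rng(cfg.seed)
    partition = build_partition(genome, cfg.granule_bp)
    n = partition.n_granules
    chrom = partition.granule_chrom

    iu, ju = np.triu_indices(n, k=1)
    same = chrom[iu] == chrom[ju]
    valid = ~(same & (ju - iu == 1))
    iu, ju, same = iu[valid], ju[valid], same[valid]

    w = np.where(
        same,
        (ju - iu).astype(float) ** (-cfg.decay_alpha),
        cfg.inter_weight,
    )
    cen, tel = _zone_masks(genome, partition, cfg)
    w = w * np.where(cen[iu] & cen[ju], cfg.cen_boost, 1.0)
    w = w * np.where(tel[iu] & tel[ju], cfg.tel_boost, 1.0)

    if cfg.n_pairs > len(iu):
        raise ConfigurationError(
            f"requested {cfg.n_pairs} distinct pairs but only {len(iu)} exist"
        )
    pick = rng.choice(len(iu), size=cfg.n_pairs, replace=False, p=w / w.sum())
    pick.sort()

    lam = cfg.freq_mean * w[pick] / w[pick].mean()
    gam = rng.gamma(cfg.freq_dispersion, lam / cfg.freq_dispersion)
    freq = 1 + rng.poisson(gam)

    records = []
    for gi, gj, f in zip(iu[pick], ju[pick], freq):
        ca, sa, ea = partition.granule_interval(int(gi))
        cb, sb, eb = partition.granule_interval(int(gj))
        records.append(
            ContactRecord(
                chromA=ca, posA=int(rng.integers(sa, ea)),
                chromB=cb, posB=int(rng.integers(sb, eb)),
                frequency=int(f),
            )
        )
    return records


def _interval_complement(genome, intervals):
    """Per-chromosome complement of a set of (chrom, start, end) intervals."""
    out = []
    for c in genome:
        ivs = sorted((s, e) for ch, s, e in intervals if ch == c.name)
        pos = 0
        for s, e in ivs:
            if s > pos:
                out.append((c.name, pos, s))
            pos = max(pos, e)
        if pos < c.length:
            out.append((c.name, pos, c.length))
    return out


def _sample_positions(rng, intervals, size, width):
    """Uniform record starts within a set of intervals, weighted by length."""
    lens = np.array([max(e - s - width, 1) for _, s, e in intervals], dtype=float)
    which = rng.choice(len(intervals), size=size, p=lens / lens.sum())
    out = []
    for k in which:
        chrom, s, e = intervals[k]
        hi = max(e - width, s + 1)
        out.append((chrom, int(rng.integers(s, hi))))
    return out


def make_chip_track(
    genome: list[ChromosomeSpec],
    cfg: SyntheticConfig,
    compartment: str = "peripheral_het",
) -> FeatureTrack:
    """Probe-sized ChIP records with compartment-biased top signals.

    With probability ``chip_bias`` a record is placed inside its
    compartment's territory (heterochromatic zones for ``peripheral_het``,
    their complement for ``central_eu``) and its log-normal signal is
    multiplied by ``zone_enrichment``; otherwise it is placed uniformly with
    a base signal.  At bias 1 every record (hence every top-signal peak)
    falls in the territory; at bias 0 placement is uniform over the genome.
    """
    if compartment not in ("peripheral_het", "central_eu"):
        raise ConfigurationError(f"unknown compartment {compartment!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1 if compartment == "peripheral_het" else 2])
    )
    het = het_intervals(genome, cfg)
    zone = het if compartment == "peripheral_het" else _interval_complement(genome, het)
    whole = [(c.name, 0, c.length) for c in genome]

    in_zone = rng.random(cfg.n_peaks) < cfg.chip_bias
    n_zone = int(in_zone.sum())
    pos_zone = _sample_positions(rng, zone, n_zone, cfg.probe_bp)
    pos_bg = _sample_positions(rng, whole, cfg.n_peaks - n_zone, cfg.probe_bp)

    sig = rng.lognormal(0.0, cfg.signal_sigma, size=cfg.n_peaks)
    sig[:n_zone] *= cfg.zone_enrichment
    chroms, starts = zip(*(pos_zone + pos_bg)) if cfg.n_peaks else ((), ())
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": np.asarray(starts, dtype=int) + cfg.probe_bp,
            "signal": sig,
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return FeatureTrack(name=f"chip_{compartment}", records=df, kind="chip_signal")


def make_origins(genome: list[ChromosomeSpec], cfg: SyntheticConfig) -> pd.DataFrame:
    """Replication origins with timing/efficiency classes tied to compartments.

    Early and high-efficiency classes are biased (probability
    ``origin_bias``) toward euchromatic arms and pericentromeric zones; late
    and low-efficiency classes toward subtelomeric heterochromatin.  Returns
    a BED-like DataFrame (chrom, start, end, name, score, cls).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    partition = build_partition(genome, cfg.granule_bp)
    het = het_intervals(genome, cfg)
    eu = _interval_complement(genome, het)
    pericen = []
    subtel = []
    for c in genome:
        s = max(0, c.centromere[0] - cfg.pericentromere_bp)
        e = min(c.length, c.centromere[1] + cfg.pericentromere_bp)
        pericen.append((c.name, s, e))
        subtel.append((c.name, 0, cfg.telomere_bp + cfg.subtelomere_bp))
        subtel.append((c.name, c.length - cfg.telomere_bp - cfg.subtelomere_bp, c.length))
    whole = [(c.name, 0, c.length) for c in genome]

    rows = []
    counter = 0
    width = 100
    for cls in sorted(cfg.class_counts):
        timing, eff = cls.split("_")
        if timing == "late" or eff == "low":
            zone = subtel
        elif eff == "high":
            zone = eu + pericen
        else:
            zone = eu
        for _ in range(int(cfg.class_counts[cls])):
            target = zone if rng.random() < cfg.origin_bias else whole
            (chrom, start), = _sample_positions(rng, target, 1, width)
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": start + width,
                    "name": f"ori{counter:03d}", "score": 0, "cls": cls,
                }
            )
            counter += 1
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    return df.reset_index(drop=True)


def contacts_to_tsv(records: list[ContactRecord], path) -> None:
    """Write contact records as the 5-column TSV dialect the reader consumes."""
    with open(path, "w") as fh:
        fh.write("# chromA\tposA\tchromB\tposB\tcount\n")
        for r in records:
            fh.write(f"{r.chromA}\t{r.posA}\t{r.chromB}\t{r.posB}\t{r.frequency}\n")


def track_to_bed(track: FeatureTrack, path) -> None:
    df = track.records
    with open(path, "w") as fh:
        for k, row in enumerate(df.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak{k:05d}\t{row.signal:.6g}\n")


def origins_to_bed(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.cls}\n"
            )
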