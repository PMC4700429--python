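"""Synthetic genome, contact, ChIP and origin generators."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

import pombe3d as p3
from pombe3d.contacts import contacts_from_records
from pombe3d.exceptions import ConfigurationError
from pombe3d.features import map_binary, top_fraction_filter
from pombe3d.synthetic import (
    SyntheticConfig,
    contacts_to_tsv,
    het_granule_mask,
    het_intervals,
    make_chip_track,
    make_contacts,
    make_genome,
    make_origins,
    origins_to_bed,
    track_to_bed,
)


def test_default_genome_has_230_granules(genome, partition):
    assert partition.n_granules == 230
    assert [len(c.name) for c in genome] == [4, 5, 6]  # chrI, chrII, chrIII


def test_single_35kb_chromosome():
    cfg = SyntheticConfig(chromosome_lengths=(35_000,))
    part = p3.build_partition(make_genome(cfg))
    assert part.n_granules == 10


def test_genome_deterministic(cfg):
    a = make_genome(cfg)
    b = make_genome(SyntheticConfig(seed=cfg.seed))
    assert a == b


def test_contacts_roundtrip_and_byte_stability(genome, cfg, partition, tmp_path):
    records = make_contacts(genome, cfg)
    assert len(records) == cfg.n_pairs
    direct = contacts_from_records(records, partition)
    path1, path2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    contacts_to_tsv(records, path1)
    contacts_to_tsv(make_contacts(genome, SyntheticConfig(seed=cfg.seed)), path2)
    assert path1.read_bytes() == path2.read_bytes()  # seeded byte-identity
    reread = p3.read_contacts(path1, partition)
    assert np.array_equal(direct.i, reread.i)
    assert np.array_equal(direct.j, reread.j)
    assert np.allclose(direct.weight, reread.weight)


def test_contacts_too_many_pairs_error(genome):
    cfg = SyntheticConfig(n_pairs=10**6)
    with pytest.raises(ConfigurationError):
        make_contacts(genome, cfg)


def test_contacts_uniform_when_unbiased(genome, partition):
    """With no distance decay and no boosts, granule endpoint usage is
    uniform (chi-square at the 1% level)."""
    cfg = SyntheticConfig(
        seed=2, n_pairs=10_000, decay_alpha=0.0, inter_weight=1.0,
        cen_boost=1.0, tel_boost=1.0,
    )
    cset = contacts_from_records(make_contacts(genome, cfg), partition)
    counts = np.bincount(
        np.concatenate([cset.i, cset.j]), minlength=partition.n_granules
    )
    assert chisquare(counts).pvalue > 0.01


def test_contacts_centromere_boost_enriches_top_decile(genome, cfg, partition):
    strong = SyntheticConfig(seed=3, cen_boost=200.0)
    cset = contacts_from_records(make_contacts(genome, strong), partition)
    cen, _tel = _zone_masks(genome, partition, strong)
    cc = cen[cset.i] & cen[cset.j]
    order = np.argsort(-cset.weight)
    top = order[: cset.total // 10]
    assert cc[top].mean() > 3 * cc.mean() > 0


def _zone_masks(genome, partition, cfg):
    from pombe3d.synthetic import _zone_masks as zm

    return zm(genome, partition, cfg)


def test_chip_track_counts_and_probe_size(genome, cfg):
    t = make_chip_track(genome, cfg, "peripheral_het")
    assert len(t) == cfg.n_peaks
    assert np.all(t.records.end - t.records.start == cfg.probe_bp)


def test_chip_track_degenerate_bias(genome, partition):
    cfg = SyntheticConfig(seed=4, chip_bias=1.0)
    t = top_fraction_filter(make_chip_track(genome, cfg, "peripheral_het"), 0.05)
    het = het_granule_mask(genome, partition, cfg)
    flagged = map_binary(t, partition).values > 0
    assert np.all(het[flagged])  # every top peak inside planted heterochromatin


def test_chip_track_unbiased_uniform(genome, cfg):
    cfg0 = SyntheticConfig(seed=5, chip_bias=0.0, n_peaks=2000)
    t = make_chip_track(genome, cfg0, "peripheral_het")
    offsets = dict(zip([c.name for c in genome], np.cumsum([0] + [c.length for c in genome[:-1]])))
    pos = np.array([offsets[r.chrom] + r.start for r in t.records.itertuples()])
    total = sum(c.length for c in genome)
    assert kstest(pos / total, "uniform").pvalue > 0.01


def test_origins_counts_and_classes(genome, cfg, partition, tmp_path):
    df = make_origins(genome, cfg)
    for cls, n in cfg.class_counts.items():
        assert (df.cls == cls).sum() == n
    path = tmp_path / "origins.bed"
    origins_to_bed(df, path)
    sigs = p3.load_origins(path, partition)
    assert set(sigs) == {"early", "late", "high", "medium", "low"}
    early_total = sum(n for c, n in cfg.class_counts.items() if c.startswith("early"))
    assert sigs["early"].values.sum() <= early_total  # co-granular dedup allowed


def test_origins_full_bias_late_subtelomeric(genome):
    cfg = SyntheticConfig(seed=6, origin_bias=1.0)
    df = make_origins(genome, cfg)
    sub = []
    for c in genome:
        w = cfg.telomere_bp + cfg.subtelomere_bp
        sub.append((c.name, 0, w))
        sub.append((c.name, c.length - w, c.length))
    late_low = df[df.cls == "late_low"]
    for row in late_low.itertuples():
        assert any(
            ch == row.chrom and s <= row.start < e for ch, s, e in sub
        ), f"late_low origin outside subtelomeric zone: {row}"


def test_origins_deterministic(genome, cfg):
    a = make_origins(genome, cfg)
    b = make_origins(genome, SyntheticConfig(seed=cfg.seed))
    assert a.equals(b)


def test_track_to_bed_roundtrip(genome, cfg, partition, tmp_path):
    t = make_chip_track(genome, cfg, "central_eu")
    path = tmp_path / "track.bed"
    track_to_bed(t, path)
    back = p3.read_bed(path, name="eu")
    assert len(back) == len(t)
    assert np.allclose(
        np.sort(back.records.signal.to_numpy()), np.sort(t.records.signal.to_numpy()),
        rtol=1e-5,
    )


def test_het_intervals_cover_landmarks(genome, cfg, partition):
    het = het_intervals(genome, cfg)
    mask = het_granule_mask(genome, partition, cfg)
    for c in genome:
        cen_g = partition.bp_to_granule(c.name, (c.centromere[0] + c.centromere[1]) // 2)
        assert mask[cen_g]
        assert mask[partition.bp_to_granule(c.name, 0)]
    assert 0 < mask.sum() < partition.n_granules
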