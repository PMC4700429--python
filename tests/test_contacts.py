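"""Contact reading, granule aggregation and frequency-weighted subsampling."""

import numpy as np
import pytest

import pombe3d as p3
from pombe3d.contacts import (
    GranuleContactSet,
    SubsetSpec,
    assign_subsets,
    sample_subset,
)
from pombe3d.exceptions import (
    CalibrationError,
    ConfigurationError,
    ContactParseError,
)
from pombe3d.genome import ChromosomeSpec, build_partition


@pytest.fixture
def tiny_partition():
    c = ChromosomeSpec("chrA", 70_000, (35_000, 36_000), ((0, 100), (69_900, 70_000)))
    return build_partition([c], 3500)  # 20 granules


def write_tsv(path, rows, header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


def test_read_contacts_merges_and_drops(tiny_partition, tmp_path):
    rows = [
        ("chrA", 100, "chrA", 20_000, 2),   # granules 0-5
        ("chrA", 20_100, "chrA", 200, 3),   # same pair, reversed -> merged
        ("chrA", 100, "chrA", 200, 4),      # both ends granule 0 -> self, dropped
        ("chrA", 35_100, "chrA", 38_600, 1),  # granules 10,11 adjacent -> dropped
    ]
    path = write_tsv(tmp_path / "c.tsv", rows, header="# chromA\tposA\tchromB\tposB\tcount")
    cset = p3.read_contacts(path, tiny_partition)
    assert cset.total == 1
    assert (cset.i[0], cset.j[0]) == (0, 5)
    assert cset.weight[0] == 5  # 2 + 3 merged


def test_read_contacts_plain_header_tolerated(tiny_partition, tmp_path):
    path = write_tsv(
        tmp_path / "c.tsv",
        [("chrA", 100, "chrA", 20_000, 2)],
        header="chromA\tposA\tchromB\tposB\tcount",
    )
    assert p3.read_contacts(path, tiny_partition).total == 1


@pytest.mark.parametrize(
    "row",
    [
        ("chrA", 100, "chrA", 20_000),            # too few fields
        ("chrA", "xx", "chrA", 20_000, 2),        # non-numeric position
        ("chrA", 100, "chrA", 80_000, 2),         # off-chromosome coordinate
        ("chrZ", 100, "chrA", 20_000, 2),         # unknown chromosome
        ("chrA", 100, "chrA", 20_000, 0),         # frequency < 1
    ],
)
def test_read_contacts_malformed_line_number(tiny_partition, tmp_path, row):
    path = write_tsv(
        tmp_path / "bad.tsv",
        [("chrA", 100, "chrA", 24_000, 1), row],
    )
    with pytest.raises(ContactParseError) as err:
        p3.read_contacts(path, tiny_partition)
    assert err.value.line_number == 2


def make_cset(tiny_partition, n_pairs, weights=None):
    i = np.zeros(n_pairs, dtype=int)
    j = np.arange(2, n_pairs + 2)
    w = np.asarray(weights) if weights is not None else np.ones(n_pairs)
    return GranuleContactSet(i, j, w, tiny_partition)


def test_contact_set_invariants(tiny_partition):
    with pytest.raises(ConfigurationError):  # adjacent pair
        GranuleContactSet([0], [1], [1.0], tiny_partition)
    with pytest.raises(ConfigurationError):  # i >= j
        GranuleContactSet([5], [3], [1.0], tiny_partition)
    with pytest.raises(ConfigurationError):  # duplicate
        GranuleContactSet([0, 0], [5, 5], [1.0, 1.0], tiny_partition)


def test_sample_subset_sizes(tiny_partition):
    cset = make_cset(tiny_partition, 10)
    assert len(sample_subset(cset, SubsetSpec(fraction=0.2, seed=0))) == 2
    full = sample_subset(cset, SubsetSpec(fraction=1.0, seed=0))
    assert sorted(full) == list(range(10))
    with pytest.raises(ConfigurationError):
        sample_subset(cset, SubsetSpec(fraction=0.01, seed=0))  # 0.1 pair


def test_sample_subset_deterministic(tiny_partition):
    cset = make_cset(tiny_partition, 12, weights=np.arange(1, 13))
    a = sample_subset(cset, SubsetSpec(fraction=0.5, seed=42))
    b = sample_subset(cset, SubsetSpec(fraction=0.5, seed=42))
    assert np.array_equal(a, b)
    c = sample_subset(cset, SubsetSpec(fraction=0.5, seed=43))
    assert not np.array_equal(a, c)


def test_weighted_sampling_favours_heavy_pair(tiny_partition):
    """Weights 9:1, one draw: heavy pair selected ~90% of seeded draws."""
    cset = make_cset(tiny_partition, 2, weights=[9.0, 1.0])
    n = 4000
    hits = sum(
        sample_subset(cset, SubsetSpec(fraction=0.5, seed=s))[0] == 0
        for s in range(n)
    )
    p = 0.9
    assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_assign_subsets_forced_coverage(tiny_partition):
    """5 pairs, fraction 0.2, one structure: 1 drawn + 4 forced = all present."""
    cset = make_cset(tiny_partition, 5)
    subsets = assign_subsets(cset, SubsetSpec(fraction=0.2, seed=0), 1)
    assert len(subsets) == 1
    assert sorted(subsets[0]) == list(range(5))


def test_assign_subsets_full_fraction(tiny_partition):
    cset = make_cset(tiny_partition, 10)
    subsets = assign_subsets(cset, SubsetSpec(fraction=1.0, seed=0), 3)
    for s in subsets:
        assert sorted(s) == list(range(10))


def test_calibrate_preconditions(contact_set, geometry):
    with pytest.raises(ConfigurationError):
        p3.calibrate_fraction(contact_set, 1300.0, geometry=geometry)
    empty = GranuleContactSet(
        np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0), contact_set.partition
    )
    with pytest.raises(ConfigurationError):
        p3.calibrate_fraction(empty, 650.0, geometry=geometry)


def test_calibration_failure_reports_bracket(contact_set, geometry):
    """An unreachably compact target fails with the bracketing Rg values."""
    params = p3.EnergyParams(n_temps=4, sweeps_per_temp=10)
    with pytest.raises(CalibrationError) as err:
        p3.calibrate_fraction(
            contact_set, 20.0, geometry=geometry, params=params,
            n_structures=2, seed=0, max_iter=2,
        )
    assert "Rg" in str(err.value)
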