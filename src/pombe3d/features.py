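"""Linear feature tracks (ChIP enrichment, elements, replication origins) on granules.

Tracks arrive as BED-like interval records with a signal column; they are
projected onto the granule partition either as binary presence (any overlap)
or as per-granule counts of record midpoints.  ChIP tracks are first
restricted to their strongest signals (top 5% by default in the analyses this
package supports) because flooding the 3.5 kb granules with weak sites erases
spatial discrimination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CoordinateError, FeatureError
from .genome import GranulePartition

__all__ = [
    "FeatureTrack",
    "GranuleSignal",
    "read_bed",
    "top_fraction_filter",
    "map_binary",
    "map_counts",
    "load_origins",
    "TIMING_CLASSES",
    "EFFICIENCY_CLASSES",
]

TIMING_CLASSES = ("early", "late")
EFFICIENCY_CLASSES = ("high", "medium", "low")


@dataclass
class FeatureTrack:
    """A named set of interval records with a signal value.

    ``records`` is a DataFrame with columns chrom, start, end, signal
    (0-based half-open intervals).  ``kind`` is ``"chip_signal"`` for
    continuous enrichment or ``"point_element"`` for discrete elements.
    """

    name: str
    records: pd.DataFrame
    kind: str = "chip_signal"

    def __post_init__(self):
        req = {"chrom", "start", "end", "signal"}
        if not req.issubset(self.records.columns):
            raise FeatureError(f"track records need columns {sorted(req)}")
        if self.kind not in ("chip_signal", "point_element"):
            raise FeatureError(f"unknown track kind {self.kind!r}")
        r = self.records
        if len(r) and (np.any(r.start >= r.end) or np.any(r.start < 0)):
            raise FeatureError("invalid intervals in track")
        if len(r) and not np.all(np.isfinite(r.signal)):
            raise FeatureError("non-finite signal values in track")

    def __len__(self):
        return len(self.records)


@dataclass
class GranuleSignal:
    """Per-granule annotation: binary presence or a non-negative count."""

    name: str
    values: np.ndarray
    mode: str = "binary"  # or "count"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.mode == "binary":
            if not np.all(np.isin(self.values, (0, 1))):
                raise FeatureError("binary signal values must be 0 or 1")
        elif self.mode == "count":
            if np.any(self.values < 0) or not np.issubdtype(self.values.dtype, np.integer):
                raise FeatureError("count signal values must be non-negative integers")
        else:
            raise FeatureError(f"unknown signal mode {self.mode!r}")

    @property
    def n_set(self) -> int:
        return int(np.sum(self.values > 0))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"granule": np.arange(len(self.values)), "value": self.values}).to_csv(
            path, sep="\t", index=False
        )


def read_bed(path, name: str | None = None, kind: str = "chip_signal") -> FeatureTrack:
    """Read a 5-column BED (chrom, start, end, name, score) as a FeatureTrack.

    The BED score column becomes the signal.  Comment (#) and track lines are
    skipped.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score"],
        usecols=[0, 1, 2, 3, 4], dtype={0: str},
    )
    rec = pd.DataFrame(
        {"chrom": df.chrom, "start": df.start, "end": df.end, "signal": df.score}
    )
    return FeatureTrack(name=name or str(path), records=rec, kind=kind)


def top_fraction_filter(track: FeatureTrack, fraction: float) -> FeatureTrack:
    """Retain the ``ceil(fraction * N)`` records with the highest signal.

    Ties at the threshold are broken by genomic order (chromosome, then
    start), so exactly ``ceil(fraction * N)`` records survive.  Output keeps
    genomic order.  Idempotent at a fixed fraction.
    """
    if not 0 < fraction <= 1:
        raise FeatureError(f"fraction must be in (0, 1], got {fraction}")
    if track.kind != "chip_signal":
        raise FeatureError("top-fraction filtering applies to chip_signal tracks")
    n = len(track)
    if n == 0:
        warnings.warn(f"top_fraction_filter: track {track.name!r} is empty")
        return FeatureTrack(track.name, track.records.copy(), track.kind)
    keep = math.ceil(fraction * n)
    df = track.records.sort_values(
        ["signal", "chrom", "start"], ascending=[False, True, True], kind="stable"
    ).head(keep)
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return FeatureTrack(track.name, df, track.kind)


def _check_bounds(partition: GranulePartition, chrom: str, start: int, end: int):
    ci = partition.chrom_index(chrom)
    L = partition.chrom_lengths[ci]
    if not (0 <= start < end <= L):
        raise CoordinateError(
            f"record [{start}, {end}) off the end of chromosome {chrom!r} (length {L})"
        )


def map_binary(track: FeatureTrack, partition: GranulePartition) -> GranuleSignal:
    """1 for every granule overlapped by at least one record (any overlap), else 0."""
    values = np.zeros(partition.n_granules, dtype=np.int64)
    for row in track.records.itertuples(index=False):
        _check_bounds(partition, row.chrom, int(row.start), int(row.end))
        values[partition.overlapping_granules(row.chrom, int(row.start), int(row.end))] = 1
    return GranuleSignal(name=track.name, values=values, mode="binary")


def map_counts(track: FeatureTrack, partition: GranulePartition) -> GranuleSignal:
    """Per-granule count of records whose midpoint falls inside the granule.

    The midpoint rule makes counts additive over the partition; for 300 bp
    ChIP probes the count measures the enriched span inside the granule.
    """
    values = np.zeros(partition.n_granules, dtype=np.int64)
    for row in track.records.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        _check_bounds(partition, row.chrom, s, e)
        mid = (s + e) // 2
        values[partition.bp_to_granule(row.chrom, mid)] += 1
    return GranuleSignal(name=track.name, values=values, mode="count")


def _split_class(label: str) -> list[str]:
    parts = [p for p in label.replace(":", "_").replace(",", "_").split("_") if p]
    for p in parts:
        if p not in TIMING_CLASSES + EFFICIENCY_CLASSES:
            raise FeatureError(
                f"unknown origin class {p!r} (allowed: "
                f"{TIMING_CLASSES + EFFICIENCY_CLASSES})"
            )
    return parts


def load_origins(path, partition: GranulePartition) -> dict[str, GranuleSignal]:
    """Read replication origins (BED + class column) as per-class binary signals.

    The 6th column carries the class label: a timing class (early/late), an
    efficiency class (high/medium/low), or a combined label such as
    ``early_high``; combined labels contribute to both axis signals.
    Duplicated origins flag a granule once (binary).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "cls"],
        dtype={0: str, 5: str},
    )
    per_class: dict[str, np.ndarray] = {}
    for row in df.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        _check_bounds(partition, row.chrom, s, e)
        gs = partition.overlapping_granules(row.chrom, s, e)
        for cls in _split_class(str(row.cls)):
            arr = per_class.setdefault(cls, np.zeros(partition.n_granules, dtype=np.int64))
            arr[gs] = 1
    return {
        cls: GranuleSignal(name=f"origins_{cls}", values=v, mode="binary")
        for cls, v in per_class.items()
    }
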