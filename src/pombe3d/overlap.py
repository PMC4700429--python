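"""Linear (granule-level) and spatial (contour-level) co-localization statistics.

The linear statistic counts granules carrying each of two binary elements and
both; the spatial statistic counts pixels of two contour masks.  Both report
the Jaccard index and the min-normalised overlap; the directional coincidence
|A intersect B| / |A| quantifies how much of one element's territory lies
inside the other's.
"""

from __future__ import annotations

from dataclasses import dataclass


from .exceptions import ConfigurationError, FeatureError
from .density import ContourMask
from .features import GranuleSignal

__all__ = ["OverlapReport", "linear_overlap", "spatial_overlap", "coincidence"]


@dataclass(frozen=True)
class OverlapReport:
    """Counts and normalised overlaps of two sets (granules or pixels)."""

    n_a: int
    n_b: int
    n_intersection: int

    def __post_init__(self):
        if self.n_intersection > min(self.n_a, self.n_b):
            raise ConfigurationError("intersection larger than a set")

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_intersection

    @property
    def jaccard(self) -> float:
        return self.n_intersection / self.n_union if self.n_union else 0.0

    @property
    def min_overlap(self) -> float:
        m = min(self.n_a, self.n_b)
        return self.n_intersection / m if m else 0.0


def linear_overlap(a: GranuleSignal, b: GranuleSignal) -> OverlapReport:
    """Granule-level overlap of two binary signals on the same partition."""
    if a.mode != "binary" or b.mode != "binary":
        raise FeatureError("linear_overlap requires binary signals")
    if len(a.values) != len(b.values):
        raise FeatureError("signals are on different partitions")
    va = a.values > 0
    vb = b.values > 0
    return OverlapReport(
        n_a=int(va.sum()), n_b=int(vb.sum()), n_intersection=int((va & vb).sum())
    )


def spatial_overlap(a: ContourMask, b: ContourMask) -> OverlapReport:
    """Pixel-level overlap of two contour masks on congruent grids."""
    if a.mask.shape != b.mask.shape:
        raise ConfigurationError("contour masks are not congruent")
    return OverlapReport(
        n_a=int(a.mask.sum()),
        n_b=int(b.mask.sum()),
        n_intersection=int((a.mask & b.mask).sum()),
    )


def coincidence(a: ContourMask, b: ContourMask) -> float:
    """Directional coincidence of a within b: |A intersect B| / |A|."""
    if a.mask.shape != b.mask.shape:
        raise ConfigurationError("contour masks are not congruent")
    na = int(a.mask.sum())
    if na == 0:
        raise ConfigurationError("coincidence undefined for an empty mask")
    return int((a.mask & b.mask).sum()) / na
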