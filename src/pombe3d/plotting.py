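"""Matplotlib rendering: density heatmaps, contour overlays, impact profiles, Venns."""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "plot_density_map",
    "plot_contours",
    "plot_impact_profile",
    "plot_proportional_venn",
]


def _extent(grid_like):
    R = grid_like.nuclear_radius
    return (-R, R, 0, R)


def plot_density_map(grid, ax=None, cmap="magma", **imshow_kwargs):
    """Heatmap of a density (or relative density) grid on the (z, r) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        grid.values.T, origin="lower", extent=_extent(grid), aspect="auto",
        cmap=cmap, **imshow_kwargs,
    )
    ax.set_xlabel("z along SPB-nucleolus axis (nm)")
    ax.set_ylabel("r from axis (nm)")
    ax.figure.colorbar(im, ax=ax, label="density")
    return ax


def plot_contours(masks: dict, reference_map, ax=None):
    """Overlay contour masks (name -> ContourMask) on a relative density map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        reference_map.values.T, origin="lower", extent=_extent(reference_map),
        aspect="auto", cmap="Greys", alpha=0.6,
    )
    R = reference_map.nuclear_radius
    n = reference_map.npix
    z = np.linspace(-R, R, n)
    r = np.linspace(0, R, n)
    for name, cm in masks.items():
        ax.contour(z, r, cm.mask.T.astype(float), levels=[0.5])
        ax.plot([], [], label=name)
    ax.legend()
    ax.set_xlabel("z (nm)")
    ax.set_ylabel("r (nm)")
    return ax


def plot_impact_profile(profile, partition, element_mask=None, ax=None):
    """Per-granule % density change against concatenated-genome position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = partition.genome_position / 1e6
    ax.plot(x, profile.values, color="grey", lw=0.8)
    if element_mask is not None:
        sel = np.asarray(element_mask, dtype=bool)
        ax.plot(x[sel], profile.values[sel], "o", ms=4, color="tab:blue")
    ax.set_xlabel("genome position (Mb, chromosomes concatenated)")
    ax.set_ylabel("% density change")
    return ax


def _venn_center_distance(r1, r2, target_area):
    """Distance between circle centres giving a lens of the target area."""
    amax = np.pi * min(r1, r2) ** 2
    if target_area <= 0:
        return r1 + r2
    if target_area >= amax:
        return abs(r1 - r2)

    def lens_area(d):
        a1 = r1**2 * np.arccos(np.clip((d**2 + r1**2 - r2**2) / (2 * d * r1), -1, 1))
        a2 = r2**2 * np.arccos(np.clip((d**2 + r2**2 - r1**2) / (2 * d * r2), -1, 1))
        tri = 0.5 * np.sqrt(
            max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
        )
        return a1 + a2 - tri

    return brentq(
        lambda d: lens_area(d) - target_area, abs(r1 - r2) + 1e-9, r1 + r2 - 1e-9
    )


def plot_proportional_venn(report, labels=("A", "B"), ax=None):
    """Two-set Venn with circle areas proportional to counts and to the overlap.

    When both sets enclose the same signal fraction (as contour masks at one
    cut do by construction), the two circles are drawn equal-sized.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots()
    r1 = np.sqrt(max(report.n_a, 1) / np.pi)
    r2 = np.sqrt(max(report.n_b, 1) / np.pi)
    d = _venn_center_distance(r1, r2, float(report.n_intersection))
    ax.add_patch(Circle((0, 0), r1, alpha=0.4, color="tab:red"))
    ax.add_patch(Circle((d, 0), r2, alpha=0.4, color="tab:blue"))
    ax.text(-r1, r1, labels[0])
    ax.text(d + r2 * 0.5, r2, labels[1])
    pad = 0.2 * max(r1, r2)
    ax.set_xlim(-r1 - pad, d + r2 + pad)
    ax.set_ylim(-max(r1, r2) - pad, max(r1, r2) + pad)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
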