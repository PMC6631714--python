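"""Per-atom solvent-accessible surface area by the Shrake-Rupley method.

Test points are placed on a deterministic Fibonacci lattice over each atom's
probe-expanded sphere; a point is accessible when it lies outside every other
atom's probe-expanded sphere.  The exposed *fraction* divides by the full
probe-expanded sphere area, so it equals the accessible solid-angle fraction
and is radius-independent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import SiteModel


@dataclass
class SasaResult:
    areas: np.ndarray  # Å² per atom
    fractions: np.ndarray  # accessible fraction of the probe-expanded sphere

    def __post_init__(self) -> None:
        if np.any(self.areas < 0) or np.any(~np.isfinite(self.areas)):
            raise ValueError("SASA areas must be finite and non-negative")


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (n_points, 3)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    site: SiteModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom SASA of the (ligand-free) site.

    Deterministic for a fixed lattice: area_i = (accessible / total points)
    x 4 pi (r_i + probe)^2.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    coords = site.coords
    radii = site.vdw_radii + probe_radius
    n = len(radii)
    unit = fibonacci_sphere(n_points)
    areas = np.zeros(n)
    fractions = np.zeros(n)
    if n == 0:
        return SasaResult(areas, fractions)
    tree = cKDTree(coords)
    r_max = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        # only neighbours whose expanded sphere can reach atom i's surface
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + r_max) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        fractions[i] = frac
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(areas, fractions)
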