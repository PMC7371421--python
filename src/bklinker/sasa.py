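"""Shrake-Rupley numerical solvent-accessible surface area.

Each atom is inflated by the probe radius and sampled with a deterministic
golden-spiral point set; the accessible fraction of points (not inside any
other inflated sphere) times the inflated sphere area gives the per-atom
SASA. An isolated atom of radius r therefore scores exactly 4*pi*(r+probe)^2
irrespective of the point count.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["VDW_RADII", "sphere_points", "shrake_rupley"]

# Bondi-style van der Waals radii (A)
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52,
    "P": 1.80, "S": 1.80, "K": 2.75, "X": 1.70,
}


def sphere_points(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom SASA (A^2) of one conformation.

    Parameters
    ----------
    coords : (n_atoms, 3) positions in A.
    radii : per-atom van der Waals radii in A.
    probe : solvent probe radius (water: 1.4 A).
    n_points : quadrature points per atom; error scales ~1/n_points.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    inflated = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.empty(n)
    rmax = inflated.max()
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], inflated[i] + rmax)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return out
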