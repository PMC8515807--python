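"""Minimal conductor-like continuum solvation (COSMO / CPCM).

The dielectric response of the solvent is represented by polarization
charges Q on a discretized molecular cavity surface.  Under conductor
boundary conditions the surface charges satisfy A Q = -f(eps) V, where V is
the solute ESP at the surface points, A the tesserae interaction matrix
(Coulomb off-diagonal, a standard self-interaction diagonal), and

    f(eps) = (eps - 1) / (eps + x),   x in {0.5 (default), 0.0}

scales the perfect-conductor response back to the finite dielectric.  The
electrostatic solvation free energy is dG = 1/2 sum_i Q_i V_i.

The cavity is built from Fibonacci point sets on per-atom spheres of radius
(atomic radius + probe radius) with exposed-point filtering; the
spherical-cavity Born ion has the analytic dG = -f(eps) q^2 k_e / (2R)
against which the solver is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KCAL

DEFAULT_EPSILON = 80.4            # ambient water, CPCM default
DEFAULT_PROBE_RADIUS = 1.3        # A
DEFAULT_MIN_SPACING = 0.1         # A, minimal distance of adjacent points


def scaling_function(eps: float, variant: str = "cosmo") -> float:
    """f(eps): 'cosmo' -> (eps-1)/(eps+0.5); 'cpcm' -> (eps-1)/eps."""
    if eps <= 1:
        raise ValueError("dielectric constant must exceed 1")
    if variant == "cosmo":
        return (eps - 1.0) / (eps + 0.5)
    if variant == "cpcm":
        return (eps - 1.0) / eps
    raise ValueError(f"unknown scaling variant {variant!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5.0))
    theta = golden * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


@dataclass
class CavitySurface:
    points: np.ndarray             # (m, 3) A
    areas: np.ndarray              # A^2
    parent_atom: np.ndarray        # int
    sphere_radii: np.ndarray       # per-point parent sphere radius, A

    @property
    def n_points(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def build_cavity(
    atom_coords,
    radii,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    points_per_atom: int = 302,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> CavitySurface:
    """Exposed-point surface on interlocking atomic spheres.

    Each atom contributes a Fibonacci point set on a sphere of radius
    (radius + probe_radius); points buried inside any other atom's sphere
    are removed, and a greedy pass enforces the minimal spacing between
    adjacent surviving points.  Per-point areas are the parent sphere's
    area divided by its generated point count.
    """
    coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    R = radii + probe_radius
    pts, areas, parent, sph = [], [], [], []
    for a in range(len(coords)):
        local = coords[a] + R[a] * _fibonacci_sphere(points_per_atom)
        exposed = np.ones(len(local), dtype=bool)
        for b in range(len(coords)):
            if b == a:
                continue
            d = np.linalg.norm(local - coords[b], axis=1)
            exposed &= d >= R[b]
        if not exposed.any():
            warnings.warn(f"atom {a} fully buried; contributes no surface",
                          RuntimeWarning)
            continue
        kept = local[exposed]
        if min_spacing > 0 and len(kept) > 1:
            # greedy thinning in generation order
            sel = []
            for i, p in enumerate(kept):
                if all(np.linalg.norm(p - kept[j]) >= min_spacing for j in sel):
                    sel.append(i)
            kept = kept[sel]
        area = 4 * np.pi * R[a] ** 2 / points_per_atom
        pts.append(kept)
        areas.append(np.full(len(kept), area))
        parent.append(np.full(len(kept), a, dtype=int))
        sph.append(np.full(len(kept), R[a]))
    if not pts:
        raise ValueError("no exposed surface points")
    return CavitySurface(
        points=np.concatenate(pts),
        areas=np.concatenate(areas),
        parent_atom=np.concatenate(parent),
        sphere_radii=np.concatenate(sph),
    )


def interaction_matrix(surface: CavitySurface) -> np.ndarray:
    """Tesserae matrix A: off-diagonal k_e/d, diagonal k_e*1.0694*sqrt(4pi/S_i)
    (the standard COSMO self-interaction for a flat circular tessera)."""
    d = np.linalg.norm(
        surface.points[:, None, :] - surface.points[None, :, :], axis=-1
    )
    np.fill_diagonal(d, 1.0)
    A = COULOMB_KCAL / d
    np.fill_diagonal(A, COULOMB_KCAL * 1.0694 * np.sqrt(4 * np.pi / surface.areas))
    return A


def solve_conductor_charges(
    surface: CavitySurface,
    solute_charges,
    solute_coords,
    eps: float = DEFAULT_EPSILON,
    variant: str = "cosmo",
):
    """Polarization charges Q = -f(eps) A^-1 V and dG = 1/2 sum Q V.

    Returns (Q, dG_solv in kcal/mol).  sum(Q) approximates
    -f(eps) * total solute charge (Gauss law on the conductor surface).
    """
    q = np.atleast_1d(np.asarray(solute_charges, dtype=float))
    coords = np.atleast_2d(np.asarray(solute_coords, dtype=float))
    d = np.linalg.norm(
        surface.points[:, None, :] - coords[None, :, :], axis=-1
    )
    if np.any(d < 1e-10):
        raise ValueError("solute charge sits on the cavity surface")
    V = COULOMB_KCAL * (1.0 / d) @ q
    A = interaction_matrix(surface)
    f = scaling_function(eps, variant)
    try:
        Q = -f * np.linalg.solve(A, V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular tesserae interaction matrix") from exc
    dg = 0.5 * float(Q @ V)
    return Q, dg


def born_energy(q: float, radius: float, eps: float = DEFAULT_EPSILON,
                variant: str = "cosmo") -> float:
    """Analytic Born-ion solvation energy -f(eps) k_e q^2 / (2R), kcal/mol."""
    return -scaling_function(eps, variant) * COULOMB_KCAL * q * q / (2 * radius)


def solvation_coupling(Q, surface: CavitySurface, probe_positions) -> np.ndarray:
    """Potential of the polarization charges at probe points, kcal/mol/e.

    The classical analogue of the 'solvation' one-electron operator: linear
    in Q, superposable over surface points."""
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    pts = np.atleast_2d(np.asarray(probe_positions, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - surface.points[None, :, :], axis=-1)
    d = np.maximum(d, 1e-10)
    return COULOMB_KCAL * (1.0 / d) @ Q
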