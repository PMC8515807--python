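"""Embedding background charges from converged solvent distributions.

The solvent polarizes the solute through discrete background charges
obtained from the site distribution functions: each voxel of the solvation
grid carries

    q_i = dV * sum_gamma  q_gamma * rho_gamma * g_gamma(r_i)

(bulk-inclusive form; the excess-only variant replaces g by g-1).  The raw
set — one charge per voxel — is then coalesced by a Barnes-Hut-inspired
octree: cells far from the solute collapse to their charge barycenters,
conserving the monopole exactly, with positive and negative content split
so that near-cancelling cells never produce ill-defined centroids.

ESP-derived auxiliary atomic charges (CHelpG-style) are fitted by
constrained linear least squares on shells of points outside the
Breneman-Wiberg atomic radii.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .constants import COULOMB_KCAL
from .fields import Grid3D
from .rism3d import CorrelationFields
from .solvent import SolventModel

#: Breneman-Wiberg CHelpG exclusion radii (A), standard H/C/N/O set
BRENEMAN_WIBERG_RADII = {"H": 1.45, "C": 1.50, "N": 1.70, "O": 1.70}


@dataclass
class EmbeddingChargeSet:
    positions: np.ndarray          # (n, 3) A
    charges: np.ndarray            # e
    provenance: str = "raw-grid"   # raw-grid | coarsened

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.charges) != len(self.positions):
            raise ValueError("positions/charges length mismatch")

    @property
    def count(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def potential_at(self, points) -> np.ndarray:
        """ESP in kcal/mol/e at probe points (direct sum)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(pts))
        # chunked to bound memory on large raw-grid sets
        for i, p in enumerate(pts):
            d = np.linalg.norm(self.positions - p, axis=1)
            d = np.maximum(d, 1e-10)
            out[i] = COULOMB_KCAL * np.sum(self.charges / d)
        return out

    def to_text(self, path) -> None:
        data = np.column_stack([self.positions, self.charges])
        np.savetxt(path, data, fmt="%.10g",
                   header="x_A y_A z_A q_e  provenance=" + self.provenance)

    @classmethod
    def from_text(cls, path) -> "EmbeddingChargeSet":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(positions=data[:, :3], charges=data[:, 3], provenance="raw-grid")


def discretize_solvent_charge(
    fields: CorrelationFields,
    model: SolventModel,
    grid: Grid3D,
    solute_coords=None,
    exclusion_radius: float = 1.0,
    excess_only: bool = False,
    drop_below: float = 0.0,
    force: bool = False,
) -> EmbeddingChargeSet:
    """One point charge per voxel from the converged site distributions.

    Voxels within ``exclusion_radius`` of any solute atom are dropped (the
    repulsive cores make g ~ 0 there anyway).  ``drop_below`` optionally
    discards |q| below a threshold to shrink the raw set.
    """
    if not fields.converged and not force:
        raise ValueError("refusing to discretize unconverged fields "
                         "(pass force=True to override)")
    weight = fields.g - 1.0 if excess_only else fields.g
    dv = grid.voxel_volume
    dens = np.zeros(grid.n**3)
    for s in range(model.n_sites):
        dens += model.site_charges[s] * model.number_density * weight[s].ravel()
    q = dens * dv
    pos = grid.points()
    keep = np.ones(len(q), dtype=bool)
    if solute_coords is not None and len(np.atleast_2d(solute_coords)):
        tree = cKDTree(np.atleast_2d(solute_coords))
        d, _ = tree.query(pos)
        keep &= d > exclusion_radius
    if drop_below > 0:
        keep &= np.abs(q) > drop_below
    return EmbeddingChargeSet(positions=pos[keep], charges=q[keep],
                              provenance="raw-grid")


def _octree_coarsen(positions, charges, center, half, solute_tree, theta,
                    out_pos, out_q, max_leaf=8):
    n = len(charges)
    if n == 0:
        return
    size = 2.0 * half
    d_center, _ = solute_tree.query(center)
    # conservative opening distance: nearest possible point of the cell
    d_solute = max(d_center - np.sqrt(3.0) * half, 1e-12)
    collapse = (size / d_solute) < theta
    if collapse or n == 1:
        if n == 1:
            out_pos.append(positions[0])
            out_q.append(charges[0])
            return
        # sign-split barycenters: monopole conserved exactly per cell
        for sel in (charges > 0, charges < 0):
            if np.any(sel):
                qs = charges[sel]
                tot = qs.sum()
                bary = (qs[:, None] * positions[sel]).sum(axis=0) / tot
                out_pos.append(bary)
                out_q.append(tot)
        return
    if n <= max_leaf:
        for p, q in zip(positions, charges):
            out_pos.append(p)
            out_q.append(q)
        return
    oct_idx = (
        (positions[:, 0] > center[0]).astype(int)
        + 2 * (positions[:, 1] > center[1]).astype(int)
        + 4 * (positions[:, 2] > center[2]).astype(int)
    )
    for o in range(8):
        sel = oct_idx == o
        if not np.any(sel):
            continue
        off = np.array([
            0.5 if o & 1 else -0.5,
            0.5 if o & 2 else -0.5,
            0.5 if o & 4 else -0.5,
        ]) * half
        _octree_coarsen(positions[sel], charges[sel], center + off, half / 2,
                        solute_tree, theta, out_pos, out_q, max_leaf)


def coarsen_charges(
    raw: EmbeddingChargeSet,
    solute_coords,
    theta: float = 0.5,
) -> EmbeddingChargeSet:
    """Hierarchically merge background charges, treecode style.

    Octree cells whose (size / distance-to-nearest-solute-atom) falls below
    the opening parameter theta collapse into sign-split charge barycenters;
    the number of charges merged into one grows with distance from the
    solute while the near field stays fully resolved.
    """
    if theta <= 0:
        raise ValueError("opening parameter theta must be positive")
    if raw.count <= 1:
        return EmbeddingChargeSet(raw.positions.copy(), raw.charges.copy(),
                                  provenance="coarsened")
    solute_tree = cKDTree(np.atleast_2d(np.asarray(solute_coords, dtype=float)))
    lo = raw.positions.min(axis=0)
    hi = raw.positions.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * float(np.max(hi - lo)) + 1e-9
    out_pos: list = []
    out_q: list = []
    _octree_coarsen(raw.positions, raw.charges, center, half, solute_tree,
                    theta, out_pos, out_q)
    return EmbeddingChargeSet(
        positions=np.array(out_pos).reshape(-1, 3),
        charges=np.array(out_q),
        provenance="coarsened",
    )


@dataclass
class EspFitSpec:
    """CHelpG-style fit settings: exclusion radii per element, sample grid
    spacing, outer cutoff (max distance of a kept point from any atom)."""

    radii: dict = None
    grid_spacing: float = 0.3
    outer_cutoff: float = 2.8
    total_charge: float = 0.0

    def __post_init__(self):
        if self.radii is None:
            self.radii = dict(BRENEMAN_WIBERG_RADII)
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.outer_cutoff <= max(self.radii.values()):
            raise ValueError("outer cutoff must exceed the largest radius")


def esp_sample_points(elements, atom_coords, spec: EspFitSpec) -> np.ndarray:
    """Regular-grid sample points in the CHelpG shell: outside every atom's
    exclusion radius, within the outer cutoff of at least one atom."""
    coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    radii = np.array([spec.radii[e] for e in elements])
    lo = coords.min(axis=0) - spec.outer_cutoff
    hi = coords.max(axis=0) + spec.outer_cutoff
    axes = [np.arange(lo[i], hi[i] + spec.grid_spacing, spec.grid_spacing)
            for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    keep = np.all(d > radii[None, :], axis=1) & np.any(
        d <= spec.outer_cutoff, axis=1
    )
    return pts[keep]


def fit_esp_charges(
    sample_points,
    sample_potentials,
    atom_coords,
    spec: EspFitSpec = None,
) -> np.ndarray:
    """Least-squares atomic charges reproducing an ESP, with the total
    charge imposed as an exact equality constraint (KKT solve).

    sample_potentials in kcal/mol/e; returns charges in e.  Deterministic:
    the normal equations carry a fixed 1e-12 Tikhonov regularization and are
    solved directly.
    """
    if spec is None:
        spec = EspFitSpec()
    pts = np.asarray(sample_points, dtype=float).reshape(-1, 3)
    v = np.asarray(sample_potentials, dtype=float)
    coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    n_atoms = len(coords)
    if len(pts) < n_atoms + 1:
        raise ValueError("need at least n_atoms + 1 sample points")
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d < 1e-10):
        raise ValueError("sample point coincides with an atom")
    A = COULOMB_KCAL / d
    AtA = A.T @ A
    scale = np.trace(AtA) / n_atoms
    AtA = AtA + 1e-12 * scale * np.eye(n_atoms)
    Atv = A.T @ v
    kkt = np.zeros((n_atoms + 1, n_atoms + 1))
    kkt[:n_atoms, :n_atoms] = AtA
    kkt[:n_atoms, n_atoms] = 1.0
    kkt[n_atoms, :n_atoms] = 1.0
    rhs = np.concatenate([Atv, [spec.total_charge]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient ESP design matrix") from exc
    cond = np.linalg.cond(AtA)
    if cond > 1e12:
        raise ValueError(f"rank-deficient ESP design matrix (cond={cond:.1e})")
    return sol[:n_atoms]


def embedding_energy_operator(charges: EmbeddingChargeSet, solute):
    """Classical electrostatic coupling of background charges to the solute.

    Returns (energy in kcal/mol, field at each solute atom in kcal/mol/e/A).
    This is the classical contract a surrogate electronic model consumes in
    place of the one-electron embedding operator of a QM code.
    """
    coords = solute.coords
    q_at = solute.charges
    if charges.count == 0:
        return 0.0, np.zeros_like(coords)
    dvec = coords[:, None, :] - charges.positions[None, :, :]
    d = np.linalg.norm(dvec, axis=-1)
    if np.any(d < 1e-6):
        warnings.warn("embedding charge overlaps a solute atom; capping",
                      RuntimeWarning)
        d = np.maximum(d, 1e-6)
    inv = 1.0 / d
    energy = COULOMB_KCAL * float(np.sum(q_at[:, None] * charges.charges[None, :] * inv))
    field = COULOMB_KCAL * np.sum(
        charges.charges[None, :, None] * dvec * inv[:, :, None] ** 3, axis=1
    )
    return energy, field
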