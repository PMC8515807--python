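"""Cubic grids and solute-solvent interaction potentials u_gamma(r).

The solute enters the 3D solvation solver only through per-solvent-site
potential grids: a Lennard-Jones dispersion-repulsion part built with
Lorentz-Berthelot combining, and an electrostatic part from the solute's
partial charges acting on the solvent site charges.  The Coulomb part is
Ewald-split into an erfc short-range grid plus an analytic Gaussian
long-range term carried in k-space, so that the periodic FFT convolution in
the solver never sees the bare 1/r tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_KCAL
from .cube import CubeVolume
from .solvent import SolventModel

#: default cap on beta*u near nuclei (dimensionless), see module docs
DEFAULT_BETA_U_CAP = 700.0


@dataclass
class Grid3D:
    """Uniform cubic grid: n points per axis, spacing in Angstrom.

    Grid point (i,j,k) sits at origin + spacing*(i,j,k); with even n the
    nominal center lands on the point i=n/2 on each axis.
    """

    n: int
    spacing: float
    origin: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.n < 8:
            raise ValueError("grid needs at least 8 points per axis")
        if self.n % 2 != 0:
            raise ValueError("n_points must be even (FFT-friendly)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def box_length(self) -> float:
        return self.n * self.spacing

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def axes(self):
        ax = self.origin[:, None] + self.spacing * np.arange(self.n)[None, :]
        return ax[0], ax[1], ax[2]

    def meshgrid(self):
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")

    def points(self) -> np.ndarray:
        X, Y, Z = self.meshgrid()
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def k_meshgrid(self):
        """Angular wavenumber components matching numpy's FFT layout (A^-1)."""
        k1 = 2 * np.pi * np.fft.fftfreq(self.n, d=self.spacing)
        return np.meshgrid(k1, k1, k1, indexing="ij")

    def k_magnitude(self) -> np.ndarray:
        KX, KY, KZ = self.k_meshgrid()
        return np.sqrt(KX**2 + KY**2 + KZ**2)

    def as_cube(self, values, atom_numbers=None, atom_coords=None) -> CubeVolume:
        return CubeVolume(
            origin=self.origin,
            spacing=np.repeat(self.spacing, 3),
            values=np.asarray(values).reshape(self.n, self.n, self.n),
            atom_numbers=list(atom_numbers or []),
            atom_coords=atom_coords,
        )


def build_grid(n: int, spacing: float, center=(0.0, 0.0, 0.0)) -> Grid3D:
    """Grid whose mid-box point coincides with ``center``.

    Defaults used throughout the package are n=120, spacing=0.5 A
    (box length 60 A)."""
    center = np.asarray(center, dtype=float)
    origin = center - spacing * (n // 2)
    return Grid3D(n=n, spacing=spacing, origin=origin)


@dataclass
class SoluteConformer:
    """Rigid solute geometry with point charges and LJ parameters."""

    elements: list
    coords: np.ndarray             # (n, 3) A
    charges: np.ndarray            # e
    lj_sigma: Optional[np.ndarray] = None    # A
    lj_epsilon: Optional[np.ndarray] = None  # kcal/mol
    roles: dict = field(default_factory=dict)  # e.g. {"nitroxide_N": 0}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("solute coordinates must be finite")
        if len(self.charges) != len(self.elements):
            raise ValueError("charges length does not match elements")
        if self.lj_sigma is not None:
            self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        if self.lj_epsilon is not None:
            self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_charges(self, charges) -> "SoluteConformer":
        return SoluteConformer(
            elements=list(self.elements),
            coords=self.coords.copy(),
            charges=np.asarray(charges, dtype=float),
            lj_sigma=None if self.lj_sigma is None else self.lj_sigma.copy(),
            lj_epsilon=None if self.lj_epsilon is None else self.lj_epsilon.copy(),
            roles=dict(self.roles),
        )


def lj_potential(
    solute: SoluteConformer,
    model: SolventModel,
    grid: Grid3D,
    cap_kcal: Optional[float] = None,
) -> np.ndarray:
    """12-6 potential per solvent site, shape (n_sites, n, n, n), kcal/mol.

    Lorentz-Berthelot combining; values are capped at ``cap_kcal``
    (default: 700 kT at the solvent temperature) to keep exp(-beta*u)
    evaluable right on top of nuclei.
    """
    if solute.lj_sigma is None or solute.lj_epsilon is None:
        raise ValueError("solute lacks LJ parameters")
    if cap_kcal is None:
        cap_kcal = DEFAULT_BETA_U_CAP / model.beta
    X, Y, Z = grid.meshgrid()
    out = np.zeros((model.n_sites, grid.n, grid.n, grid.n))
    for g in range(model.n_sites):
        sg, eg = model.lj_sigma[g], model.lj_epsilon[g]
        acc = np.zeros_like(X)
        for a in range(solute.n_atoms):
            ea = np.sqrt(solute.lj_epsilon[a] * eg)
            if ea == 0.0:
                continue
            sa = 0.5 * (solute.lj_sigma[a] + sg)
            dx = X - solute.coords[a, 0]
            dy = Y - solute.coords[a, 1]
            dz = Z - solute.coords[a, 2]
            r2 = dx * dx + dy * dy + dz * dz
            np.maximum(r2, 1e-12, out=r2)
            s6 = (sa * sa / r2) ** 3
            acc += 4 * ea * (s6 * s6 - s6)
        out[g] = np.minimum(acc, cap_kcal)
    return out


@dataclass
class SplitCoulomb:
    """Ewald-split solute electrostatic potential (per unit probe charge).

    v_short: erfc-screened grid in kcal/mol/e;  v_long_k: analytic Fourier
    coefficients of the smooth part on the grid's k-mesh (the k=0 element is
    set to zero, i.e. a uniform neutralizing background);  eta: splitting
    width in Angstrom.
    """

    v_short: np.ndarray
    v_long_k: np.ndarray
    eta: float
    grid: Grid3D
    charges: np.ndarray
    positions: np.ndarray

    def v_long_real(self, points) -> np.ndarray:
        """The smooth erf part evaluated directly in real space (for
        recombination checks; no background term)."""
        from scipy.special import erf

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.positions[None, :, :], axis=-1)
        d = np.maximum(d, 1e-12)
        return COULOMB_KCAL * np.sum(self.charges * erf(d / self.eta) / d, axis=1)

    def direct(self, points) -> np.ndarray:
        """Unsplit direct sum k_e * sum q/r at probe points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.positions[None, :, :], axis=-1)
        d = np.maximum(d, 1e-12)
        return COULOMB_KCAL * np.sum(self.charges / d, axis=1)


def coulomb_potential(
    charges,
    positions,
    grid: Grid3D,
    eta: float = 1.0,
) -> SplitCoulomb:
    """Ewald-split electrostatic potential of solute point charges.

    Returns the short-range erfc grid and the analytic long-range k-space
    coefficients; v_short(r) + v_long(r) recombine to the direct Coulomb sum
    everywhere away from the nuclei.
    """
    if eta <= 0:
        raise ValueError("splitting width eta must be positive")
    charges = np.asarray(charges, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    X, Y, Z = grid.meshgrid()
    v_short = np.zeros_like(X)
    for q, pos in zip(charges, positions):
        if q == 0.0:
            continue
        dx = X - pos[0]
        dy = Y - pos[1]
        dz = Z - pos[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r = np.maximum(r, 1e-12)
        v_short += COULOMB_KCAL * q * erfc(r / eta) / r
    KX, KY, KZ = grid.k_meshgrid()
    k2 = KX**2 + KY**2 + KZ**2
    v_long_k = np.zeros_like(k2, dtype=complex)
    if np.any(charges != 0.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            kernel = np.where(k2 > 0, 4 * np.pi / np.where(k2 > 0, k2, 1.0), 0.0)
        kernel = kernel * np.exp(-k2 * eta**2 / 4)
        phase = np.zeros_like(k2, dtype=complex)
        for q, pos in zip(charges, positions):
            rel = pos - grid.origin
            phase += q * np.exp(-1j * (KX * rel[0] + KY * rel[1] + KZ * rel[2]))
        # FFT-convention coefficients: multiply by inverse voxel volume when
        # pairing with numpy ifftn of grid-sampled data
        v_long_k = COULOMB_KCAL * kernel * phase / grid.voxel_volume
    return SplitCoulomb(
        v_short=v_short,
        v_long_k=v_long_k,
        eta=eta,
        grid=grid,
        charges=charges,
        positions=positions,
    )


def solvent_site_potentials(
    solute: SoluteConformer,
    model: SolventModel,
    grid: Grid3D,
    eta: float = 1.0,
    cap_kcal: Optional[float] = None,
):
    """(u_short per site, SplitCoulomb) pair consumed by the 3D solver.

    u_short[g] = u_LJ[g] + q_g * v_short, in kcal/mol; the long-range
    electrostatic part stays analytic in k-space.
    """
    if cap_kcal is None:
        cap_kcal = DEFAULT_BETA_U_CAP / model.beta
    # LJ must stay uncapped until combined with the electrostatics: right on
    # a nucleus the r^-12 core has to dominate the attractive Coulomb
    # singularity before the symmetric cap is applied
    ulj = lj_potential(solute, model, grid, cap_kcal=np.inf)
    split = coulomb_potential(solute.charges, solute.coords, grid, eta=eta)
    u_short = np.empty_like(ulj)
    for g in range(model.n_sites):
        u_short[g] = np.clip(
            ulj[g] + model.site_charges[g] * split.v_short, -cap_kcal, cap_kcal
        )
    return u_short, split
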