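"""Pure-solvent models and the site-site susceptibility chi_gg'(k).

The 3D solvation solver needs the pure solvent only through its site-site
susceptibility (the density-density correlation of the bulk liquid),

    chi_gg'(k) = omega_gg'(k) + rho * h_gg'(k),

a dimensionless matrix-valued function of the radial wavenumber.  omega is
the rigid intramolecular structure factor, sin(kL)/(kL) for a site pair at
fixed distance L, and h_gg'(k) is the Fourier-transformed total correlation
function of the pure liquid, here produced by a 1D XRISM solve with
Ng-renormalized Coulomb tails.  The normalization convention is recorded in
every table ("omega+rho*h/dimensionless") so consumers can refuse mismatched
inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dst

from .constants import COULOMB_KCAL, beta_kcal

CHI_CONVENTION = "omega+rho*h/dimensionless"


@dataclass
class SolventModel:
    """Rigid-molecule solvent definition.

    Sites are explicit (a water is O, H1, H2 with identical H parameters);
    number_density is the molecular number density in A^-3, so every site
    carries that same density.
    """

    site_names: list
    site_coords: np.ndarray        # (n, 3) A, rigid molecular frame
    site_charges: np.ndarray       # e
    lj_sigma: np.ndarray           # A
    lj_epsilon: np.ndarray         # kcal/mol
    number_density: float          # molecules / A^3
    dielectric_constant: float
    temperature: float = 298.15    # K

    def __post_init__(self):
        self.site_coords = np.asarray(self.site_coords, dtype=float).reshape(-1, 3)
        self.site_charges = np.asarray(self.site_charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        n = len(self.site_names)
        for arr, nm in [
            (self.site_coords, "site_coords"),
            (self.site_charges, "site_charges"),
            (self.lj_sigma, "lj_sigma"),
            (self.lj_epsilon, "lj_epsilon"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{nm} length does not match site_names")
        if self.number_density <= 0:
            raise ValueError("number_density must be positive")
        total = float(self.site_charges.sum())
        if abs(total) > 1e-12 and abs(total) < 1e-6:
            raise ValueError(f"solvent net charge {total} is nonzero but tiny; "
                             "charges look mis-specified")

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def beta(self) -> float:
        return beta_kcal(self.temperature)

    def distances(self) -> np.ndarray:
        d = self.site_coords[:, None, :] - self.site_coords[None, :, :]
        return np.linalg.norm(d, axis=-1)


def spce_water(temperature: float = 298.15) -> SolventModel:
    """SPC/E-like 3-site rigid water (the shipped default solvent).

    Dielectric constant 78.4 and number density 0.0333295 A^-3 follow the
    modified-SPC/E ambient-water parameterization used for precomputed
    susceptibilities.
    """
    theta = np.deg2rad(109.47)
    r_oh = 1.0
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh, 0.0, 0.0],
            [r_oh * np.cos(theta), r_oh * np.sin(theta), 0.0],
        ]
    )
    return SolventModel(
        site_names=["O", "H", "H"],
        site_coords=coords,
        site_charges=np.array([-0.8476, 0.4238, 0.4238]),
        lj_sigma=np.array([3.166, 1.0, 1.0]),
        lj_epsilon=np.array([0.1554, 0.0460, 0.0460]),
        number_density=0.0333295,
        dielectric_constant=78.4,
        temperature=temperature,
    )


TIP3P_CHARGES = {"O": -0.834, "H": 0.417}


@dataclass
class SusceptibilityTable:
    """chi_gg'(k) on a uniform radial k-grid, plus provenance.

    provenance is one of {"intramolecular-only", "rism1d", "file"}.
    """

    k_grid: np.ndarray             # A^-1
    chi: np.ndarray                # (nk, n_sites, n_sites)
    site_names: list
    number_density: float
    temperature: float
    provenance: str = "intramolecular-only"
    convention: str = CHI_CONVENTION

    def __post_init__(self):
        self.k_grid = np.asarray(self.k_grid, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.shape[0] != self.k_grid.size:
            raise ValueError("chi first axis must match k_grid")
        if not np.allclose(self.chi, np.swapaxes(self.chi, 1, 2), atol=1e-10):
            raise ValueError("chi must be symmetric in the site indices")

    def interpolate(self, k) -> np.ndarray:
        """chi at arbitrary |k| values (linear interpolation, flat beyond range)."""
        k = np.asarray(k, dtype=float)
        if k.max() > self.k_grid.max() * (1 + 1e-9):
            raise ValueError(
                f"requested k={k.max():.3f} beyond table range "
                f"{self.k_grid.max():.3f} A^-1"
            )
        n = len(self.site_names)
        out = np.empty(k.shape + (n, n))
        for a in range(n):
            for b in range(n):
                out[..., a, b] = np.interp(k, self.k_grid, self.chi[:, a, b])
        return out


def build_intramolecular_matrix(model: SolventModel, k_grid) -> SusceptibilityTable:
    """omega_gg'(k) = j0(k * L_gg') for the rigid intramolecular geometry."""
    k = np.asarray(k_grid, dtype=float)
    if np.any(k < 0):
        raise ValueError("k_grid must be non-negative")
    L = model.distances()
    n = model.n_sites
    off_diag_zero = (L < 1e-10) & ~np.eye(n, dtype=bool)
    if off_diag_zero.any():
        raise ValueError("coincident distinct solvent sites (L=0 off-diagonal)")
    kl = k[:, None, None] * L[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(kl > 1e-12, np.sin(kl) / np.where(kl > 1e-12, kl, 1.0), 1.0)
    for i in range(n):
        omega[:, i, i] = 1.0
    return SusceptibilityTable(
        k_grid=k,
        chi=omega,
        site_names=list(model.site_names),
        number_density=model.number_density,
        temperature=model.temperature,
        provenance="intramolecular-only",
    )


# ---------------------------------------------------------------------------
# radial Fourier-Bessel transforms on a uniform grid (DST-I based)

def _ft_grids(n_points: int, dr: float):
    r = dr * np.arange(1, n_points + 1)
    dk = np.pi / ((n_points + 1) * dr)
    k = dk * np.arange(1, n_points + 1)
    return r, k, dk


def fbt_forward(f_r, r, dr):
    """f(r) -> fhat(k) = (4 pi / k) int r f(r) sin(kr) dr on DST-I grids."""
    k = (np.pi / ((len(r) + 1) * dr)) * np.arange(1, len(r) + 1)
    return (2 * np.pi * dr / k) * dst(r * f_r, type=1)


def fbt_inverse(f_k, r, dr):
    k = (np.pi / ((len(r) + 1) * dr)) * np.arange(1, len(r) + 1)
    dk = k[0]
    return dk / (4 * np.pi**2 * r) * dst(k * f_k, type=1)


@dataclass
class Rism1dResult:
    r: np.ndarray
    k: np.ndarray
    h_r: np.ndarray                # (n, n, nr)
    c_r: np.ndarray
    g_r: np.ndarray
    h_k: np.ndarray
    residuals: list
    converged: bool
    closure: str


def _closure_g(tstar, kind: str, order: int):
    if kind == "hnc":
        # the +50 clamp only guards transient overflow during iteration;
        # converged liquid-state solutions stay far below it
        return np.exp(np.minimum(tstar, 50.0))
    # PSE-k: exp branch for tstar<=0, k-term Taylor partial sum above
    g = np.exp(np.minimum(tstar, 0.0))
    pos = tstar > 0
    if np.any(pos):
        t = tstar[pos]
        s = np.ones_like(t)
        term = np.ones_like(t)
        for i in range(1, order + 1):
            term = term * t / i
            s = s + term
        g[pos] = s
    return g


def solve_rism1d(
    model: SolventModel,
    closure: str = "kh",
    n_points: int = 2048,
    dr: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 20000,
    mix: float = 0.25,
    eta: float = 1.0,
) -> Rism1dResult:
    """Solve the pure-solvent site-site (XRISM) equations on a radial grid.

    closure: "hnc", "kh" (= PSE-1), or "pseN" for order N.  Long-range
    Coulomb tails are Ng-separated: the smooth erf part is handled with its
    analytic Fourier transform so that only short-ranged functions are
    discretely transformed.  Iteration is damped Picard on the short-range
    direct correlation function; residual is the max-norm of its update.
    """
    kind, order = _parse_closure(closure)
    n = model.n_sites
    beta = model.beta
    rho = model.number_density
    r, k, dk = _ft_grids(n_points, dr)

    q_full = model.site_charges
    sig = 0.5 * (model.lj_sigma[:, None] + model.lj_sigma[None, :])
    eps = np.sqrt(model.lj_epsilon[:, None] * model.lj_epsilon[None, :])
    from scipy.special import erf

    ulj = np.empty((n, n, n_points))
    for a in range(n):
        for b in range(n):
            if eps[a, b] > 0 and sig[a, b] > 0:
                sr = sig[a, b] / r
                ulj[a, b] = 4 * eps[a, b] * (sr**12 - sr**6)
            else:
                ulj[a, b] = 0.0

    # intramolecular matrix on the k grid
    omega = build_intramolecular_matrix(model, k).chi  # (nk, n, n)
    ident = np.eye(n)

    def potentials(lam):
        q = lam * q_full
        qq = q[:, None] * q[None, :]
        u = ulj + COULOMB_KCAL * qq[:, :, None] / r
        ulr = COULOMB_KCAL * qq[:, :, None] * erf(r / eta) / r
        ulk = (
            COULOMB_KCAL * qq[:, :, None] * 4 * np.pi / k**2
            * np.exp(-(k**2) * eta**2 / 4)
        )
        return np.minimum(beta * u, 700.0), ulr, ulk

    def iterate(bu, u_long_r, u_long_k, cs, n_iter, stage_tol):
        t_r = np.zeros_like(cs)
        residuals = []
        for _ in range(n_iter):
            # OZ in k-space: H = (I - W C rho)^-1 W C W with C = Cs - b*Ulong
            ck = np.empty((n_points, n, n))
            for a in range(n):
                for b in range(a, n):
                    col = fbt_forward(cs[a, b], r, dr) - beta * u_long_k[a, b]
                    ck[:, a, b] = col
                    ck[:, b, a] = col
            WC = omega @ ck
            M = ident[None, :, :] - rho * WC
            rhs = WC @ omega
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                sol = np.stack([
                    np.linalg.lstsq(M[m], rhs[m], rcond=None)[0]
                    for m in range(n_points)
                ])
            hk = 0.5 * (sol + np.swapaxes(sol, 1, 2))
            # (h - c) is short-ranged once the analytic Coulomb parts cancel
            for a in range(n):
                for b in range(a, n):
                    # renormalized t: (h - c)_short = h_k - cs_k; the analytic
                    # +beta*u_long tail of t is restored in r-space
                    tk = hk[:, a, b] - ck[:, a, b] - beta * u_long_k[a, b]
                    row = fbt_inverse(tk, r, dr) + beta * u_long_r[a, b]
                    t_r[a, b] = row
                    t_r[b, a] = row
            g = _closure_g(-bu + t_r, kind, order)
            cs_new = g - 1.0 - t_r + beta * u_long_r
            res = float(np.max(np.abs(cs_new - cs)))
            residuals.append(res)
            if res < stage_tol:
                return cs_new, t_r, residuals, True
            cs = cs + mix * (cs_new - cs)
        return cs, t_r, residuals, False

    # charge-ramp homotopy: the neutral LJ skeleton first, then scale the
    # site charges up in stages, reusing the previous stage's solution
    if np.any(q_full != 0):
        stages = [0.0, 0.4, 0.7, 0.9, 1.0]
    else:
        stages = [1.0]
    bu, u_long_r, u_long_k = potentials(stages[0])
    cs = np.exp(-bu) - 1.0 + beta * u_long_r
    residuals = []
    converged = False
    for lam in stages:
        bu, u_long_r, u_long_k = potentials(lam)
        final = lam == stages[-1]
        stage_tol = tol if final else max(tol, 1e-4)
        n_iter = max_iter if final else max_iter // 4
        cs, t_r, res_hist, converged = iterate(bu, u_long_r, u_long_k, cs,
                                               n_iter, stage_tol)
        residuals.extend(res_hist)
    if not converged:
        warnings.warn(
            f"1D RISM not converged after {len(residuals)} total iterations "
            f"(last residual {residuals[-1]:.2e})",
            RuntimeWarning,
        )
    g = _closure_g(-bu + t_r, kind, order)
    h_r = g - 1.0
    h_k = np.empty((n, n, n_points))
    for a in range(n):
        for b in range(n):
            h_k[a, b] = fbt_forward(h_r[a, b], r, dr)
    return Rism1dResult(
        r=r, k=k, h_r=h_r, c_r=cs - beta * u_long_r, g_r=g, h_k=h_k,
        residuals=residuals, converged=converged, closure=closure,
    )


def _parse_closure(closure: str):
    c = closure.lower()
    if c == "hnc":
        return "hnc", 0
    if c == "kh" or c == "pse1":
        return "pse", 1
    if c.startswith("pse"):
        order = int(c[3:])
        if order < 1:
            raise ValueError("PSE order must be >= 1")
        return "pse", order
    raise ValueError(f"unknown closure {closure!r}")


def assemble_susceptibility(
    omega: SusceptibilityTable, h_k: np.ndarray, model: SolventModel
) -> SusceptibilityTable:
    """chi(k) = omega(k) + rho * h(k); h_k shaped (n, n, nk) on omega's grid."""
    h_k = np.asarray(h_k, dtype=float)
    nk = omega.k_grid.size
    if h_k.shape != (model.n_sites, model.n_sites, nk):
        raise ValueError("h_k grid does not match omega's k_grid")
    chi = omega.chi + model.number_density * np.moveaxis(h_k, -1, 0)
    chi = 0.5 * (chi + np.swapaxes(chi, 1, 2))
    return SusceptibilityTable(
        k_grid=omega.k_grid,
        chi=chi,
        site_names=list(omega.site_names),
        number_density=model.number_density,
        temperature=model.temperature,
        provenance="rism1d",
    )


def build_water_susceptibility(
    model: SolventModel = None, closure: str = "kh", **solver_kwargs
) -> SusceptibilityTable:
    """Convenience: 1D-solve the given (default SPC/E-like) solvent and
    assemble chi on the solver's k grid, prepending k=0 by extrapolation."""
    if model is None:
        model = spce_water()
    res = solve_rism1d(model, closure=closure, **solver_kwargs)
    omega = build_intramolecular_matrix(model, res.k)
    table = assemble_susceptibility(omega, res.h_k, model)
    table.provenance = "rism1d"
    return table


def write_chi(path, table: SusceptibilityTable) -> None:
    """Columnar text serialization: header lines, then k and the upper
    triangle of chi row-wise."""
    n = len(table.site_names)
    pairs = [(a, b) for a in range(n) for b in range(a, n)]
    with open(path, "w") as fh:
        fh.write("# ecrism susceptibility table\n")
        fh.write(f"# sites: {' '.join(table.site_names)}\n")
        fh.write(f"# number_density: {table.number_density:.10g}\n")
        fh.write(f"# temperature: {table.temperature:.6g}\n")
        fh.write(f"# provenance: {table.provenance}\n")
        fh.write(f"# convention: {table.convention}\n")
        fh.write("# k " + " ".join(
            f"chi[{table.site_names[a]},{table.site_names[b]}]" for a, b in pairs
        ) + "\n")
        for i, k in enumerate(table.k_grid):
            row = " ".join(f"{table.chi[i, a, b]:.12e}" for a, b in pairs)
            fh.write(f"{k:.10e} {row}\n")


def read_chi(path) -> SusceptibilityTable:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(x) for x in line.split()])
    if "convention" not in meta:
        raise ValueError("susceptibility file lacks a convention tag; refusing to load")
    if meta["convention"] != CHI_CONVENTION:
        raise ValueError(f"unsupported chi convention {meta['convention']!r}")
    sites = meta["sites"].split()
    n = len(sites)
    pairs = [(a, b) for a in range(n) for b in range(a, n)]
    data = np.array(rows)
    if data.shape[1] != 1 + len(pairs):
        raise ValueError("susceptibility file truncated or malformed")
    k = data[:, 0]
    chi = np.empty((len(k), n, n))
    for col, (a, b) in enumerate(pairs, start=1):
        chi[:, a, b] = data[:, col]
        chi[:, b, a] = data[:, col]
    return SusceptibilityTable(
        k_grid=k,
        chi=chi,
        site_names=sites,
        number_density=float(meta.get("number_density", 0.0)),
        temperature=float(meta.get("temperature", 298.15)),
        provenance=meta.get("provenance", "file"),
    )
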