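"""3D solver: closures, OZ convolution, convergence, chemical potential."""

import numpy as np
import pytest

from ecrism.fields import build_grid, solvent_site_potentials
from ecrism.rism3d import (
    ClosureSpec,
    apply_closure,
    chi_on_grid,
    excess_chemical_potential,
    oz_step,
    solve,
)
from ecrism.solvent import build_intramolecular_matrix


def kh_closure_reference(tstar):
    """Hand-coded Kovalenko-Hirata closure: exp below zero, linear above."""
    return np.where(tstar <= 0, np.exp(np.minimum(tstar, 0)), 1.0 + tstar)


class TestClosures:
    def test_pse1_is_bitwise_kovalenko_hirata(self):
        rng = np.random.default_rng(12)
        t = rng.normal(scale=3.0, size=(4, 16, 16, 16))
        g_pse1 = ClosureSpec("pse", 1).g_of_tstar(t)
        assert np.array_equal(g_pse1, kh_closure_reference(t))

    def test_pse50_approaches_hnc(self):
        rng = np.random.default_rng(13)
        t = rng.uniform(-20, 4.9, size=(100000,))
        g50 = ClosureSpec("pse", 50).g_of_tstar(t)
        ghnc = ClosureSpec("hnc").g_of_tstar(t)
        assert np.abs(g50 - ghnc).max() < 1e-8

    def test_zero_exponent_gives_unit_g(self):
        t = np.zeros(10)
        for spec in (ClosureSpec("hnc"), ClosureSpec("pse", 1),
                     ClosureSpec("pse", 3)):
            assert np.allclose(spec.g_of_tstar(t), 1.0)

    def test_pse1_partial_sum_value(self):
        assert ClosureSpec("pse", 1).g_of_tstar(np.array([0.5]))[0] == 1.5

    def test_hnc_negative_branch(self):
        assert ClosureSpec("hnc").g_of_tstar(np.array([-0.9]))[0] == \
            pytest.approx(np.exp(-0.9))

    def test_continuity_across_zero(self):
        eps = 1e-9
        for spec in (ClosureSpec("pse", 1), ClosureSpec("pse", 3)):
            lo = spec.g_of_tstar(np.array([-eps]))[0]
            hi = spec.g_of_tstar(np.array([eps]))[0]
            assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_parse_names(self):
        assert ClosureSpec.parse("kh").order == 1
        assert ClosureSpec.parse("pse3").order == 3
        assert ClosureSpec.parse("hnc").kind == "hnc"
        with pytest.raises(ValueError):
            ClosureSpec.parse("percus")

    def test_apply_closure_returns_g(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 1, size=(1, 8, 8, 8))
        h = rng.normal(scale=0.1, size=(1, 8, 8, 8))
        c = rng.normal(scale=0.1, size=(1, 8, 8, 8))
        g = apply_closure(u, h, c, ClosureSpec("hnc"), beta=1.0)
        assert np.allclose(g, np.exp(-u + h - c))


class TestOzStep:
    def test_zero_c_gives_zero_h(self, lj_chi):
        grid = build_grid(16, 0.5)
        cg = chi_on_grid(lj_chi, grid)
        h = oz_step(np.zeros((1, 16, 16, 16)), cg)
        assert np.abs(h).max() == 0.0

    def test_identity_chi_returns_c(self, lj_solvent):
        grid = build_grid(16, 0.5)
        omega = build_intramolecular_matrix(
            lj_solvent, np.linspace(0.0, 50, 256)
        )
        cg = chi_on_grid(omega, grid)
        rng = np.random.default_rng(5)
        c = rng.normal(size=(1, 16, 16, 16))
        h = oz_step(c, cg)
        assert np.abs(h - c).max() < 1e-12

    def test_fft_matches_direct_convolution(self, water_chi):
        """FFT OZ step equals the O(N^2) direct cyclic convolution."""
        n = 16
        grid = build_grid(n, 0.5)
        cg = chi_on_grid(water_chi, grid)
        rng = np.random.default_rng(6)
        c = rng.normal(scale=0.1, size=(3, n, n, n))
        h_fft = oz_step(c, cg)
        # direct-space oracle: build the real-space kernel from chi and
        # convolve cyclically with explicit index arithmetic
        from numpy.fft import ifftn
        h_direct = np.zeros_like(c)
        for b in range(3):
            for a in range(3):
                kern = np.real(ifftn(cg[..., a, b]))
                acc = np.zeros((n, n, n))
                ker = kern
                ca = c[a]
                for dx in range(n):
                    for dy in range(n):
                        for dz in range(n):
                            acc += ca[dx, dy, dz] * np.roll(
                                np.roll(np.roll(ker, dx, 0), dy, 1), dz, 2
                            )
                h_direct[b] += acc
        assert np.abs(h_fft - h_direct).max() < 1e-10

    def test_linear_in_c(self, lj_chi):
        grid = build_grid(16, 0.5)
        cg = chi_on_grid(lj_chi, grid)
        rng = np.random.default_rng(7)
        c1 = rng.normal(size=(1, 16, 16, 16))
        c2 = rng.normal(size=(1, 16, 16, 16))
        h = oz_step(c1 + 2 * c2, cg)
        assert np.allclose(h, oz_step(c1, cg) + 2 * oz_step(c2, cg),
                           atol=1e-12)

    def test_chi_k_range_too_short_rejected(self, lj_solvent):
        omega = build_intramolecular_matrix(lj_solvent, np.linspace(0.0, 2, 32))
        grid = build_grid(16, 0.5)   # Nyquist ~ 6.3 A^-1 > 2
        with pytest.raises(ValueError, match="Nyquist|k-range"):
            chi_on_grid(omega, grid)


class TestSolve:
    def test_zero_potential_unit_g_within_two_iterations(self, water_chi):
        grid = build_grid(16, 0.5)
        f = solve(np.zeros((3, 16, 16, 16)), water_chi, grid, beta=1.0)
        assert f.converged
        assert len(f.residuals) <= 2
        assert np.abs(f.g - 1.0).max() == 0.0

    def test_high_temperature_limit_flattens_g(self, lj_chi, lj_solute,
                                               lj_solvent):
        grid = build_grid(32, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        f = solve(u, lj_chi, grid, beta=1e-8)
        assert f.converged
        assert np.abs(f.g - 1.0).max() < 1e-4

    def test_accelerators_agree(self, lj_chi, lj_solute, lj_solvent):
        grid = build_grid(32, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        kw = dict(beta=lj_solvent.beta, closure=ClosureSpec("hnc"), tol=1e-8)
        f_m = solve(u, lj_chi, grid, accel="mdiis", **kw)
        f_p = solve(u, lj_chi, grid, accel="picard", mix=0.5, **kw)
        assert f_m.converged and f_p.converged
        assert np.abs(f_m.g - f_p.g).max() < 1e-7

    def test_core_exclusion(self, lj_chi, lj_solute, lj_solvent):
        """g vanishes wherever the repulsive core exceeds 50 kT."""
        grid = build_grid(32, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        f = solve(u, lj_chi, grid, beta=lj_solvent.beta)
        core = lj_solvent.beta * u > 50.0
        assert f.g[core].max() < 1e-3

    def test_g_nonnegative_and_h_consistent(self, lj_chi, lj_solute,
                                            lj_solvent):
        grid = build_grid(32, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        f = solve(u, lj_chi, grid, beta=lj_solvent.beta)
        assert np.all(f.g >= 0)
        assert np.allclose(f.g, f.h + 1.0)

    def test_deterministic_rerun(self, lj_chi, lj_solute, lj_solvent):
        grid = build_grid(16, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        f1 = solve(u, lj_chi, grid, beta=lj_solvent.beta)
        f2 = solve(u, lj_chi, grid, beta=lj_solvent.beta)
        assert np.array_equal(f1.g, f2.g)


class TestExcessChemicalPotential:
    def test_zero_fields_give_zero(self, lj_chi):
        grid = build_grid(16, 0.5)
        f = solve(np.zeros((1, 16, 16, 16)), lj_chi, grid, beta=1.0)
        assert excess_chemical_potential(f) == pytest.approx(0.0, abs=1e-12)

    def test_kh_functional_equals_hnc_where_exponent_negative(self, lj_chi):
        """On fields with t* < 0 everywhere the PSE Heaviside correction
        vanishes and the KH functional reduces to the HNC form exactly."""
        from dataclasses import replace
        grid = build_grid(16, 0.5)
        x, y, z = grid.meshgrid()
        r2 = (x - 4) ** 2 + (y - 4) ** 2 + (z - 4) ** 2
        h = -0.3 * np.exp(-r2 / 6.0)[None]
        c = 0.9 * h
        u = np.exp(-r2 / 10.0)[None]          # beta*u >= 0 -> t* < 0
        base = solve(np.zeros_like(u), lj_chi, grid, beta=1.0)
        fields_kh = replace(base, h=h, g=h + 1, c_short=c, u_short=u,
                            closure=ClosureSpec("pse", 1))
        fields_hnc = replace(fields_kh, closure=ClosureSpec("hnc"))
        assert excess_chemical_potential(fields_kh) == pytest.approx(
            excess_chemical_potential(fields_hnc), abs=1e-14
        )

    def test_hnc_matches_thermodynamic_integration(self, lj_chi, lj_solute,
                                                   lj_solvent):
        """Closed-form HNC functional vs 10-point coupling-parameter TI on a
        bounded-core LJ solute (see methods note for the path choice)."""
        grid = build_grid(32, 0.5)
        beta = lj_solvent.beta
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid,
                                       cap_kcal=25.0 / beta)
        f = solve(u, lj_chi, grid, beta=beta, closure=ClosureSpec("hnc"))
        mu = excess_chemical_potential(f)
        nodes, wts = np.polynomial.legendre.leggauss(10)
        lam = 0.5 * (nodes + 1)
        w = 0.5 * wts
        ti = 0.0
        for l, ww in zip(lam, w):
            fl = solve(l * u, lj_chi, grid, beta=beta,
                       closure=ClosureSpec("hnc"))
            ti += ww * lj_solvent.number_density * np.sum(fl.g * u) \
                * grid.voxel_volume
        assert mu == pytest.approx(ti, rel=0.02)

    def test_unconverged_fields_warn(self, lj_chi, lj_solute, lj_solvent):
        grid = build_grid(16, 0.5)
        u, _ = solvent_site_potentials(lj_solute, lj_solvent, grid)
        with pytest.warns(RuntimeWarning):
            f = solve(u, lj_chi, grid, beta=lj_solvent.beta, max_iter=1)
        with pytest.warns(RuntimeWarning, match="unconverged"):
            excess_chemical_potential(f)


class TestRadialConsistency:
    def test_3d_matches_radial_solver_for_charged_lj_site(self, water_chi,
                                                          water_model):
        """Spherical solute: 3D axis profile vs the radial solver, contact
        peak within 1%."""
        from scipy.special import erfc

        from ecrism.constants import COULOMB_KCAL
        from ecrism.fields import SoluteConformer
        from ecrism.rism3d import solve_radial

        m = water_model
        beta = m.beta
        q_sol, sig, eps = 0.5, 3.5, 0.2
        sol = SoluteConformer(["X"], [[0, 0, 0]], [q_sol],
                              lj_sigma=[sig], lj_epsilon=[eps])
        n, sp = 64, 0.25
        grid = build_grid(n, sp)
        us, split = solvent_site_potentials(sol, m, grid, eta=1.0)
        f3 = solve(us, water_chi, grid, beta=beta,
                   closure=ClosureSpec("pse", 3), split=split,
                   site_charges=m.site_charges)
        assert f3.converged

        def u_of_r(r):
            out = np.empty((3, r.size))
            for g in range(3):
                sa = 0.5 * (sig + m.lj_sigma[g])
                ea = np.sqrt(eps * m.lj_epsilon[g])
                ulj = 4 * ea * ((sa / r) ** 12 - (sa / r) ** 6) if ea > 0 \
                    else 0 * r
                out[g] = np.clip(
                    ulj + COULOMB_KCAL * q_sol * m.site_charges[g]
                    * erfc(r / 1.0) / r,
                    -700 / beta, 700 / beta,
                )
            return out

        fr = solve_radial(u_of_r, water_chi, beta, m.site_charges,
                          solute_charge=q_sol, closure=ClosureSpec("pse", 3),
                          n_points=1024, dr=0.04, mix=0.2)
        assert fr.converged
        c = n // 2
        r_axis = sp * np.arange(n - c)
        g_axis = f3.g[0, c:, c, c]
        g_radial = np.interp(r_axis, fr.r, fr.g[0])
        peak3, peak1 = g_axis.max(), g_radial.max()
        assert abs(peak3 - peak1) / peak1 < 0.01
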