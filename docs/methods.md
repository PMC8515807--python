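# Methods

This note records the models the package implements, the numerical choices
behind them, and what the synthetic-data generators do and do not emulate.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Solvent model and susceptibility

The shipped solvent is a rigid 3-site SPC/E-like water (O–H 1.0 Å, H–O–H
109.47°, q_O = −0.8476 e, with small LJ parameters on the hydrogens so the
site-site equations have a repulsive core on every site), at the ambient
parameters used throughout: number density 0.0333295 Å⁻³, dielectric
constant 78.4, temperature 298.15 K. The temperature is the one genuinely
open choice (the workflow spans 295–300 K depending on the stage); ambient
standard conditions were chosen once and kept.

The susceptibility convention is dimensionless:

    chi_gg'(k) = omega_gg'(k) + rho * h_gg'(k),

with omega = j0(k L_gg') for the rigid geometry and rho the *molecular*
number density (each site carries it; site multiplicity is represented by
explicit sites). Every serialized table carries the tag
`omega+rho*h/dimensionless` and loaders refuse tables without it, because a
wrong normalization here silently corrupts every downstream solve.

### 1D solver

Plain XRISM (no DRISM dielectric correction — the workflow this package
supports imports its susceptibility precomputed, so dielectric consistency
is out of scope): matrix OZ equation H = (I − WCρ)⁻¹WCW on
Fourier–Bessel transforms (DST-I, default 1024 points, dr = 0.04 Å), damped
Picard iteration (mix 0.25–0.3) on the short-range direct correlation
function, max-norm residual, tolerance 1e-6. Long-range Coulomb tails are
Ng-separated with an erf splitting (η = 1 Å): the smooth part transforms
analytically, so only short-ranged functions are discretized. Charged
solvents are ramped in (λ = 0 → 1 in five stages, each reusing the previous
solution) because the bare Picard map can cross a singularity of (I − WCρ)
from a cold start; a least-squares fallback guards the remaining corner
cases. The Mayer-f function is the initial guess — `exp(−βu) − 1` is
bounded, unlike −βu.

## Solute fields

Solute–solvent site potentials are LJ 12-6 with Lorentz–Berthelot
combining plus point-charge electrostatics. The Coulomb part is
Ewald-split (erfc on the grid, analytic Gaussian long-range carried in
k-space with the k = 0 coefficient set to zero, i.e. a neutralizing
background). The combined short-range potential is capped symmetrically at
±700 k_BT **after** summation: capping the LJ core before adding a deeply
attractive nuclear Coulomb term would invert the sign of the core region.
The cap value only has to make exp(−βu) evaluable; converged distributions
never probe it because the closure suppresses the core to g ≈ 0.

## 3D solver

The iteration variable is the short-range direct correlation c_s; the
analytic long-range part −βq_γ V_long enters only in k-space, and the
closure exponent t* = −βu_short + h − c_s is exactly free of Coulomb tails
(they cancel algebraically between u, h and c). Closures: HNC
(g = exp t*), PSE-k (k-term Taylor partial sum for t* > 0), bridge function
zero. PSE-3 is the default production closure; PSE-1 is the
Kovalenko–Hirata closure and is bitwise identical to a hand-coded KH in the
suite. Acceleration is MDIIS (depth 10, damping 0.7) with a damped-Picard
reference path; the two agree within 10× the tolerance on the suite's
problems, which guards the accelerator's correctness. The residual is the
max-norm of the c_s update, tolerance 1e-6, fully deterministic (no RNG
anywhere in the solver).

The excess chemical potential is the Kovalenko-form closed functional

    mu = kT rho sum_g int [ h²/2 − c − hc/2 − Θ(t*) t*^(k+1)/(k+1)! ] dr,

reducing to the HNC form wherever t* ≤ 0. It is validated against 10-point
Gauss–Legendre thermodynamic integration over a linear coupling path on an
LJ solute whose core is capped at 25 k_BT: with the production 700 k_BT cap
the integrand develops an exp(−700λ) boundary layer at λ → 0 that no
10-point rule resolves (a 40-point rule reproduces the closed form to six
digits either way), so the bounded core is part of the oracle's
test-problem definition, not of the production configuration.

A radial (spherically symmetric solute) solver with the same algebra on
Fourier–Bessel transforms provides the independent 1D route for the
3D-vs-1D consistency check; at 64³ × 0.25 Å the contact-peak heights agree
to better than 1% when both are compared at the same radial sample points
(the residual difference is a finite-box effect that shrinks with box
size).

## Embedding charges

Discretization uses the bulk-inclusive density
q_i = ΔV Σ_γ q_γ ρ_γ g_γ(r_i) (for a neutral solvent each bulk voxel is
individually neutral); the excess-only (g − 1) variant is available behind
a flag, and the suite surfaces the difference between the two. Voxels
within 1 Å of a solute atom are dropped — the repulsive cores make g ≈ 0
there anyway.

Coarsening is a Barnes–Hut-style octree with monopole-only collapsed
charges, with two refinements. First, cells are split by charge sign
before barycentering, which (a) avoids the ill-defined centroid of a
near-neutral cell and (b) makes the collapsed pair dipole-exact, so the
leading far-field error is quadrupolar. Second, the opening criterion
(size / distance < θ) measures distance to the cell's nearest *corner*
rather than its center; the center rule admits large cells whose contents
reach much closer to the solute than the criterion suggests, and measured
ESP errors on realistic discretizations are ~4× larger with it. Error
scales like θ²·Σ|Q_cell|/d: near-field structured regions (large per-cell
monopoles at small d) are therefore protected by the distance criterion and
stay resolved, while the far-field bulk — where solvent neutrality makes
per-voxel charges nearly vanish — coalesces aggressively. That far-field
regime is where the method is designed to operate and where its accuracy
target (≤1e-3 kcal/mol/e at the solute at θ = 0.5) is verified.

ESP fitting is constrained linear least squares (KKT system with an exact
total-charge equality, 1e-12 relative Tikhonov on the normal matrix) on
regular-grid sample points in the shell between the Breneman–Wiberg radii
(H 1.45, C 1.50, N 1.70, O 1.70 Å) and a 2.8 Å outer cutoff at 0.3 Å
spacing; no dipole restraint. The fit recovers generator charges placed at
atom centers to 1e-8 e and is translation-invariant to 1e-12.

## Conductor-like continuum model

Cavity: Fibonacci point sets on per-atom spheres of radius
(atomic radius + probe radius, probe default 1.3 Å), exposed-point
filtering against all other spheres, optional greedy thinning to a 0.1 Å
minimum point spacing; per-point areas are the parent sphere area divided
by its generated point count. This replaces interlocking-sphere (GEPOL)
tessellation: the working equations are tessellation-agnostic and the Born
ion pins the solver (≤0.1% at 974 points, error strictly decreasing with
resolution). The interaction matrix uses the standard flat-tessera
diagonal 1.0694·√(4π/S_i); the dielectric scaling defaults to
f = (ε−1)/(ε+0.5) with the (ε−1)/ε variant selectable; ε defaults to 80.4.
The probe-radius scan (1.1–1.4 Å) is kept as a robustness harness: the
observable must vary smoothly, no printed values are asserted.

## Embedded-cluster cycle

One cycle: solve 3D equations → discretize + coarsen solvent charges →
query the solute model → rebuild potentials. Convergence: |Δμ_ex| < 0.01
kcal/mol between consecutive cycles. The solute model consumes coarsened
charges (a flag switches to raw-grid for oracle comparisons); the
coarsening tree is rebuilt every cycle; charge-update damping exists but is
off by default — the shipped surrogates converge undamped in ≤5 cycles.

The `SoluteElectronicModel` contract is classical: embedding charges in,
(charges, induced dipoles, energy) out, deterministic. A rigid-charge
model makes the cycle a fixed point from cycle 2 by construction — the
suite asserts exactly that. The polarizable surrogate induces point
dipoles μ_a = α_a E_a (represented as ±q pairs split by 0.2 Å for
potential construction). Its self-consistent dipole is compared with the
first-order estimate α·E(cycle-1 field): the comparison is made at
α = 0.2 Å³ on heavy atoms, inside the linear-response regime (doubling α
doubles the dipole to within a few percent); at α = 0.5 Å³ the
self-consistent feedback already exceeds 10% of the first-order value,
which the linear-response property test covers with its wider band.
An in-cycle model may differ from the final-property model (both are
caller-supplied), representing workflows where a cheap electronic
structure drives the iterations and an expensive one evaluates the
property once at convergence.

## Snapshot protocol

Extraction replicates the periodic cubic frame 3×3×3 about the nitroxide
oxygen (the pivot) and keeps every water whose oxygen lies within
R = d_nearest-image-pivot − r_shell (r_shell = 3.4 Å, the first RDF
minimum). The triangle inequality then guarantees no kept water penetrates
the first shell of any solute image — the clash-free property is asserted,
not assumed. Waters enter whole, decided by their O site; membership by
the nitrogen site is available behind a flag. Shells: first ≤ 3.4 Å,
second 3.4–5.5 Å, outer beyond; QM/MM partitions are nested
(none ⊂ first ⊂ second ⊂ full) and the MM remainder becomes TIP3P point
charges (O −0.834, H +0.417 e) at snapshot positions, written as a
two-file deck (QM xyz + MM x y z q) for external QC codes.

RDFs use minimum-image distances with the textbook shell-volume
normalization; errors are standard errors over frames. The computation is
implemented directly on the package's frame container rather than through
a trajectory-analysis framework, because the site selections are defined
on this container's molecule labels; the ideal-gas oracle (g ≡ 1 within
3σ) and the fixed-pair and error-scaling checks validate it.

## Hyperfine layer

Fermi contact: A_iso = (2μ₀/3) g_e μ_B g_N μ_N ρ(R_N)/(2S)/h with ρ in
a₀⁻³. Among the equivalent typographic conventions for this prefactor,
the implementation is pinned numerically: 800.237407 MHz per (g_N · a₀⁻³)
at S = 1/2, frozen in the suite from an independent CODATA recomputation,
and cross-checked against the hydrogen-atom 1s value (≈1420 MHz). Nuclear
g-factors ship for ¹H, ¹⁴N, ¹⁷O from a standard isotope compilation and
are overridable per nucleus.

Ensemble statistics follow the reporting conventions of thermal-average
studies: histograms normalized so the maximum bin is exactly 1
(Freedman–Diaconis bin count by default, caller-overridable), running
means whose endpoint is bitwise the full mean, and block-doubling standard
errors with a 5%-plateau detection (largest-block value if no plateau).
Solvent shifts are differences of ensemble means with errors combined in
quadrature, and are only defined between ensembles of the same nucleus.

Spectra: fast-motion isotropic multiplets, 2I+1 equal Lorentzian
first-derivative lines at B₀ − a·m_I, with a = A_iso·h/(gμ_B) and Γ =
(√3/2)·ΔB_pp. Rotational-correlation (m_I-dependent) line broadening is
deliberately not modeled; all lines share one peak-to-peak width.

## Synthetic data

The fixture generator emulates the *geometry* of the study system — one
rigid 6-atom nitroxide fragment (a reduced stand-in for the full 31-atom
probe; geometry-level tests do not need the full molecule) centered in a
cubic periodic box, 128 rigid 3-site waters at ambient density (box 15.67
Å), frames 200 fs apart with small rigid-body jitter per molecule
(default 0.06 Å). Waters are placed by random sequential insertion with a
2.4 Å minimum O–O / O–solute distance (minimum image). It does **not**
emulate solvation physics: no hydrogen-bond network, no realistic RDFs, no
dynamical correlation between frames. Consequently, passing tests built on
these fixtures demonstrate the correctness of the geometric protocol,
bookkeeping and statistics — not the realism of any solvation structure,
which in this package comes only from the integral-equation solvers.
Ensembles are i.i.d. normal per treatment label; spin-density cubes are
analytic (constant / Gaussian / linear). Every generator is bitwise
reproducible under a fixed seed.

## Problem sizes and degenerate inputs

Default production grids follow the 120³ × 0.5 Å convention; the suite and
the acceptance script run 16³–64³ grids, 1024-point radial grids, 974-point
Born surfaces, 10⁴-charge coarsening sets and 1000-sample ensembles —
sizes at which every oracle comparison is sharp. Degenerate inputs are
contracts, not accidents: empty ensembles, unconverged fields, coincident
solvent sites, odd grid sizes, missing susceptibility convention tags,
boxes smaller than the shell radius, and point-charge backends without an
MM set all raise with specific messages, and the suite asserts each.

## Known limitations

- No solvent mixtures, flexible or polarizable solvent models; no DRISM.
- No triclinic boxes; extraction assumes cubic periodicity.
- Monopole-only treecode (sign-split): near-field structured charge sets
  require small opening parameters for tight ESP tolerances; the cycle
  therefore keeps near cells resolved by construction.
- The continuum cavity is a point-set approximation; energies carry the
  ~quadrature error the Born scan quantifies (≲0.2% at default
  resolution).
- No electronic structure: spin densities and solute charges are inputs;
  the surrogate models are contracts for coupling, not physical electron
  distributions.
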