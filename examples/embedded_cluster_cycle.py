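"""Self-consistent solute-solvent polarization (embedded-cluster cycle).

Alternates a surrogate electronic model with the 3D solvation solver:
the solvent distribution is discretized into background point charges,
coarsened with a treecode, and handed to the solute model, which responds
with induced dipoles; the cycle repeats until the excess chemical potential
is stable to 0.01 kcal/mol.
"""

import numpy as np

from ecrism.ecscf import PolarizableSurrogate, RigidChargeModel, run_ec_cycle
from ecrism.fields import build_grid
from ecrism.fixtures import nitroxide_fragment
from ecrism.solvent import (assemble_susceptibility,
                            build_intramolecular_matrix, solve_rism1d,
                            spce_water)

water = spce_water()
w1d = solve_rism1d(water, "kh", n_points=1024, dr=0.04, mix=0.3,
                   max_iter=8000)
chi = assemble_susceptibility(build_intramolecular_matrix(water, w1d.k),
                              w1d.h_k, water)

frag = nitroxide_fragment()
grid = build_grid(32, 0.5, center=frag.coords.mean(axis=0))

print("rigid (non-polarizable) solute:")
rigid = run_ec_cycle(RigidChargeModel(frag), frag, chi, water, grid,
                     tol_mu=0.01)
for i, mu in enumerate(rigid.trace.mu_history):
    print(f"  cycle {i + 1}: mu_ex = {mu:.4f} kcal/mol")
print(f"  -> fixed point at cycle {rigid.trace.n_cycles} (by construction)")

print("\npolarizable surrogate (alpha = 0.3 A^3 on heavy atoms):")
heavy = np.array([e != "H" for e in frag.elements])
polar = run_ec_cycle(PolarizableSurrogate(frag, np.where(heavy, 0.3, 0.0)),
                     frag, chi, water, grid, tol_mu=0.01, max_cycles=12)
for i, mu in enumerate(polar.trace.mu_history):
    print(f"  cycle {i + 1}: mu_ex = {mu:.4f} kcal/mol")
mu_tot = np.linalg.norm(polar.state.induced_dipoles, axis=1).sum()
print(f"  total induced dipole magnitude: {mu_tot:.4f} e*A")
print("\nThe drop in mu_ex between the rigid and polarizable runs is the")
print("mutual-polarization energy the self-consistent cycle captures.")
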