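"""Hyperfine couplings: from spin density to an X-band EPR spectrum.

Converts spin density at a nucleus to the isotropic coupling via the
Fermi-contact expression, averages a synthetic per-snapshot ensemble the
way thermal ensembles are reported (max-bin-normalized histograms, running
means, block errors), forms a solvent shift, and synthesizes the
fast-motion nitrogen triplet at the experimental simulation parameters.
"""

import numpy as np

from ecrism.fixtures import make_hfcc_samples, make_spin_density_cube
from ecrism.hfcc import (NucleusSpec, SpectrumParams, ensemble_stats,
                         fermi_contact_aiso, sample_cube_at_point,
                         simulate_isotropic_spectrum, solvent_shift)

# Fermi contact: spin density (a.u.) -> A_iso (MHz)
n14 = NucleusSpec("14N")
cube = make_spin_density_cube("gaussian", n=24, spacing=0.25, amplitude=0.05,
                              width=0.6)
center = cube.origin + cube.spacing * (np.array(cube.shape) - 1) / 2
rho = sample_cube_at_point(cube, center)
print(f"spin density at N: {rho:.4f} a0^-3 "
      f"-> A_iso = {fermi_contact_aiso(rho, n14):.2f} MHz")

# thermal ensemble statistics (solvated vs vertically desolvated)
ens = make_hfcc_samples({"solvated": 36.7, "desolvated": 31.2},
                        sigmas=4.0, n=1000, seed=0)
s = ensemble_stats(ens["solvated"])
print(f"\nsolvated ensemble: mean {s.mean:.2f} MHz, "
      f"block stderr {s.stderr_block:.2f} MHz, {s.n_samples} snapshots")
print(f"histogram max bin (normalized): {s.histogram.max():.1f}")
shift, err = solvent_shift(ens["solvated"], ens["desolvated"])
print(f"solvent shift: {shift:+.2f} +/- {err:.2f} MHz")

# fast-motion isotropic spectrum: 14N triplet at X band
p = SpectrumParams(frequency_ghz=9.2, aiso_mhz=44.87, linewidth_mt=0.12,
                   nuclear_spin=1.0)
B, y, centers = simulate_isotropic_spectrum(p)
print(f"\nX-band spectrum: {len(centers)} lines at "
      + ", ".join(f"{c:.2f}" for c in centers) + " mT")
print(f"line spacing {abs(np.diff(centers)).mean():.3f} mT "
      f"(field equivalent of {p.aiso_mhz} MHz)")
print("\nThe three equally spaced derivative lines are the signature of a")
print("rapidly tumbling nitroxide; their splitting in field units encodes")
print("the isotropic hyperfine coupling to the 14N nucleus.")
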