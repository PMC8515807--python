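"""Small readers/writers for solute geometries and parameter tables."""

from __future__ import annotations

import numpy as np

from .fields import SoluteConformer

#: Bondi-style van der Waals radii (A) for cavity construction
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        raise ValueError(f"no van der Waals radius tabulated for {element!r}")


def read_solute_xyz(path, params_path=None) -> SoluteConformer:
    """Solute from an XYZ file, optionally with extra columns.

    Per-atom lines may carry ``el x y z [q [sigma eps]]``; alternatively a
    separate whitespace table (params_path) with columns
    ``element charge sigma epsilon`` keyed by element supplies parameters.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    nat = int(lines[0].split()[0])
    elements, coords, charges, sig, eps = [], [], [], [], []
    have_q = have_lj = True
    for ln in lines[2 : 2 + nat]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
        if len(parts) >= 5:
            charges.append(float(parts[4]))
        else:
            have_q = False
        if len(parts) >= 7:
            sig.append(float(parts[5]))
            eps.append(float(parts[6]))
        else:
            have_lj = False
    table = {}
    if params_path is not None:
        data = np.genfromtxt(params_path, dtype=None, encoding="utf-8",
                             names=("element", "charge", "sigma", "epsilon"))
        data = np.atleast_1d(data)
        for row in data:
            table[str(row["element"])] = (
                float(row["charge"]), float(row["sigma"]), float(row["epsilon"])
            )
    if not have_q:
        charges = [table[e][0] if e in table else 0.0 for e in elements]
    if not have_lj:
        sig = [table[e][1] if e in table else None for e in elements]
        eps = [table[e][2] if e in table else None for e in elements]
        if any(s is None for s in sig):
            sig = eps = None
    return SoluteConformer(
        elements=elements,
        coords=np.array(coords),
        charges=np.array(charges, dtype=float),
        lj_sigma=None if sig is None else np.array(sig, dtype=float),
        lj_epsilon=None if eps is None else np.array(eps, dtype=float),
    )


def write_solute_xyz(path, solute: SoluteConformer, with_params=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"{solute.n_atoms}\n")
        fh.write("ecrism solute: el x y z q sigma eps\n")
        for i in range(solute.n_atoms):
            x, y, z = solute.coords[i]
            line = f"{solute.elements[i]} {x:.8f} {y:.8f} {z:.8f}"
            if with_params and solute.lj_sigma is not None:
                line += (f" {solute.charges[i]:.6f}"
                         f" {solute.lj_sigma[i]:.4f} {solute.lj_epsilon[i]:.5f}")
            elif with_params:
                line += f" {solute.charges[i]:.6f}"
            fh.write(line + "\n")
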