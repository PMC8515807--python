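"""Embedded-cluster self-consistency: solute model <-> 3D solvation solver.

One cycle: solve the 3D integral equations in the current solute field,
discretize and coarsen the solvent charge density into background charges,
hand those to a pluggable solute electronic model which returns polarized
atomic charges, rebuild the solute-solvent potentials, repeat.  Convergence
is declared when the excess chemical potential changes by less than tol_mu
(default 0.01 kcal/mol) between consecutive cycles.

No quantum-chemistry backend is bundled: the SoluteElectronicModel contract
is deliberately classical (charges in, charges + ESP + energy out) so that
a rigid-charge model, the shipped isotropic-polarizability surrogate, or an
adapter around an external QC code can all drive the same cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np

from .constants import COULOMB_KCAL
from .embedding import (
    EmbeddingChargeSet,
    coarsen_charges,
    discretize_solvent_charge,
    embedding_energy_operator,
)
from .fields import Grid3D, SoluteConformer, solvent_site_potentials
from .rism3d import ClosureSpec, CorrelationFields, excess_chemical_potential, solve
from .solvent import SolventModel, SusceptibilityTable


@dataclass
class SoluteState:
    """What a solute electronic model reports back for one polarization."""

    charges: np.ndarray            # per-atom effective charges, e
    energy: float = 0.0            # internal (distortion) energy, kcal/mol
    induced_dipoles: Optional[np.ndarray] = None   # (n, 3) e*A


class SoluteElectronicModel(Protocol):
    """Contract: deterministic mapping from an embedding charge set (or
    None) to a SoluteState; with no external charges it must return the
    reference gas-phase charges."""

    def polarize(self, embedding: Optional[EmbeddingChargeSet]) -> SoluteState:
        ...


@dataclass
class RigidChargeModel:
    """Non-polarizable solute: returns the reference charges regardless of
    the embedding.  The EC cycle with this model is a fixed point from
    cycle 2 onward by construction."""

    solute: SoluteConformer

    def polarize(self, embedding=None) -> SoluteState:
        return SoluteState(charges=self.solute.charges.copy())


@dataclass
class PolarizableSurrogate:
    """Isotropic atomic-polarizability surrogate for the electronic model.

    Each atom a carries alpha_a (A^3).  The field E_a of the embedding
    charges induces a point dipole mu_a = alpha_a * E_a / k_e (units e*A),
    represented for potential-building purposes as a +/- charge pair split
    by ``dipole_split`` along the local field.  alpha = 0 reduces to the
    rigid model exactly.
    """

    solute: SoluteConformer
    polarizabilities: np.ndarray
    dipole_split: float = 0.2      # A

    def __post_init__(self):
        self.polarizabilities = np.atleast_1d(
            np.asarray(self.polarizabilities, dtype=float)
        )
        if np.any(self.polarizabilities < 0):
            raise ValueError("polarizabilities must be non-negative")
        if self.polarizabilities.size == 1:
            self.polarizabilities = np.repeat(
                self.polarizabilities, self.solute.n_atoms
            )

    def polarize(self, embedding=None) -> SoluteState:
        base = self.solute.charges.copy()
        if embedding is None or embedding.count == 0 or np.all(
            self.polarizabilities == 0
        ):
            return SoluteState(charges=base,
                               induced_dipoles=np.zeros((self.solute.n_atoms, 3)))
        _, E = embedding_energy_operator(embedding, self.solute)
        mu = self.polarizabilities[:, None] * E / COULOMB_KCAL   # e*A
        return SoluteState(charges=base, induced_dipoles=mu,
                           energy=0.0)

    def expanded_sites(self, state: SoluteState):
        """Atomic charges plus +/- pairs representing induced dipoles.

        Returns (positions, charges) for potential construction."""
        pos = [self.solute.coords]
        chg = [state.charges]
        if state.induced_dipoles is not None:
            for a in range(self.solute.n_atoms):
                mu = state.induced_dipoles[a]
                m = np.linalg.norm(mu)
                if m < 1e-14:
                    continue
                u = mu / m
                q = m / self.dipole_split
                pos.append(self.solute.coords[a] + 0.5 * self.dipole_split * u)
                pos.append(self.solute.coords[a] - 0.5 * self.dipole_split * u)
                chg.append(np.array([q]))
                chg.append(np.array([-q]))
        return np.concatenate([np.atleast_2d(p) for p in pos]), np.concatenate(
            [np.atleast_1d(c) for c in chg]
        )


@dataclass
class ScfTrace:
    mu_history: list = field(default_factory=list)     # kcal/mol per cycle
    charge_history: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.mu_history)


@dataclass
class EcScfResult:
    trace: ScfTrace
    fields: CorrelationFields
    embedding: EmbeddingChargeSet
    state: SoluteState


def run_ec_cycle(
    model,
    solute: SoluteConformer,
    chi: SusceptibilityTable,
    solvent: SolventModel,
    grid: Grid3D,
    closure: ClosureSpec = None,
    tol_mu: float = 0.01,
    max_cycles: int = 20,
    theta: float = 0.5,
    use_raw_charges: bool = False,
    charge_mixing: float = 0.0,
    rism_kwargs: dict = None,
) -> EcScfResult:
    """Alternate (3D solve -> embedding charges -> solute model -> new u)
    until |d mu_ex| < tol_mu between consecutive cycles.

    use_raw_charges skips treecode coarsening (oracle comparisons);
    charge_mixing in [0,1) blends old and new solute charges (0 = undamped).
    The coarsening tree is rebuilt every cycle.
    """
    if closure is None:
        closure = ClosureSpec("pse", 3)
    rism_kwargs = dict(rism_kwargs or {})
    trace = ScfTrace()
    state = model.polarize(None)
    current = solute.with_charges(state.charges)
    fields = None
    emb = EmbeddingChargeSet(np.zeros((0, 3)), np.zeros(0))
    for cycle in range(max_cycles):
        # dipole-carrying surrogates expose expanded charge sites
        if hasattr(model, "expanded_sites"):
            pos, chg = model.expanded_sites(state)
            eff = _with_extra_sites(current, pos, chg)
        else:
            eff = current
        u_short, split = solvent_site_potentials(eff, solvent, grid)
        fields = solve(
            u_short, chi, grid, beta=solvent.beta, closure=closure,
            split=split, site_charges=solvent.site_charges, **rism_kwargs,
        )
        mu = excess_chemical_potential(fields)
        trace.mu_history.append(mu)
        trace.charge_history.append(state.charges.copy())
        if len(trace.mu_history) >= 2 and abs(
            trace.mu_history[-1] - trace.mu_history[-2]
        ) < tol_mu:
            trace.converged = True
            break
        raw = discretize_solvent_charge(
            fields, solvent, grid, solute_coords=solute.coords
        )
        emb = raw if use_raw_charges else coarsen_charges(
            raw, solute.coords, theta=theta
        )
        new_state = model.polarize(emb)
        if charge_mixing > 0:
            new_state.charges = (
                charge_mixing * state.charges
                + (1 - charge_mixing) * new_state.charges
            )
        state = new_state
        current = solute.with_charges(state.charges)
    return EcScfResult(trace=trace, fields=fields, embedding=emb, state=state)


def _with_extra_sites(solute: SoluteConformer, positions, charges):
    """Solute plus massless charge-only sites (induced-dipole pairs): LJ
    parameters of the extra sites are zero."""
    n_extra = len(charges) - solute.n_atoms
    if n_extra <= 0:
        return solute.with_charges(charges)
    return SoluteConformer(
        elements=list(solute.elements) + ["X"] * n_extra,
        coords=positions,
        charges=charges,
        lj_sigma=np.concatenate([solute.lj_sigma, np.zeros(n_extra)]),
        lj_epsilon=np.concatenate([solute.lj_epsilon, np.zeros(n_extra)]),
        roles=dict(solute.roles),
    )


# ---------------------------------------------------------------------------
# treatment taxonomy

VALID_BACKENDS = ("none", "ecrism", "cosmo", "point-charges")
VALID_LEVELS = ("desolvated", "first-shell", "second-shell")

_LABELS = {
    ("desolvated", "none"): "vertically desolvated solute",
    ("desolvated", "ecrism"): "vertically desolvated solute/EC-RISM",
    ("desolvated", "cosmo"): "vertically desolvated solute/CPCM",
    ("first-shell", "none"): "solute + first solvation shell",
    ("first-shell", "ecrism"): "solute + first solvation shell/EC-RISM",
    ("first-shell", "cosmo"): "solute + first solvation shell/CPCM",
    ("first-shell", "point-charges"): "solute + first shell/MM point charges",
    ("second-shell", "none"): "solute + second solvation shell",
    ("second-shell", "ecrism"): "solute up to second solvation shell/EC-RISM",
    ("second-shell", "cosmo"): "solute up to second solvation shell/CPCM",
    ("second-shell", "point-charges"):
        "solute up to second shell/MM point charges",
}


@dataclass
class TreatmentVariant:
    """A fully specified run configuration in the explicit/implicit
    solvation taxonomy: which waters stay explicit, and which backend
    embeds the rest."""

    conformer: SoluteConformer
    waters_explicit_level: str
    solvation_backend: str
    label: str


def treatment_variants(
    conformer: SoluteConformer,
    waters_explicit_level: str,
    solvation_backend: str,
    mm_sites: Optional[EmbeddingChargeSet] = None,
) -> TreatmentVariant:
    """Validate and label a solvation-treatment combination."""
    if waters_explicit_level not in VALID_LEVELS:
        raise ValueError(f"unknown explicit-water level "
                         f"{waters_explicit_level!r}; expected {VALID_LEVELS}")
    if solvation_backend not in VALID_BACKENDS:
        raise ValueError(f"unknown backend {solvation_backend!r}; "
                         f"expected {VALID_BACKENDS}")
    if solvation_backend == "point-charges" and (
        mm_sites is None or mm_sites.count == 0
    ):
        raise ValueError("point-charges backend requires a non-empty MM set")
    key = (waters_explicit_level, solvation_backend)
    if key not in _LABELS:
        raise ValueError(f"inconsistent treatment combination {key}")
    label = _LABELS[key]
    return TreatmentVariant(
        conformer=conformer,
        waters_explicit_level=waters_explicit_level,
        solvation_backend=solvation_backend,
        label=label,
    )
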