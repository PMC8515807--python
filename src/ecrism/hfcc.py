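"""Isotropic hyperfine couplings: Fermi contact, ensembles, spectra.

The isotropic hyperfine coupling constant of nucleus N is the Fermi-contact
term, proportional to the spin density at the nucleus:

    A_iso = (2 mu0 / 3) g_e mu_B g_N mu_N rho(R_N) / (2S) / h

with rho in a0^-3 as printed by quantum-chemistry codes; the numeric
prefactor is 800.237 MHz per (g_N * a0^-3) at S = 1/2 (see constants).

Per-snapshot A_iso samples over a thermal ensemble are summarized as
max-bin-normalized histograms, running means, and block-averaged standard
errors; differences of ensemble means between solvation treatments give
solvent shifts with errors combined in quadrature.  Fast-motion isotropic
EPR spectra are synthesized as 2I+1 equal Lorentzian derivative lines split
by the field equivalent of A_iso.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .constants import fermi_contact_prefactor, field_per_mhz, resonance_field_mt
from .cube import CubeVolume

#: nuclear g-factors and spins of the EPR-relevant isotopes (standard
#: isotope compilation values; overridable per NucleusSpec)
ISOTOPES = {
    "1H": {"g_n": 5.58569468, "spin": 0.5},
    "14N": {"g_n": 0.40376100, "spin": 1.0},
    "17O": {"g_n": -0.75751600, "spin": 2.5},
}


@dataclass
class NucleusSpec:
    isotope: str
    g_n: Optional[float] = None
    spin: Optional[float] = None
    position: Optional[np.ndarray] = None      # A

    def __post_init__(self):
        ref = ISOTOPES.get(self.isotope)
        if self.g_n is None:
            if ref is None:
                raise ValueError(f"unknown isotope {self.isotope!r}; supply g_n")
            self.g_n = ref["g_n"]
        if self.spin is None:
            if ref is None:
                raise ValueError(f"unknown isotope {self.isotope!r}; supply spin")
            self.spin = ref["spin"]
        if self.g_n == 0:
            raise ValueError("nuclear g-factor must be nonzero")
        if self.spin <= 0:
            raise ValueError("EPR-active nuclei need spin > 0")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)


def fermi_contact_aiso(rho_at_nucleus: float, nucleus: NucleusSpec,
                       electron_spin: float = 0.5) -> float:
    """A_iso in MHz from the spin density at the nucleus (a0^-3).

    Strictly linear in rho and g_N; sign follows sign(g_N * rho).  The
    1/(2S) factor normalizes the spin magnetization (S = 1/2 default)."""
    if electron_spin <= 0:
        raise ValueError("electron spin S must be positive")
    return (
        fermi_contact_prefactor() * nucleus.g_n * rho_at_nucleus
        / (2 * electron_spin)
    )


def sample_cube_at_point(cube: CubeVolume, point) -> float:
    """Spin density at an arbitrary point by trilinear interpolation."""
    return cube.sample(point)


# ---------------------------------------------------------------------------

ENSEMBLE_COLUMNS = ["snapshot_id", "time_fs", "nucleus", "treatment",
                    "method", "aiso_mhz"]


@dataclass
class HfccEnsemble:
    """Per-snapshot A_iso samples with treatment / method labels.

    Backed by a pandas DataFrame with the canonical TSV columns."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(ENSEMBLE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ensemble table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty ensemble")

    @classmethod
    def from_samples(cls, aiso_mhz, nucleus: str, treatment: str,
                     method: str = "surrogate", times_fs=None) -> "HfccEnsemble":
        a = np.atleast_1d(np.asarray(aiso_mhz, dtype=float))
        n = len(a)
        t = np.arange(n) * 200.0 if times_fs is None else np.asarray(times_fs)
        return cls(pd.DataFrame({
            "snapshot_id": np.arange(n),
            "time_fs": t,
            "nucleus": nucleus,
            "treatment": treatment,
            "method": method,
            "aiso_mhz": a,
        }))

    @property
    def values(self) -> np.ndarray:
        return self.table["aiso_mhz"].to_numpy()

    @property
    def nucleus(self) -> str:
        nuc = self.table["nucleus"].unique()
        if len(nuc) != 1:
            raise ValueError("ensemble mixes nuclei")
        return str(nuc[0])

    def subset(self, treatment: str) -> "HfccEnsemble":
        sub = self.table[self.table["treatment"] == treatment]
        return HfccEnsemble(sub.reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HfccEnsemble":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class EnsembleStats:
    mean: float
    std: float
    stderr_block: float
    bin_centers: np.ndarray
    histogram: np.ndarray          # max bin == 1
    running_mean: np.ndarray
    n_samples: int


def block_standard_error(x: np.ndarray, min_blocks: int = 8) -> float:
    """Standard error by block doubling with plateau detection.

    Block sizes 1, 2, 4, ... (while at least ``min_blocks`` blocks remain);
    the estimate is the first plateau (relative change < 5% between
    consecutive doublings), else the largest-block value."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an error estimate")
    estimates = []
    size = 1
    while n // size >= min_blocks:
        nb = n // size
        blocks = x[: nb * size].reshape(nb, size).mean(axis=1)
        estimates.append(blocks.std(ddof=1) / np.sqrt(nb))
        size *= 2
    if not estimates:
        return float(x.std(ddof=1) / np.sqrt(n))
    for i in range(1, len(estimates)):
        if estimates[i - 1] > 0 and abs(
            estimates[i] - estimates[i - 1]
        ) / estimates[i - 1] < 0.05:
            return float(estimates[i])
    return float(estimates[-1])


def freedman_diaconis_bins(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0 or len(x) < 4:
        return max(1, min(20, len(np.unique(x))))
    width = 2 * iqr / np.cbrt(len(x))
    span = x.max() - x.min()
    return max(1, int(np.ceil(span / width)))


def ensemble_stats(ens: HfccEnsemble, n_bins: Optional[int] = None) -> EnsembleStats:
    """Mean, max-bin-normalized histogram, running mean, block error.

    The histogram's maximum bin is exactly 1; the running mean's last point
    equals the full mean bitwise (same summation order)."""
    x = ens.values
    if n_bins is None:
        n_bins = freedman_diaconis_bins(x)
    if x.max() > x.min():
        hist, edges = np.histogram(x, bins=n_bins)
    else:
        hist = np.array([len(x)])
        edges = np.array([x[0] - 0.5, x[0] + 0.5])
    hist = hist / hist.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    running = np.cumsum(x) / np.arange(1, len(x) + 1)
    stderr = block_standard_error(x) if len(x) >= 2 else 0.0
    return EnsembleStats(
        mean=float(running[-1]),
        std=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        stderr_block=stderr,
        bin_centers=centers,
        histogram=hist,
        running_mean=running,
        n_samples=len(x),
    )


def solvent_shift(ens_a: HfccEnsemble, ens_b: HfccEnsemble):
    """mean(a) - mean(b) in MHz with errors combined in quadrature.

    The two ensembles must refer to the same nucleus (shifts across nuclei
    are meaningless)."""
    if ens_a.nucleus != ens_b.nucleus:
        raise ValueError("solvent shift requires matching nuclei")
    sa, sb = ensemble_stats(ens_a), ensemble_stats(ens_b)
    shift = sa.mean - sb.mean
    err = float(np.hypot(sa.stderr_block, sb.stderr_block))
    return shift, err


# ---------------------------------------------------------------------------

@dataclass
class SpectrumParams:
    """Fast-motion isotropic spectrum inputs (X-band defaults)."""

    frequency_ghz: float = 9.2
    g_value: float = 2.0059
    aiso_mhz: float = 44.87
    linewidth_mt: float = 0.12     # peak-to-peak of the derivative line
    nuclear_spin: float = 1.0
    field_range_mt: Optional[tuple] = None
    n_points: int = 4096

    def __post_init__(self):
        if self.frequency_ghz <= 0:
            raise ValueError("microwave frequency must be positive")
        if self.linewidth_mt <= 0:
            raise ValueError("linewidth must be positive")
        if (2 * self.nuclear_spin) % 1 != 0:
            raise ValueError("nuclear spin must be a multiple of 1/2")


def simulate_isotropic_spectrum(params: SpectrumParams):
    """First-derivative absorption spectrum vs field (mT).

    2I+1 lines centered at B0 - a_field*m_I with a_field the field
    equivalent of A_iso (h/(g mu_B) conversion); equal Lorentzian
    derivative lineshapes with the given peak-to-peak width.  Returns
    (field axis mT, derivative amplitude, line centers mT)."""
    import warnings

    b0 = resonance_field_mt(params.frequency_ghz, params.g_value)
    a_field = params.aiso_mhz * field_per_mhz(params.g_value)
    I = params.nuclear_spin
    m_values = np.arange(-I, I + 1e-9, 1.0)
    centers = b0 - a_field * m_values
    if params.field_range_mt is None:
        span = max(abs(a_field) * (I + 1), 10 * params.linewidth_mt) + 2.0
        lo, hi = b0 - span, b0 + span
    else:
        lo, hi = params.field_range_mt
        if centers.min() < lo or centers.max() > hi:
            warnings.warn("field range does not cover all hyperfine lines",
                          RuntimeWarning)
    B = np.linspace(lo, hi, params.n_points)
    gamma = np.sqrt(3.0) / 2.0 * params.linewidth_mt   # Lorentzian HWHM
    y = np.zeros_like(B)
    for c in centers:
        x = B - c
        y += -2 * gamma * x / (np.pi * (gamma**2 + x**2) ** 2)
    return B, y, centers
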