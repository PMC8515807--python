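"""Deterministic synthetic data generators.

Everything downstream — extraction, shells, QM/MM decks, RDFs, ensembles,
cubes — is testable without any external data through these generators.
They emulate the study system's geometry (a rigid nitroxide solute in a
cubic periodic box of rigid 3-site waters at ambient density, frames with
thermal jitter), not its physics: waters are placed by random sequential
insertion with a hard minimum distance, and frame-to-frame motion is
uncorrelated harmonic jitter, so the generated structure carries no real
solvation correlations.  A fixed seed reproduces output bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import CubeVolume
from .fields import SoluteConformer
from .hfcc import HfccEnsemble
from .snapshots import TrajectoryFrame

#: defaults mirror the study system: 128 waters in a ~15.67 A cubic box
DEFAULT_BOX_LENGTH = 15.67
DEFAULT_N_WATERS = 128
DEFAULT_FRAME_SPACING_FS = 200.0


@dataclass
class FixtureSpec:
    seed: int = 0
    box_length: float = DEFAULT_BOX_LENGTH
    n_waters: int = DEFAULT_N_WATERS
    jitter: float = 0.06           # A, thermal displacement scale
    n_frames: int = 5
    frame_spacing_fs: float = DEFAULT_FRAME_SPACING_FS
    min_distance: float = 2.4      # A, O-O and O-solute insertion cutoff
    solute_template: str = "nitroxide6"


def nitroxide_fragment() -> SoluteConformer:
    """Reduced rigid 6-atom nitroxide fragment: >N-O* with two carbon
    stand-ins for the ring and two capping hydrogens.

    Charges are a plausible nitroxide-like set (N +0.15, O -0.35, the rest
    balancing to neutrality); LJ parameters are generic GAFF-like values.
    """
    coords = np.array([
        [0.000, 0.000, 0.000],     # N
        [0.000, 0.000, 1.280],     # O (nitroxide oxygen)
        [1.310, 0.000, -0.720],    # C
        [-1.310, 0.000, -0.720],   # C
        [1.350, 0.880, -1.360],    # H
        [-1.350, -0.880, -1.360],  # H
    ])
    return SoluteConformer(
        elements=["N", "O", "C", "C", "H", "H"],
        coords=coords,
        charges=np.array([0.15, -0.35, 0.05, 0.05, 0.05, 0.05]),
        lj_sigma=np.array([3.25, 2.96, 3.40, 3.40, 2.47, 2.47]),
        lj_epsilon=np.array([0.17, 0.21, 0.109, 0.109, 0.0157, 0.0157]),
        roles={"nitroxide_N": 0, "nitroxide_O": 1},
    )


_WATER_LOCAL = np.array([
    [0.0, 0.0, 0.0],
    [0.9572, 0.0, 0.0],
    [-0.2400, 0.9266, 0.0],
])


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_water_box(spec: FixtureSpec = None):
    """Frames of one rigid solute + rigid waters in a periodic cubic box.

    Waters are inserted by rejection sampling against a minimum O-O /
    O-solute distance (minimum image); each frame applies independent
    small rigid-body jitter to every water.  Raises if the requested
    density cannot be packed.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    L = spec.box_length
    solute = nitroxide_fragment()
    sol_coords = solute.coords + L / 2        # solute at box center
    o_positions = []
    fail_streak = 0
    while len(o_positions) < spec.n_waters:
        if fail_streak > 20000:
            raise RuntimeError(
                f"could not pack {spec.n_waters} waters at the requested "
                f"density (box {L} A, min distance {spec.min_distance} A)"
            )
        cand = rng.uniform(0, L, size=3)
        d_sol = _min_image_dist(cand[None, :], sol_coords, L).min()
        if d_sol < spec.min_distance:
            fail_streak += 1
            continue
        if o_positions:
            d_oo = _min_image_dist(cand[None, :], np.array(o_positions), L).min()
            if d_oo < spec.min_distance:
                fail_streak += 1
                continue
        fail_streak = 0
        o_positions.append(cand)
    o_positions = np.array(o_positions).reshape(-1, 3)
    orientations = [_random_rotation(rng) for _ in range(spec.n_waters)]

    frames = []
    for f in range(spec.n_frames):
        elements = list(solute.elements)
        coords = [sol_coords]
        mol_ids = [0] * len(solute.elements)
        for w in range(spec.n_waters):
            shift = rng.normal(scale=spec.jitter, size=3)
            wobble = _random_rotation(rng) if spec.jitter > 0 else np.eye(3)
            # small rotational jitter: blend toward identity
            R = orientations[w] @ (
                np.eye(3) + 0.1 * (wobble - np.eye(3))
            )
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
            mol = (_WATER_LOCAL @ R.T) + o_positions[w] + shift
            elements.extend(["O", "H", "H"])
            coords.append(mol)
            mol_ids.extend([w + 1] * 3)
        frames.append(TrajectoryFrame(
            coords=np.concatenate(coords),
            elements=elements,
            mol_ids=np.array(mol_ids),
            box_length=L,
            time_fs=f * spec.frame_spacing_fs,
        ))
    return frames


def _min_image_dist(a, b, L):
    d = a[:, None, :] - b[None, :, :]
    d -= L * np.round(d / L)
    return np.linalg.norm(d, axis=-1)


def make_hfcc_samples(means: dict, sigmas, n: int, seed: int = 0,
                      nucleus: str = "14N") -> dict:
    """i.i.d. normal A_iso ensembles, one per treatment label.

    means: {treatment: mean MHz}; sigmas: scalar or matching dict."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    out = {}
    for label, mu in means.items():
        sigma = sigmas[label] if isinstance(sigmas, dict) else float(sigmas)
        samples = rng.normal(loc=mu, scale=sigma, size=n) if sigma > 0 \
            else np.full(n, float(mu))
        out[label] = HfccEnsemble.from_samples(
            samples, nucleus=nucleus, treatment=label
        )
    return out


def make_spin_density_cube(kind: str, n: int = 24, spacing: float = 0.25,
                           origin=(0.0, 0.0, 0.0), **params) -> CubeVolume:
    """Analytic spin-density volumes: 'constant' (value=), 'gaussian'
    (amplitude=, width=, center=), or 'linear' (gradient=, offset=)."""
    origin = np.asarray(origin, dtype=float)
    ax = [origin[i] + spacing * np.arange(n) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    if kind == "constant":
        vals = np.full((n, n, n), float(params.get("value", 1.0)))
    elif kind == "gaussian":
        amp = float(params.get("amplitude", 1.0))
        width = float(params.get("width", 1.0))
        center = np.asarray(params.get("center",
                                       origin + spacing * (n - 1) / 2))
        r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        vals = amp * np.exp(-r2 / (2 * width**2))
    elif kind == "linear":
        grad = np.asarray(params.get("gradient", (1.0, 0.0, 0.0)), dtype=float)
        vals = params.get("offset", 0.0) + grad[0] * X + grad[1] * Y + grad[2] * Z
    else:
        raise ValueError(f"unknown cube kind {kind!r}")
    return CubeVolume(origin=origin, spacing=np.repeat(spacing, 3), values=vals)
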