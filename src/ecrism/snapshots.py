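"""Periodic-snapshot extraction and solvation-shell bookkeeping.

A periodic cubic frame holding one solute and rigid 3-site waters is
converted into a finite spherical cluster suited to nonperiodic electronic
structure: the frame is replicated 3x3x3, the nitroxide oxygen of the
central solute copy is the pivot, and every replicated water whose oxygen
lies within the extraction radius

    R = (nearest image-pivot distance) - r_shell

is included.  By the triangle inequality no included water penetrates the
first solvation shell (radius r_shell) of any solute image, which is
exactly the clash-free condition the construction is designed around.
Waters are included or excluded as whole molecules, decided by their oxygen
site.

Shell labels come from radial-distribution-function minima around the
nitroxide oxygen: first shell up to 3.4 A, second shell 3.4-5.5 A.
QM/MM partitions assign the solute plus all waters up to a chosen shell to
the QM region and the remaining waters to an MM point-charge set (TIP3P
charges by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .embedding import EmbeddingChargeSet
from .fields import SoluteConformer
from .solvent import TIP3P_CHARGES

#: RDF-minimum shell cutoffs around the nitroxide oxygen (A)
FIRST_SHELL_RADIUS = 3.4
SECOND_SHELL_RADIUS = 5.5


@dataclass
class TrajectoryFrame:
    coords: np.ndarray             # (n, 3) A
    elements: list
    mol_ids: np.ndarray            # int, solute = 0, waters 1..n_w
    box_length: float              # A, cubic
    time_fs: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        if self.box_length <= 0:
            raise ValueError("box length must be positive")
        for m in np.unique(self.mol_ids):
            if m == 0:
                continue
            sel = self.mol_ids == m
            if sel.sum() != 3:
                raise ValueError(f"water molecule {m} has {sel.sum()} atoms, "
                                 "expected 3 (O,H,H)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def solute_indices(self) -> np.ndarray:
        return np.where(self.mol_ids == 0)[0]

    def water_ids(self) -> np.ndarray:
        ids = np.unique(self.mol_ids)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# extended-XYZ I/O (Lattice=... comment-line convention)

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([0-9.eE+-]+)")


def write_frames_extxyz(path, frames) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            L = fr.box_length
            fh.write(f"{fr.n_atoms}\n")
            fh.write(
                f'Lattice="{L} 0.0 0.0 0.0 {L} 0.0 0.0 0.0 {L}" '
                f'Properties=species:S:1:pos:R:3:mol:I:1 Time={fr.time_fs}\n'
            )
            for el, xyz, m in zip(fr.elements, fr.coords, fr.mol_ids):
                fh.write(f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f} {m}\n")


def _parse_extxyz(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].split()[0])
        comment = lines[i + 1]
        mlat = _LATTICE_RE.search(comment)
        if not mlat:
            raise ValueError("frame lacks a Lattice specification")
        lat = np.array([float(x) for x in mlat.group(1).split()])
        if lat.size != 9:
            raise ValueError("malformed Lattice line")
        lat = lat.reshape(3, 3)
        if not np.allclose(lat, np.diag(np.diag(lat))) or not np.allclose(
            np.diag(lat), lat[0, 0]
        ):
            raise ValueError("only cubic boxes are supported")
        mtime = _TIME_RE.search(comment)
        time_fs = float(mtime.group(1)) if mtime else 0.0
        has_mol = "mol:I:1" in comment
        elements, coords, mols = [], [], []
        for row in lines[i + 2 : i + 2 + nat]:
            parts = row.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
            if has_mol:
                mols.append(int(parts[4]))
        yield elements, np.array(coords), (np.array(mols, dtype=int)
                                           if has_mol else None), lat[0, 0], time_fs
        i += 2 + nat


def infer_mol_ids(elements, n_solute_atoms: int) -> np.ndarray:
    """Solute atoms first (mol 0), then O-H-H water triplets."""
    n = len(elements)
    if (n - n_solute_atoms) % 3 != 0:
        raise ValueError("trailing atoms do not form O,H,H water triplets")
    ids = np.zeros(n, dtype=int)
    w = 1
    for start in range(n_solute_atoms, n, 3):
        if elements[start] != "O" or elements[start + 1] != "H" \
                or elements[start + 2] != "H":
            raise ValueError(f"atoms {start}..{start+2} are not an O,H,H water")
        ids[start : start + 3] = w
        w += 1
    return ids


def read_frames(
    path,
    fmt: str = "extxyz",
    stride_fs: Optional[float] = None,
    n_solute_atoms: Optional[int] = None,
):
    """Frames from extended XYZ (Lattice= comment) or PDB (CRYST1).

    stride_fs keeps only frames whose time advances by at least that much
    since the last kept frame.  Molecule ids come from the mol column when
    present, else from the solute-first + O,H,H-triplet layout
    (n_solute_atoms required then).
    """
    if fmt == "extxyz":
        raw = _parse_extxyz(path)
    elif fmt == "pdb":
        raw = _parse_pdb(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    frames = []
    last_kept = None
    for elements, coords, mols, L, time_fs in raw:
        if stride_fs is not None and last_kept is not None and (
            time_fs - last_kept
        ) < stride_fs - 1e-9:
            continue
        last_kept = time_fs
        if mols is None:
            if n_solute_atoms is None:
                raise ValueError(
                    "no molecule ids in file; n_solute_atoms required"
                )
            mols = infer_mol_ids(elements, n_solute_atoms)
        frames.append(TrajectoryFrame(coords=coords, elements=elements,
                                      mol_ids=mols, box_length=L,
                                      time_fs=time_fs))
    return frames


def _parse_pdb(path):
    """Single-model PDB with CRYST1; molecule ids from residue numbers
    (residue 1 = solute)."""
    import MDAnalysis as mda

    u = mda.Universe(path)
    if u.dimensions is None or u.dimensions[0] <= 0:
        raise ValueError("PDB lacks box information (CRYST1)")
    a, b, c = u.dimensions[:3]
    if not (abs(a - b) < 1e-6 and abs(a - c) < 1e-6):
        raise ValueError("only cubic boxes are supported")
    elements = [n[0] for n in u.atoms.names]
    mols = u.atoms.resids - int(u.atoms.resids.min())
    yield elements, u.atoms.positions.astype(float), np.asarray(mols), float(a), 0.0


# ---------------------------------------------------------------------------

@dataclass
class SphericalCluster:
    solute_elements: list
    solute_coords: np.ndarray
    water_coords: np.ndarray       # (n_w, 3, 3): O,H,H per water
    water_distances: np.ndarray    # O distance to pivot, per water
    extraction_radius: float
    pivot_index: int               # index into solute atoms

    def __post_init__(self):
        self.solute_coords = np.asarray(self.solute_coords, dtype=float)
        self.water_coords = np.asarray(self.water_coords, dtype=float).reshape(
            -1, 3, 3
        )
        self.water_distances = np.asarray(self.water_distances, dtype=float)

    @property
    def n_waters(self) -> int:
        return len(self.water_coords)

    @property
    def pivot(self) -> np.ndarray:
        return self.solute_coords[self.pivot_index]


def extract_spherical_cluster(
    frame: TrajectoryFrame,
    pivot_atom: int,
    r_shell: float = FIRST_SHELL_RADIUS,
) -> SphericalCluster:
    """Replicate 3x3x3 and carve the clash-free sphere around the pivot.

    pivot_atom indexes the frame's atoms and must belong to the solute
    (the nitroxide oxygen in the intended use).  Extraction radius is the
    nearest image-pivot distance minus r_shell; inclusion is decided by
    each water's O site; waters enter whole.
    """
    if frame.mol_ids[pivot_atom] != 0:
        raise ValueError("pivot atom must belong to the solute")
    L = frame.box_length
    pivot = frame.coords[pivot_atom]
    shifts = np.array([
        [i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    ]) * L
    image_pivot_d = np.linalg.norm(shifts, axis=1)
    d_nn = image_pivot_d[image_pivot_d > 0].min()   # = L for a cubic box
    R = d_nn - r_shell
    if R <= 0:
        raise ValueError(
            f"box too small: nearest-image pivot distance {d_nn:.2f} A does "
            f"not exceed the shell radius {r_shell:.2f} A"
        )
    sol_idx = frame.solute_indices()
    water_coords = []
    water_d = []
    for wid in frame.water_ids():
        sel = np.where(frame.mol_ids == wid)[0]
        # O first within the triplet
        order = sorted(sel, key=lambda a: 0 if frame.elements[a] == "O" else 1)
        mol = frame.coords[order]
        for s in shifts:
            o_pos = mol[0] + s
            d = np.linalg.norm(o_pos - pivot)
            if d <= R:
                water_coords.append(mol + s)
                water_d.append(d)
    return SphericalCluster(
        solute_elements=[frame.elements[a] for a in sol_idx],
        solute_coords=frame.coords[sol_idx].copy(),
        water_coords=(np.array(water_coords).reshape(-1, 3, 3)
                      if water_coords else np.zeros((0, 3, 3))),
        water_distances=np.array(water_d),
        extraction_radius=R,
        pivot_index=int(np.where(sol_idx == pivot_atom)[0][0]),
    )


@dataclass
class ShellPartition:
    labels: np.ndarray             # per-water: "first" | "second" | "outer"
    r1: float
    r2: float

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))


def assign_shells(
    cluster: SphericalCluster,
    r1: float = FIRST_SHELL_RADIUS,
    r2: float = SECOND_SHELL_RADIUS,
) -> ShellPartition:
    """Label waters by O distance to the pivot: <=r1 first, (r1,r2] second,
    beyond that outer."""
    if not r1 < r2:
        raise ValueError("need r1 < r2")
    d = cluster.water_distances
    labels = np.where(d <= r1, "first", np.where(d <= r2, "second", "outer"))
    return ShellPartition(labels=labels, r1=r1, r2=r2)


def vertical_desolvation(cluster: SphericalCluster) -> SoluteConformer:
    """Strip all waters, keeping the instantaneous solute geometry
    bit-for-bit (the structural memory of the solvation environment)."""
    return SoluteConformer(
        elements=list(cluster.solute_elements),
        coords=cluster.solute_coords.copy(),
        charges=np.zeros(len(cluster.solute_elements)),
    )


PARTITION_LEVELS = ("none", "first", "second", "full")


@dataclass
class QmmmPartition:
    qm_elements: list
    qm_coords: np.ndarray
    qm_water_count: int
    mm_charges: EmbeddingChargeSet


def qmmm_partition(
    cluster: SphericalCluster,
    level: str = "second",
    shells: Optional[ShellPartition] = None,
    mm_charge_model: dict = None,
) -> QmmmPartition:
    """QM = solute + waters up to the requested shell; MM = all remaining
    waters as per-site point charges at their snapshot positions."""
    if level not in PARTITION_LEVELS:
        raise ValueError(f"level must be one of {PARTITION_LEVELS}")
    if shells is None:
        shells = assign_shells(cluster)
    if mm_charge_model is None:
        mm_charge_model = dict(TIP3P_CHARGES)
    rank = {"first": 1, "second": 2, "outer": 3}
    level_rank = {"none": 0, "first": 1, "second": 2, "full": 3}[level]
    qm_el = list(cluster.solute_elements)
    qm_xyz = [cluster.solute_coords]
    mm_pos, mm_q = [], []
    qm_waters = 0
    site_q = [mm_charge_model["O"], mm_charge_model["H"], mm_charge_model["H"]]
    for w in range(cluster.n_waters):
        if rank[str(shells.labels[w])] <= level_rank:
            qm_el.extend(["O", "H", "H"])
            qm_xyz.append(cluster.water_coords[w])
            qm_waters += 1
        else:
            mm_pos.append(cluster.water_coords[w])
            mm_q.extend(site_q)
    mm = EmbeddingChargeSet(
        positions=(np.concatenate(mm_pos) if mm_pos else np.zeros((0, 3))),
        charges=np.array(mm_q),
        provenance="raw-grid",
    )
    return QmmmPartition(
        qm_elements=qm_el,
        qm_coords=np.concatenate(qm_xyz),
        qm_water_count=qm_waters,
        mm_charges=mm,
    )


def write_qm_deck(prefix, part: QmmmPartition) -> None:
    """Two-file deck: <prefix>.xyz (QM region) and <prefix>.mmq
    (x y z q MM charges), consumable by external QC codes."""
    with open(f"{prefix}.xyz", "w") as fh:
        fh.write(f"{len(part.qm_elements)}\n")
        fh.write("QM region (solute + explicit waters)\n")
        for el, xyz in zip(part.qm_elements, part.qm_coords):
            fh.write(f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")
    part.mm_charges.to_text(f"{prefix}.mmq")


def compute_rdf(
    frames,
    site_a,
    site_b,
    r_max: Optional[float] = None,
    n_bins: int = 100,
):
    """Radial distribution function between two site selections.

    site_a / site_b: callables mapping a frame to index arrays (or
    (element, mol) selector tuples, e.g. ("O", "water")).  Minimum-image
    distances in the cubic box; standard shell-volume normalization against
    the b-site bulk density.  Returns (bin centers, g, standard error over
    frames).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    L = frames[0].box_length
    if r_max is None:
        r_max = L / 2
    if r_max > L / 2 + 1e-9:
        raise ValueError("r_max must not exceed half the box length")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    per_frame = []
    for fr in frames:
        ia = _select(fr, site_a)
        ib = _select(fr, site_b)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError("empty site selection")
        d = fr.coords[ib][None, :, :] - fr.coords[ia][:, None, :]
        d -= L * np.round(d / L)
        dist = np.linalg.norm(d, axis=-1).ravel()
        dist = dist[dist > 1e-9]      # drop self pairs
        hist, _ = np.histogram(dist, bins=edges)
        rho_b = len(ib) / fr.box_length**3
        norm = len(ia) * rho_b * shell_vol
        per_frame.append(hist / norm)
    per_frame = np.array(per_frame)
    g = per_frame.mean(axis=0)
    if len(frames) > 1:
        se = per_frame.std(axis=0, ddof=1) / np.sqrt(len(frames))
    else:
        se = np.zeros_like(g)
    return centers, g, se


def _select(frame: TrajectoryFrame, sel):
    if callable(sel):
        return np.asarray(sel(frame), dtype=int)
    element, which = sel
    idx = [
        i for i, el in enumerate(frame.elements)
        if el == element and (
            (which == "water" and frame.mol_ids[i] > 0)
            or (which == "solute" and frame.mol_ids[i] == 0)
            or which == "any"
        )
    ]
    return np.asarray(idx, dtype=int)
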