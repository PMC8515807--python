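"""Gaussian cube volumetric files and trilinear sampling.

Cube files follow the conventional layout: two comment lines, an atom-count /
origin line, three voxel-vector lines, atom records, then values with the z
index fastest.  Lengths in the file are in Bohr (positive voxel counts), as
the format prescribes; the in-memory representation is in Angstrom.
Only axis-aligned (diagonal voxel matrix) cubes are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_A

# minimal symbol table; cube atom records carry atomic numbers
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}
_SYM = {v: k for k, v in _Z.items()}


@dataclass
class CubeVolume:
    """A scalar field on a uniform axis-aligned grid.

    origin: position of voxel (0,0,0) in Angstrom; spacing: per-axis voxel
    edge in Angstrom; values: array of shape (nx, ny, nz).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    atom_numbers: list = field(default_factory=list)
    atom_coords: np.ndarray = None  # Angstrom

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be a 3D array")
        if self.atom_coords is None:
            self.atom_coords = np.zeros((0, 3))

    @property
    def shape(self):
        return self.values.shape

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing[i] * np.arange(self.shape[i])

    def sample(self, point) -> float:
        """Trilinear interpolation at a Cartesian point (Angstrom).

        Exact for fields linear in each axis; raises on points outside the
        grid's convex hull.
        """
        p = np.asarray(point, dtype=float)
        t = (p - self.origin) / self.spacing
        n = np.array(self.shape)
        if np.any(t < -1e-9) or np.any(t > n - 1 + 1e-9):
            raise ValueError(f"point {point} outside cube bounds")
        t = np.clip(t, 0.0, n - 1)
        i0 = np.minimum(t.astype(int), n - 2)
        f = t - i0
        v = self.values
        ix, iy, iz = i0
        fx, fy, fz = f
        c = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    c += wx * wy * wz * v[ix + dx, iy + dy, iz + dz]
        return float(c)


def write_cube(path, vol: CubeVolume, comment: str = "ecrism volume") -> None:
    nx, ny, nz = vol.shape
    o = vol.origin / BOHR_A
    d = vol.spacing / BOHR_A
    nat = len(vol.atom_numbers)
    lines = [comment, "generated by ecrism"]
    lines.append(f"{nat:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}")
    lines.append(f"{nx:5d} {d[0]:12.6f} {0.0:12.6f} {0.0:12.6f}")
    lines.append(f"{ny:5d} {0.0:12.6f} {d[1]:12.6f} {0.0:12.6f}")
    lines.append(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {d[2]:12.6f}")
    for z, xyz in zip(vol.atom_numbers, np.asarray(vol.atom_coords) / BOHR_A):
        lines.append(
            f"{z:5d} {0.0:12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
        )
    for row in vol.values.reshape(nx * ny, nz):
        for start in range(0, nz, 6):
            chunk = row[start : start + 6]
            lines.append(" ".join(f"{v:13.5E}" for v in chunk))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path) -> CubeVolume:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    header = tokens[2].split()
    nat = int(header[0])
    origin = np.array([float(x) for x in header[1:4]]) * BOHR_A
    ns, spac = [], []
    for i in range(3):
        parts = tokens[3 + i].split()
        ns.append(int(parts[0]))
        vec = np.array([float(x) for x in parts[1:4]])
        if np.count_nonzero(vec) != 1:
            raise ValueError("only axis-aligned cubes are supported")
        spac.append(vec[i])
    atom_numbers, coords = [], []
    for i in range(nat):
        parts = tokens[6 + i].split()
        atom_numbers.append(int(parts[0]))
        coords.append([float(x) for x in parts[2:5]])
    data = []
    for line in tokens[6 + nat :]:
        data.extend(float(x) for x in line.split())
    nx, ny, nz = ns
    if len(data) != nx * ny * nz:
        raise ValueError("cube data length does not match grid dimensions")
    values = np.array(data).reshape(nx, ny, nz)
    return CubeVolume(
        origin=origin,
        spacing=np.array(spac) * BOHR_A,
        values=values,
        atom_numbers=atom_numbers,
        atom_coords=np.array(coords).reshape(-1, 3) * BOHR_A,
    )
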