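"""Molecular-interaction-field engine.

Interaction energies of four chemical probes (DRY hydrophobic, O carbonyl
oxygen, N1 amide nitrogen, TIP shape) are evaluated on a regular grid around
each molecule.  Energy model for DRY/O/N1 (per atom, pairwise additive):

* Lennard-Jones 12-6, ``eps_ij*((r0_ij/r)^12 - 2*(r0_ij/r)^6)``, with
  ``r0_ij = r_vdw(atom) + r0_delta(probe)`` and geometric-mean well depth.
  The DRY probe keeps only the repulsive branch against polar atoms so that
  its favourable regions are genuinely hydrophobic hot spots.
* Coulomb term with a distance-dependent dielectric eps(r) = 4r, i.e.
  ``332.0636*q_p*q_a/(4*r^2)``, smoothly switched off between 12 and 18 A.
* A single Gaussian H-bond well between complementary partners (probe O with
  donor atoms, probe N1 with acceptor atoms), centred at the canonical
  2.9 A donor-acceptor distance.

The TIP probe is an indicator field: -1 on a one-voxel shell just outside
the molecular van der Waals surface, 0 elsewhere (steric hot spots).

Grids are axis-aligned in a *canonical molecule-fixed frame* (principal axes
of the atom cloud with a deterministic sign convention).  Because every
downstream quantity depends only on probe-atom and node-node distances, this
makes the final descriptors invariant under rigid-body motion of the input
structure - the defining property of alignment-independent descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .params import ProbeParams, load_probe_params
from .structures import Molecule

BOHR_PER_ANGSTROM = 1.8897259886

_ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15,
                   "S": 16, "Cl": 17, "Br": 35, "I": 53}
_SYMBOLS = {v: k for k, v in _ATOMIC_NUMBERS.items()}


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    origin: np.ndarray          # world coordinates of grid point (0,0,0), A
    spacing: float              # A
    shape: tuple[int, int, int]
    margin: float = 5.0
    axes: np.ndarray = None     # (3,3) rows = grid axis directions (unit)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(s < 2 for s in self.shape):
            raise ValueError("grid shape must be at least 2 per axis")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.axes is None:
            self.axes = np.eye(3)
        self.axes = np.asarray(self.axes, dtype=float)

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def diagonal(self) -> float:
        """Box diagonal length in A (used to normalize node-spread scores)."""
        ext = (np.array(self.shape) - 1) * self.spacing
        return float(np.linalg.norm(ext))

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array, C-ordered (z fastest)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        return self.origin + (idx * self.spacing) @ self.axes


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal-axis frame of an atom cloud.

    Axes are ordered by decreasing variance; each axis sign is fixed by the
    third moment of the projections (falling back to the largest-magnitude
    projection, then +).  Degenerate clouds fall back to world axes.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if len(coords) < 3:
        axes = np.eye(3)
        if len(coords) == 2:
            v = centered[1] - centered[0]
            n = np.linalg.norm(v)
            if n > 1e-12:
                e0 = v / n
                helper = np.array([0.0, 0.0, 1.0])
                if abs(e0 @ helper) > 0.9:
                    helper = np.array([0.0, 1.0, 0.0])
                e1 = np.cross(helper, e0)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(e0, e1)
                axes = np.vstack([e0, e1, e2])
        return centroid, axes
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows
    proj = centered @ axes.T
    for k in range(3):
        skew = float(np.sum(proj[:, k] ** 3))
        if abs(skew) > 1e-9:
            sign = np.sign(skew)
        else:
            j = int(np.argmax(np.abs(proj[:, k])))
            sign = np.sign(proj[j, k]) or 1.0
        axes[k] *= sign
    # enforce a right-handed frame (reflections do not affect distances)
    if np.linalg.det(axes) < 0:
        axes[2] *= -1
    return centroid, axes


def build_grid(mol: Molecule, spacing: float = 0.5, margin: float = 5.0,
               frame: str = "canonical") -> GridSpec:
    """Bounding box of the molecule expanded by ``margin`` on every side.

    ``frame="canonical"`` (default) aligns the box with the molecule's
    principal axes; ``frame="world"`` uses laboratory axes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = mol.coords
    if frame == "canonical":
        centroid, axes = canonical_frame(coords)
    elif frame == "world":
        centroid, axes = coords.mean(axis=0), np.eye(3)
    else:
        raise ValueError(f"unknown frame {frame!r}")
    proj = (coords - centroid) @ axes.T
    lo = proj.min(axis=0) - margin
    hi = proj.max(axis=0) + margin
    extent = hi - lo
    shape = tuple(int(np.floor(e / spacing + 1e-9)) + 1 for e in extent)
    origin = centroid + lo @ axes
    return GridSpec(origin=origin, spacing=spacing, shape=shape,
                    margin=margin, axes=axes)


# ---------------------------------------------------------------------------
# Field computation
# ---------------------------------------------------------------------------

@dataclass
class Field:
    grid: GridSpec
    probe_id: str
    energies: np.ndarray  # shape = grid.shape, kcal/mol

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != tuple(self.grid.shape):
            raise ValueError("energy array shape does not match grid")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("field energies must be finite")


def _switch(r: np.ndarray, start: float, end: float) -> np.ndarray:
    """Cubic smoothstep from 1 (r<=start) to 0 (r>=end)."""
    t = np.clip((r - start) / (end - start), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def compute_field(mol: Molecule, probe: ProbeParams, grid: GridSpec) -> Field:
    """Evaluate one probe's interaction energy on every grid point."""
    coords = mol.coords
    elements = mol.elements
    points = grid.points()

    if probe.probe_id == "TIP":
        radii = np.array([probe.atom_r0[el] for el in elements])
        d = cdist(points, coords)
        d_surf = (d - radii[None, :]).min(axis=1)
        e = np.where((d_surf >= 0.0) & (d_surf <= grid.spacing), -1.0, 0.0)
        return Field(grid, "TIP", e.reshape(grid.shape))

    charges = np.array([a.partial_charge for a in mol.atoms])
    if np.all(charges == 0.0) and probe.charge != 0.0 and len(mol.atoms) > 1:
        raise ValueError(
            "molecule has no partial charges; run assign_partial_charges first")

    r0 = np.array([probe.atom_r0[el] + probe.r0_delta for el in elements])
    eps = np.array([np.sqrt(probe.atom_eps[el] * probe.eps) for el in elements])

    d = cdist(points, coords)
    np.maximum(d, probe.distance_floor, out=d)

    x6 = (r0[None, :] / d) ** 6
    if probe.probe_id == "DRY":
        hydro = np.array([a.is_hydrophobic for a in mol.atoms])
        # full LJ with hydrophobic atoms, repulsion-only with the rest
        attract = np.where(hydro[None, :], 2.0 * x6, 0.0)
        lj = eps[None, :] * (x6 * x6 - attract)
    else:
        lj = eps[None, :] * (x6 * x6 - 2.0 * x6)
    energy = lj.sum(axis=1)

    if probe.charge != 0.0:
        elec = (probe.coulomb_constant * probe.charge * charges[None, :]
                / (probe.dielectric_slope * d * d))
        elec *= _switch(d, probe.elec_cutoff_start, probe.elec_cutoff_end)
        energy += elec.sum(axis=1)

    if probe.hbond_depth > 0.0 and probe.hbond_partner != "none":
        flag = {"hba": [a.is_hba for a in mol.atoms],
                "hbd": [a.is_hbd for a in mol.atoms]}[probe.hbond_partner]
        mask = np.array(flag)
        if mask.any():
            dh = d[:, mask]
            well = probe.hbond_depth * np.exp(
                -((dh - probe.hbond_center) ** 2) / (2.0 * probe.hbond_width ** 2))
            energy -= well.sum(axis=1)

    np.minimum(energy, probe.energy_clamp, out=energy)
    return Field(grid, probe.probe_id, energy.reshape(grid.shape))


def compute_all_fields(mol: Molecule, grid: GridSpec | None = None,
                       spacing: float = 0.5, margin: float = 5.0,
                       probes: dict[str, ProbeParams] | None = None) -> dict[str, Field]:
    """All four probe fields on a shared grid (built if not given)."""
    if probes is None:
        probes = load_probe_params()
    if grid is None:
        grid = build_grid(mol, spacing=spacing, margin=margin)
    return {pid: compute_field(mol, p, grid) for pid, p in probes.items()}


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------

def write_cube(field: Field, path, mol: Molecule | None = None) -> None:
    """Write a field as a Gaussian cube file (lengths converted to Bohr)."""
    g = field.grid
    nx, ny, nz = g.shape
    b = BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"grindqsar probe field: {field.probe_id}\n")
        fh.write("interaction energies in kcal/mol\n")
        natoms = len(mol.atoms) if mol is not None else 0
        ox, oy, oz = g.origin * b
        fh.write(f"{natoms:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        for n, axis in zip(g.shape, g.axes):
            vx, vy, vz = axis * g.spacing * b
            fh.write(f"{n:5d}{vx:12.6f}{vy:12.6f}{vz:12.6f}\n")
        if mol is not None:
            for atom in mol.atoms:
                z = _ATOMIC_NUMBERS[atom.element]
                x, y, zz = atom.coords * b
                fh.write(f"{z:5d}{float(z):12.6f}{x:12.6f}{y:12.6f}{zz:12.6f}\n")
        flat = field.energies.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                vals = row[start:start + 6]
                fh.write("".join(f"{v:13.5E}" for v in vals) + "\n")


def read_cube(path) -> Field:
    """Read a cube file written by :func:`write_cube`."""
    with open(path) as fh:
        first = fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) / BOHR_PER_ANGSTROM
        shape = []
        axes = []
        spacing = None
        for _ in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            vec = np.array([float(x) for x in parts[1:4]]) / BOHR_PER_ANGSTROM
            step = float(np.linalg.norm(vec))
            spacing = step if spacing is None else spacing
            axes.append(vec / step)
        for _ in range(natoms):
            fh.readline()
        values = []
        for line in fh:
            values.extend(float(tok) for tok in line.split())
    energies = np.array(values).reshape(tuple(shape))
    grid = GridSpec(origin=origin, spacing=spacing, shape=tuple(shape),
                    axes=np.array(axes))
    # probe id lives in the first comment line
    pid = first.rsplit(":", 1)[-1].strip() if ":" in first else "field"
    return Field(grid, pid, energies)
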