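"""Molecular structures: SDF I/O, partial charges and pharmacophore atom typing.

Molecules are plain containers of typed 3D atoms.  The probe fields consume
only element symbols, coordinates, Gasteiger partial charges and three
pharmacophore flags (hydrophobic / H-bond acceptor / H-bond donor), so the
container deliberately carries nothing else beyond bonds, an identifier, an
optional activity (pIC50) and an optional structural-cluster label.

Protonation and tautomer states are taken as given in the input file:
structures are expected to arrive with explicit hydrogens (donor typing
requires them) and the reader never adds or removes atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdPartialCharges

RDLogger.DisableLog("rdApp.*")

#: elements the typing and energy rules are parameterized for
SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S", "F", "Cl", "Br", "I", "P"}

CLUSTERS = ("I", "II", "III", "IV")


class SDFParseError(ValueError):
    """Raised when an SDF record cannot be parsed; names the record index."""


class UnknownElementError(ValueError):
    pass


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    partial_charge: float = 0.0
    formal_charge: int = 0
    is_hydrophobic: bool = False
    is_hba: bool = False
    is_hbd: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    activity: float | None = None  # pIC50
    cluster: str | None = None

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("molecule needs at least one atom")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) has invalid atom indices")
        if self.activity is not None and not math.isfinite(self.activity):
            raise ValueError("activity must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


# ---------------------------------------------------------------------------
# RDKit conversion layer
# ---------------------------------------------------------------------------

_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    1.5: Chem.BondType.AROMATIC,
}


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Build an RDKit molecule (with conformer) from a :class:`Molecule`."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        if atom.element not in SUPPORTED_ELEMENTS:
            raise UnknownElementError(f"unsupported element: {atom.element}")
        rd_atom = Chem.Atom(atom.element)
        rd_atom.SetFormalCharge(int(atom.formal_charge))
        rw.AddAtom(rd_atom)
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), _BOND_TYPES.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(mol.atoms))
    for k, atom in enumerate(mol.atoms):
        conf.SetAtomPosition(k, tuple(float(x) for x in atom.coords))
    m = rw.GetMol()
    m.AddConformer(conf)
    for a in m.GetAtoms():
        a.SetNoImplicit(True)  # explicit hydrogens are authoritative
    return m


def from_rdkit(rdmol: Chem.Mol, mol_id: str) -> Molecule:
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), np.array([pos.x, pos.y, pos.z]),
                          formal_charge=a.GetFormalCharge()))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------

def read_sdf(path, activity_prop: str = "pIC50", cluster_prop: str = "cluster") -> list[Molecule]:
    """Read a V2000 SDF file into a list of molecules, in file order.

    Coordinates are taken verbatim; hydrogens are kept.  The activity is
    populated from the named SDF property when present.  A malformed record
    raises :class:`SDFParseError` naming the (0-based) record index.
    """
    import os
    if not os.path.exists(path):
        raise FileNotFoundError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols: list[Molecule] = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise SDFParseError(f"cannot parse SDF record {idx} in {path}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol = from_rdkit(rdmol, name or f"mol{idx}")
        if rdmol.HasProp(activity_prop):
            mol.activity = float(rdmol.GetProp(activity_prop))
        if rdmol.HasProp(cluster_prop):
            mol.cluster = rdmol.GetProp(cluster_prop)
        mols.append(mol)
    return mols


def write_sdf(mols: list[Molecule], path, activity_prop: str = "pIC50",
              cluster_prop: str = "cluster") -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in mols:
        rdmol = to_rdkit(mol)
        rdmol.SetProp("_Name", mol.id)
        if mol.activity is not None:
            rdmol.SetProp(activity_prop, f"{mol.activity:.6f}")
        if mol.cluster is not None:
            rdmol.SetProp(cluster_prop, mol.cluster)
        writer.write(rdmol)
    writer.close()


def read_activity_table(path) -> pd.DataFrame:
    """Read the activity CSV (columns id, pIC50, cluster, set)."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "pIC50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing column(s): {sorted(missing)}")
    if "cluster" not in df.columns:
        df["cluster"] = "I"
    if "set" not in df.columns:
        df["set"] = "unassigned"
    return df


def write_activity_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def assign_pharmacophore_types(mol: Molecule, sulfur_flags: bool = False) -> Molecule:
    """Flag hydrophobic / H-bond acceptor / H-bond donor atoms.

    Rules (deterministic functions of the bond graph):

    * carbon not bonded to N, O or S is hydrophobic;
    * oxygen is an acceptor; oxygen bonded to H is also a donor (hydroxyl);
    * nitrogen bonded to H is a donor;
    * nitrogen is an acceptor when a lone pair is plausibly available:
      three or fewer connections, not an amide nitrogen (no neighbouring
      carbonyl carbon), and not a pyrrole-type N-H inside an aromatic ring.

    Sulfur carries no flags by default (``sulfur_flags=True`` treats it like
    oxygen's acceptor rule and carbon's hydrophobe exclusion stays).
    """
    elements = mol.elements
    for el in elements:
        if el not in SUPPORTED_ELEMENTS:
            raise UnknownElementError(f"unknown element symbol: {el}")
    if not mol.bonds and len(mol.atoms) > 1:
        raise ValueError("bonds required for pharmacophore typing")

    bond_order = {}
    for i, j, order in mol.bonds:
        bond_order[(i, j)] = order
        bond_order[(j, i)] = order

    def has_carbonyl(c_idx: int) -> bool:
        for nb in mol.neighbors(c_idx):
            if elements[nb] == "O" and bond_order[(c_idx, nb)] >= 2.0:
                return True
        return False

    new_atoms = []
    for i, atom in enumerate(mol.atoms):
        nbrs = mol.neighbors(i)
        nbr_el = [elements[j] for j in nbrs]
        has_h = "H" in nbr_el
        hba = hbd = hydrophobic = False
        if atom.element == "C":
            hydrophobic = not any(e in ("N", "O", "S") for e in nbr_el)
        elif atom.element == "O":
            hba = True
            hbd = has_h
        elif atom.element == "N":
            hbd = has_h
            amide = any(elements[j] == "C" and has_carbonyl(j) for j in nbrs)
            aromatic = any(bond_order[(i, j)] == 1.5 for j in nbrs)
            pyrrole_like = aromatic and has_h
            hba = len(nbrs) <= 3 and not amide and not pyrrole_like
        elif atom.element == "S" and sulfur_flags:
            hba = True
            hbd = has_h
        new_atoms.append(replace(atom, is_hydrophobic=hydrophobic, is_hba=hba, is_hbd=hbd))
    return Molecule(mol.id, new_atoms, list(mol.bonds), mol.activity, mol.cluster)


def assign_partial_charges(mol: Molecule) -> Molecule:
    """Assign Gasteiger iterative electronegativity-equalization charges.

    Charges are computed on the bond graph (geometry plays no role) and sum
    to the molecule's net formal charge to within 1e-6.
    """
    rdmol = to_rdkit(mol)
    try:
        problems = Chem.DetectChemistryProblems(rdmol)
        if problems:
            raise ValueError("; ".join(p.Message() for p in problems))
        Chem.SanitizeMol(rdmol)
        rdPartialCharges.ComputeGasteigerCharges(rdmol, throwOnParamFailure=True)
    except Exception as exc:  # noqa: BLE001 - re-raise with molecule context
        raise ValueError(f"cannot assign charges for {mol.id!r}: {exc}") from exc
    charges = [float(a.GetDoubleProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
    if not all(math.isfinite(q) for q in charges):
        raise ValueError(f"non-finite Gasteiger charge for {mol.id!r}")
    net = sum(a.formal_charge for a in mol.atoms)
    if abs(sum(charges) - net) > 1e-6:
        raise ValueError(f"charge not conserved for {mol.id!r}: "
                         f"sum {sum(charges):.8f} vs net formal charge {net}")
    new_atoms = [replace(a, partial_charge=q) for a, q in zip(mol.atoms, charges)]
    return Molecule(mol.id, new_atoms, list(mol.bonds), mol.activity, mol.cluster)


def prepare(mol: Molecule, sulfur_flags: bool = False) -> Molecule:
    """Charges + pharmacophore flags in one call (pipeline convenience)."""
    return assign_pharmacophore_types(assign_partial_charges(mol), sulfur_flags=sulfur_flags)
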