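"""GRIND encoding: field-node extraction and auto/cross-correlograms.

A handful of favourable (negative-energy) grid points per probe -- the
*nodes* -- summarize each molecular interaction field.  Node selection
trades intensity against mutual spread, mirroring the discretization step
of alignment-independent descriptor software.  Descriptors are then the
per-molecule maximum products of node energies, indexed by probe pair and
inter-node distance bin (the MACC2 transform): for probes A, B and bin
``[k*bw, (k+1)*bw)`` the variable value is

    max over pairs (i in A, j in B) of  E_i * E_j   with  dist(i,j) in bin.

Products of two negative energies are positive, so all descriptor values
are >= 0 and a larger value marks a more intense pair of hot spots at that
distance.  Because only inter-node distances and energies enter, the
descriptor vector is invariant under rigid-body motion of the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fields import Field
from .params import PROBES

#: probe-pair blocks, in fixed order: the four autocorrelograms then the
#: six cross-correlograms.
BLOCKS = ("DRY-DRY", "O-O", "N1-N1", "TIP-TIP",
          "DRY-O", "DRY-N1", "DRY-TIP", "O-N1", "O-TIP", "N1-TIP")

_EPS = 1e-9


@dataclass
class Node:
    coords: np.ndarray
    energy: float  # kcal/mol, negative
    probe_id: str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.energy >= 0:
            raise ValueError("node energy must be negative (favorable)")


@dataclass
class NodeSet:
    molecule_id: str
    nodes: dict[str, list[Node]] = dc_field(default_factory=dict)
    n_nodes: int = 100
    w: float = 0.5


@dataclass(frozen=True)
class VariableMeta:
    index: int        # 1-based, unique across all blocks
    block: str        # e.g. "DRY-N1"
    bin_low: float    # A
    bin_high: float   # A

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``DRY-N1: 13.2–13.6 Å``."""
        return f"{self.block}: {self.bin_low:g}–{self.bin_high:g} Å"

    @property
    def column(self) -> str:
        return f"{self.block}_{self.bin_low:.1f}_{self.bin_high:.1f}"


def n_bins(bin_width: float, max_distance: float) -> int:
    """Number of complete distance bins per block."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return int(np.floor(max_distance / bin_width + _EPS))


def variable_lookup(index: int, bin_width: float = 0.4,
                    max_distance: float = 25.0) -> VariableMeta:
    nb = n_bins(bin_width, max_distance)
    total = nb * len(BLOCKS)
    if not 1 <= index <= total:
        raise IndexError(f"variable index {index} outside 1..{total}")
    block_idx, bin_idx = divmod(index - 1, nb)
    return VariableMeta(index=index, block=BLOCKS[block_idx],
                        bin_low=bin_idx * bin_width,
                        bin_high=(bin_idx + 1) * bin_width)


def meta_to_index(block: str, bin_low: float, bin_width: float = 0.4,
                  max_distance: float = 25.0) -> int:
    nb = n_bins(bin_width, max_distance)
    block_idx = BLOCKS.index(block)
    bin_idx = int(np.floor(bin_low / bin_width + 0.5))
    return block_idx * nb + bin_idx + 1


def all_variable_meta(bin_width: float = 0.4,
                      max_distance: float = 25.0) -> list[VariableMeta]:
    nb = n_bins(bin_width, max_distance)
    return [variable_lookup(i, bin_width, max_distance)
            for i in range(1, nb * len(BLOCKS) + 1)]


# ---------------------------------------------------------------------------
# Node extraction
# ---------------------------------------------------------------------------

def extract_nodes(field: Field, n_nodes: int = 100, w: float = 0.5) -> list[Node]:
    """Greedy node extraction from one probe field.

    The first node is the global energy minimum; each further node maximizes

        score = w * |E|/|E_min|  +  (1 - w) * d_nearest_selected / d_box

    over the remaining negative-energy grid points, where ``d_box`` is the
    grid box diagonal.  Ties break to the lowest flat (C-order) grid index.
    Returns an empty list (no error) when the field has no favourable points.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    energies = field.energies.ravel()
    cand = np.flatnonzero(energies < 0.0)
    if cand.size == 0:
        import logging
        logging.getLogger(__name__).warning(
            "probe %s: no favourable grid points, empty node set", field.probe_id)
        return []
    points = field.grid.points()[cand]
    e = energies[cand]
    # rounded energies and integer grid offsets make scores (and hence the
    # stated tie-break) reproducible across equivalent molecule poses
    e_r = np.round(e, 9)
    intensity = np.round(e_r / e_r.min(), 9)  # |E|/|E_min|, energies < 0
    d_box = field.grid.diagonal
    idx = np.stack(np.unravel_index(cand, field.grid.shape), axis=1).astype(float)

    first = int(np.argmin(e_r))  # lowest flat index among ties
    selected = [first]
    available = np.ones(cand.size, dtype=bool)
    available[first] = False
    d2_nearest = ((idx - idx[first]) ** 2).sum(axis=1)

    while len(selected) < min(n_nodes, cand.size):
        spread = field.grid.spacing * np.sqrt(d2_nearest) / d_box
        score = np.where(available, w * intensity + (1.0 - w) * spread, -np.inf)
        pick = int(np.argmax(score))
        selected.append(pick)
        available[pick] = False
        d2_new = ((idx - idx[pick]) ** 2).sum(axis=1)
        np.minimum(d2_nearest, d2_new, out=d2_nearest)

    return [Node(points[i], float(e[i]), field.probe_id) for i in selected]


def extract_nodeset(fields: dict[str, Field], molecule_id: str,
                    n_nodes: int = 100, w: float = 0.5) -> NodeSet:
    nodes = {pid: extract_nodes(fields[pid], n_nodes, w) for pid in PROBES}
    return NodeSet(molecule_id=molecule_id, nodes=nodes, n_nodes=n_nodes, w=w)


# ---------------------------------------------------------------------------
# Correlogram encoding
# ---------------------------------------------------------------------------

def encode_correlogram(nodeset: NodeSet, bin_width: float = 0.4,
                       max_distance: float = 25.0) -> np.ndarray:
    """One descriptor-matrix row (all 10 blocks) for one molecule."""
    nb = n_bins(bin_width, max_distance)
    row = np.zeros(nb * len(BLOCKS))
    for b_idx, block in enumerate(BLOCKS):
        pa, pb = block.split("-")
        nodes_a = nodeset.nodes.get(pa, [])
        nodes_b = nodeset.nodes.get(pb, [])
        if not nodes_a or not nodes_b:
            continue
        xa = np.array([n.coords for n in nodes_a])
        ea = np.array([n.energy for n in nodes_a])
        xb = np.array([n.coords for n in nodes_b])
        eb = np.array([n.energy for n in nodes_b])
        d = cdist(xa, xb)
        prod = np.outer(ea, eb)
        if pa == pb:
            iu = np.triu_indices(len(nodes_a), k=1)
            d, prod = d[iu], prod[iu]
        else:
            d, prod = d.ravel(), prod.ravel()
        bins = np.floor(d / bin_width + _EPS).astype(int)
        ok = (bins >= 0) & (bins < nb)
        np.maximum.at(row, b_idx * nb + bins[ok], prod[ok])
    return row


@dataclass
class DescriptorMatrix:
    """Compounds x GRIND variables, with per-variable metadata."""

    ids: list[str]
    values: np.ndarray                 # (n_compounds, n_variables), >= 0
    meta: list[VariableMeta]
    bin_width: float = 0.4
    max_distance: float = 25.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.meta)):
            raise ValueError("descriptor matrix shape mismatch")
        if (self.values < 0).any():
            raise ValueError("descriptor values must be non-negative")

    @property
    def columns(self) -> list[str]:
        return [m.column for m in self.meta]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path, config_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, bin_width: float = 0.4,
                 max_distance: float = 25.0) -> "DescriptorMatrix":
        df = pd.read_csv(path, comment="#")
        ids = df["id"].astype(str).tolist()
        values = df.drop(columns="id").to_numpy(dtype=float)
        meta = []
        for k, col in enumerate(df.columns[1:], start=1):
            block, lo, hi = col.rsplit("_", 2)
            meta.append(VariableMeta(index=k, block=block,
                                     bin_low=float(lo), bin_high=float(hi)))
        return cls(ids, values, meta, bin_width, max_distance)

    def subset(self, variable_indices: np.ndarray) -> "DescriptorMatrix":
        """Column subset (e.g. after FFD selection); metadata kept."""
        idx = np.asarray(variable_indices, dtype=int)
        return DescriptorMatrix(self.ids, self.values[:, idx],
                                [self.meta[i] for i in idx],
                                self.bin_width, self.max_distance)

    def rows(self, ids: list[str]) -> np.ndarray:
        lookup = {cid: i for i, cid in enumerate(self.ids)}
        return self.values[[lookup[c] for c in ids]]


def encode_dataset(nodesets: list[NodeSet], bin_width: float = 0.4,
                   max_distance: float = 25.0) -> DescriptorMatrix:
    rows = [encode_correlogram(ns, bin_width, max_distance) for ns in nodesets]
    meta = all_variable_meta(bin_width, max_distance)
    return DescriptorMatrix([ns.molecule_id for ns in nodesets],
                            np.array(rows), meta, bin_width, max_distance)


def write_nodes_pdb(nodeset: NodeSet, path) -> None:
    """Export nodes as pseudo-atoms (PDB HETATM; B-factor = energy)."""
    with open(path, "w") as fh:
        serial = 1
        for pid in PROBES:
            for node in nodeset.nodes.get(pid, []):
                x, y, z = node.coords
                fh.write(
                    f"HETATM{serial:5d} {'X' + pid[:2]:<4s} NOD A{serial % 9999:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{node.energy:6.2f}\n")
                serial += 1
        fh.write("END\n")
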