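"""Probe/atom parameter handling (flat key=value text file)."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

PROBES = ("DRY", "O", "N1", "TIP")


@dataclass(frozen=True)
class ProbeParams:
    probe_id: str
    r0_delta: float           # added to atom vdW radius -> LJ minimum distance
    eps: float                # probe LJ well depth, kcal/mol
    charge: float             # probe partial charge, e
    hbond_depth: float        # Gaussian H-bond well depth, kcal/mol
    hbond_center: float       # donor-acceptor distance at the well center, A
    hbond_width: float        # Gaussian width, A
    hbond_partner: str        # "hba", "hbd" or "none"
    atom_r0: dict[str, float] = field(default_factory=dict)
    atom_eps: dict[str, float] = field(default_factory=dict)
    coulomb_constant: float = 332.0636
    dielectric_slope: float = 4.0
    distance_floor: float = 0.5
    energy_clamp: float = 5.0
    elec_cutoff_start: float = 12.0
    elec_cutoff_end: float = 18.0

    def __post_init__(self):
        if self.eps < 0 or self.hbond_depth < 0:
            raise ValueError("well depths must be >= 0")
        if any(r <= 0 for r in self.atom_r0.values()):
            raise ValueError("radii must be > 0")


def _parse_kv(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_probe_params(path=None) -> dict[str, ProbeParams]:
    """Load all four probes from a parameter file (package default if None)."""
    if path is None:
        text = resources.files("grindqsar.data").joinpath("probe_params.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    kv = _parse_kv(text)
    atom_r0 = {}
    atom_eps = {}
    for key, value in kv.items():
        if key.startswith("atom."):
            _, el, prop = key.split(".")
            if prop == "r0":
                atom_r0[el] = float(value)
            elif prop == "eps":
                atom_eps[el] = float(value)
    shared = dict(
        atom_r0=atom_r0,
        atom_eps=atom_eps,
        coulomb_constant=float(kv.get("coulomb_constant", 332.0636)),
        dielectric_slope=float(kv.get("dielectric_slope", 4.0)),
        distance_floor=float(kv.get("distance_floor", 0.5)),
        energy_clamp=float(kv.get("energy_clamp", 5.0)),
        elec_cutoff_start=float(kv.get("elec_cutoff_start", 12.0)),
        elec_cutoff_end=float(kv.get("elec_cutoff_end", 18.0)),
    )
    probes = {}
    for pid in PROBES:
        probes[pid] = ProbeParams(
            probe_id=pid,
            r0_delta=float(kv[f"probe.{pid}.r0_delta"]),
            eps=float(kv[f"probe.{pid}.eps"]),
            charge=float(kv[f"probe.{pid}.charge"]),
            hbond_depth=float(kv[f"probe.{pid}.hbond_depth"]),
            hbond_center=float(kv[f"probe.{pid}.hbond_center"]),
            hbond_width=float(kv[f"probe.{pid}.hbond_width"]),
            hbond_partner=kv[f"probe.{pid}.hbond_partner"],
            **shared,
        )
    return probes
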