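# Probe and atom parameters for the molecular-interaction-field engine.
# Flat key=value format.  Energies kcal/mol, distances Angstrom, charges e.
#
# Lennard-Jones 12-6 with Lorentz-Berthelot-style combination:
#   r0_ij = atom.r0 + probe.r0_delta ; eps_ij = sqrt(atom.eps * probe.eps)
# Electrostatics: 332.0636 * q_probe * q_atom / (eps_r(r) * r), eps_r(r)=4r.
# H-bond: single Gaussian well between complementary donor/acceptor pairs,
#   E = -depth * exp(-(r - center)^2 / (2*width^2)).

# per-element van der Waals radii (Bondi-like) and LJ well depths
atom.H.r0=1.20
atom.H.eps=0.020
atom.C.r0=1.70
atom.C.eps=0.070
atom.N.r0=1.55
atom.N.eps=0.070
atom.O.r0=1.52
atom.O.eps=0.060
atom.S.r0=1.80
atom.S.eps=0.100
atom.F.r0=1.47
atom.F.eps=0.060
atom.Cl.r0=1.75
atom.Cl.eps=0.150
atom.Br.r0=1.85
atom.Br.eps=0.200
atom.I.r0=1.98
atom.I.eps=0.250
atom.P.r0=1.80
atom.P.eps=0.200

coulomb_constant=332.0636
dielectric_slope=4.0
distance_floor=0.5
energy_clamp=5.0
# smooth switching range after which the electrostatic term is exactly zero
elec_cutoff_start=12.0
elec_cutoff_end=18.0

# DRY: neutral hydrophobic probe.  LJ attraction only with hydrophobic
# atoms (non-hydrophobic atoms contribute the repulsive r^-12 branch only).
probe.DRY.r0_delta=1.70
probe.DRY.eps=0.25
probe.DRY.charge=0.0
probe.DRY.hbond_depth=0.0
probe.DRY.hbond_center=2.9
probe.DRY.hbond_width=0.35
probe.DRY.hbond_partner=none

# O: carbonyl-oxygen probe (H-bond acceptor) - complements donor atoms.
probe.O.r0_delta=1.52
probe.O.eps=0.20
probe.O.charge=-0.25
probe.O.hbond_depth=4.0
probe.O.hbond_center=2.9
probe.O.hbond_width=0.35
probe.O.hbond_partner=hbd

# N1: amide-nitrogen probe (H-bond donor) - complements acceptor atoms.
probe.N1.r0_delta=1.55
probe.N1.eps=0.20
probe.N1.charge=0.25
probe.N1.hbond_depth=4.0
probe.N1.hbond_center=2.9
probe.N1.hbond_width=0.35
probe.N1.hbond_partner=hba

# TIP: molecular-shape probe; -1 on a one-voxel shell around the surface.
probe.TIP.r0_delta=0.0
probe.TIP.eps=0.0
probe.TIP.charge=0.0
probe.TIP.hbond_depth=0.0
probe.TIP.hbond_center=2.9
probe.TIP.hbond_width=0.35
probe.TIP.hbond_partner=none
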