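# Methods

This note documents the models and procedures implemented in `grindqsar`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Probe interaction fields

For the DRY, O and N1 probes the interaction energy at a grid point is a
pairwise-additive sum over atoms:

* **Lennard-Jones 12-6**: `eps_ij * ((r0_ij/r)^12 − 2 (r0_ij/r)^6)` with
  `r0_ij = r_vdw(element) + r0_delta(probe)` (Bondi-like radii) and
  `eps_ij = sqrt(eps_atom · eps_probe)`. The DRY probe keeps the attractive
  branch only against atoms typed hydrophobic (carbons not bonded to
  N/O/S), so DRY minima are genuine hydrophobic hot spots, e.g. above and
  below an aromatic ring face.
* **Electrostatics**: `332.0636 · q_p · q_a / (4r · r)` kcal/mol — a
  distance-dependent dielectric ε(r) = 4r — smoothly switched off between
  12 and 18 Å so the field is exactly zero far from the molecule. Atomic
  partial charges are Gasteiger (iterative electronegativity equalization,
  via RDKit); they sum to the net formal charge to 1e-6 by contract.
* **H-bond term**: a single Gaussian well,
  `−4.0 · exp(−(r − 2.9)² / (2·0.35²))` kcal/mol, applied between the O
  probe and donor atoms and between the N1 probe and acceptor atoms. The
  2.9 Å centre is the canonical donor–acceptor heavy-atom distance; the
  4 kcal/mol depth dominates the other terms near polar atoms so that O/N1
  hot spots sit where a complementary partner would.

Distances are floored at 0.5 Å and total energies clamped at +5 kcal/mol
inside atoms (only negative energies matter downstream). The TIP shape
probe is an indicator field: −1 on the one-voxel shell just outside the
van der Waals surface, 0 elsewhere. All constants live in
`src/grindqsar/data/probe_params.txt` (flat key=value); they are chosen for
qualitative probe semantics, not to reproduce any proprietary force field.

**Canonical grid frame.** The grid box is the bounding box (default margin
5 Å, default spacing 0.5 Å) in the molecule's principal-axes frame, with
axis signs fixed by the third moment of the atom projections. Every
downstream quantity depends only on distances, so rotating or translating
the input structure changes no descriptor — the package's
alignment-independence tests demand agreement to 1e-6 and observe ~1e-14.
Node selection additionally rounds energies to 1e-9 and measures node
spread in integer grid steps so that the greedy tie-break (lowest flat
grid index) is pose-independent rather than floating-point-noise driven.

## Nodes and GRIND correlograms

Per probe, up to `n_nodes` negative-energy grid points are selected
greedily: the global minimum first, then repeatedly the point maximizing
`w·|E|/|E_min| + (1−w)·d_nearest/d_box`. Defaults are n_nodes = 100 and
w = 0.5; the synthetic study uses 60 and 0.8 (below).

Descriptors follow the MACC2 transform: for each ordered probe-pair block
(DRY-DRY, O-O, N1-N1, TIP-TIP, DRY-O, DRY-N1, DRY-TIP, O-N1, O-TIP,
N1-TIP) and each distance bin of width 0.4 Å up to 25 Å (62 bins/block,
620 variables), the value is the maximum product `E_i · E_j` over node
pairs whose distance falls in the bin. Products of two negative energies
are positive; a zero means no pair at that distance. A dataset-consistent
("CLACC"-style) pair choice is not implemented: the per-molecule maximum
is the documented, testable transform, and every nonzero cell is auditable
as a product of two stored node energies.

The 0.4 Å bin width follows the distance ranges this kind of analysis
reports for individual variables (e.g. "DRY-N1: 13.2–13.6 Å"); a 0.8 Å
smoothing-window alternative is exposed through configuration but not the
default, since the two conventions disagree in the sources this package
draws on and 0.4 Å is the one the variable semantics require.

## Modelling pipeline

1. **Occupancy cutoff** (`min_nonzero_fraction`, default 0.25): descriptor
   columns nonzero in fewer than 25 % of training compounds are dropped
   before any selection. Such columns are near-indicator variables; under
   unit-variance scaling a held-out compound can sit tens of SDs from the
   training column and wreck cross-validation. This is the analogue of the
   minimum-SD cutoffs standard in GRIND modelling software.
2. **FFD variable selection**: a seeded, column-balanced two-level design
   (+1 keep / −1 drop) over the surviving variables plus 20 % dummy
   factors, folded over once so each factor is kept in exactly half of the
   runs. Each run's reduced model is scored by cross-validated SDEP
   (5 random groups, kernel PLS on X'X/X'y with covariance downdating —
   verified to reproduce NIPALS coefficients to 1e-10). The effect of a
   variable is mean SDEP(runs keeping it) − mean SDEP(runs dropping it);
   variables whose effect exceeds mean + 2·SD of the dummy effects are
   dropped (keeping them demonstrably worsens prediction).
3. **PLS**: single-y NIPALS with deflation; default column scaling is
   **pareto** (1/√SD). Autoscaling is available but not the default: on
   sparse correlogram matrices it inflates rare bins and destroys LOO Q²
   (observed Q² ≈ −40 on synthetic data); pareto preserves some magnitude
   information while taming the dominant blocks. The number of latent
   variables is chosen by maximizing LOO Q² over 1..a_max (default 5),
   ties to the smaller number, with a warning when even the best Q² ≤ 0.
   `loo_q2` is a literal refit loop — each fold recomputes centering,
   scaling and the whole NIPALS fit — so no deflation shortcut can change
   a held-out prediction.

## Validation statistics

Internal: `R² = Σ(ŷ−ȳ)²/Σ(y−ȳ)²`, `PRESS = Σ e(i)²` over LOO folds,
`Q² = 1 − PRESS/Σ(y−ȳ)²`, and `RMSEE = √(PRESS/n)`. RMSEE is defined here
from PRESS (a cross-validated error); because that convention is unusual,
the conventional fitted-residual RMSE is also reported as `rmse_fit`.

External: `R²pred = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)²`, `RMSEP = √(Σe²/n_test)`,
and the Roy rm² family on the Golbraikh–Tropsha through-origin regressions
(`k = Σyŷ/Σy²`, `k′ = Σyŷ/Σŷ²`, r0² and r0′² from the corresponding
origin-constrained fits): `rm² = r²(1 − √(r² − r0²))`, `rm²′` with the
axes swapped, their mean and absolute difference. The radicand is clamped
at zero (and logged) when r0² exceeds r² numerically. Because the axis
orientation of the (r² − r0′²)/r² criterion is ambiguous in the
literature, both orientations are computed and reported.

The model-acceptance checklist is: R² > 0.9, Q² > 0.5, R²pred > 0.6,
RMSEP ≤ 2·RMSEE, rm² > 0.5, rm²′ > 0.5, mean rm² > 0.5, Δrm² < 0.2,
(r² − r0′²)/r² < 0.1, 0.85 ≤ k′ ≤ 1.15 — all strict as written, and a
model is "valid" only if every flag passes.

**Applicability domain.** Leverage `h = 1/n + x_c'(X_c'X_c)⁺x_c` in the
selected-descriptor space against `h* = 3(p+1)/n`, plus the
|standardized residual| > 3 rule (residuals divided by training RMSEE —
the standardization convention is this package's own choice). The 1/n
intercept term can be switched off to obtain SPSS-style centered leverage.
Note that when the number of selected descriptors approaches or exceeds n
(common for GRIND matrices), h* ≥ 1 and the leverage criterion is vacuous;
`GrindPLSResults.williams(space="scores")` offers the usual PLS
alternative — leverage in the latent-variable space with p = number of
components.

## Synthetic data generator

The generator emulates a four-cluster congeneric series of ~49
ATP-competitive kinase-inhibitor-like molecules: a pyridine-type hinge
ring (H-bond acceptor nitrogen), an amide or ureido linker (donor N–H,
acceptor C=O), a variable-length spacer, and a phenyl head group
(optionally para-methylated), with the hinge-N-to-phenyl-centroid distance
drawn uniformly per cluster (10.0–16.4 Å across clusters I–IV; clusters II
and IV carry the ureido linker). Chain positions get 0.03 Å Gaussian
jitter and the phenyl ring a ±0.3 rad tilt; each molecule is placed in a
random rigid-body pose, which by construction must not (and does not)
affect its descriptors.

Activities are a noisy linear function of descriptors computed through the
*real* field→node→correlogram pipeline:
`pIC50 = a + s·Σ_k β_k x_k/SD(x_k) + ε`, ε ~ N(0, 0.2²), with seeded bins
DRY-N1 13.2–13.6 Å (β = +1 SD) and O-O 2.4–2.8 Å (β = −0.4 SD) and (a, s)
calibrated so the noiseless activities span 3.8–9.0 pIC50 units. Betas are
expressed per SD of the realized descriptor so the relative contribution
of each seeded bin is controlled regardless of raw energy-product scales.
Everything is reproducible from the seed: identical configurations yield
byte-identical SDF and CSV files.

**Desk-scale study conditions.** The recovery study (100 datasets, n = 49,
σ = 0.2) runs the encoding at 1.0 Å grid spacing with 60 nodes/probe and
intensity weight w = 0.8 — the package's chosen problem size for a
simulation study that must run end-to-end many times; the per-dataset
modelling leg uses pareto scaling, the 0.25 occupancy cutoff, FFD, and
a_max = 5. Under these conditions the full pipeline achieves Q² > 0.5 and
R² > 0.9, and ranks the seeded DRY-N1 variable among the top-5 favorable
coefficients, in well over 90 % of seeds; randomly permuting activities
drives the mean LOO Q² far below zero.

**What passing these tests does and does not show.** The generator gives
real geometry, real fields and a real, known structure–activity link, so
the tests demonstrate end-to-end correctness and identifiability of the
implementation. They do not demonstrate performance on real chemistry: the
scaffolds have deliberately stretched bond lengths to hit target
distances, activity cliffs, conformational flexibility, tautomery and
assay noise structure are absent, and descriptor–activity relations in
real datasets are weaker and more collinear than the seeded linear signal.

## Numerical choices and degenerate inputs

* Node-selection tie-breaks: lowest flat (C-order) grid index, made exact
  by energy rounding (1e-9) and integer-step distances.
* Distance bin edges: `floor(d/bw + 1e-9)`, half-open bins `[lo, hi)`.
* PLS rank exhaustion raises an error naming the achievable rank
  (deflation residual below 1e-10); constant y is rejected.
* Singular descriptor covariance in the leverage computation falls back to
  the pseudoinverse, logging the achieved rank.
* Fields with no negative energies yield an empty node list with a logged
  warning; the corresponding correlogram blocks are zero.
* Split construction assigns the activity minimum and maximum, and any
  singleton cluster, to training; test slots are allocated over
  cluster × activity-quintile cells by largest remainder, then patched so
  every multi-member cluster appears in both sets.

## Known limitations

* Probe energies are qualitative; no claim of matching any proprietary
  MIF implementation's numbers — only probe semantics and the statistical
  behaviour of the pipeline are reproduced, and variable numbering is this
  package's own deterministic scheme.
* The CLACC "consistent pair" encoding variant is not implemented.
* Pharmacophore typing is rule-based on the explicit-hydrogen graph;
  protonation/tautomer states are taken as given in the input file.
* FFD effects are main effects only (resolution III with fold-over);
  interactions between variables are not resolved.
* The applicability-domain leverage in descriptor space is vacuous when
  p ≥ n (use the scores-space option).
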