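# Methods

## The system and what the package models

Azobenzene-bearing ligands such as ATA-3 photo-isomerize about their central
C–N=N–C torsion: *trans* (φ ≈ 180°) is the dark-adapted agonist form for the
AMPA-type glutamate receptor iGluR2, *cis* (φ ≈ 0°) is produced by blue light
and is inactive. The receptor's clamshell-like ligand-binding domain (LBD)
responds to the isomer change slowly, over hundreds of nanoseconds, which is
why the photo-reaction itself can be replaced by a short classical bias
rather than excited-state electronic structure. This package implements that
protocol — a time-windowed harmonic dihedral "switching potential" inside a
classical dynamics engine — at desk scale on a toy azobenzene, together with
the full trajectory-analysis layer used to characterise the LBD response:
clamshell and gate distances, ligand-pose classification, monomer→dimer
projection of the linker separation, correlation analysis, and the
docking-pose acceptance filter. Protein-scale MD is out of scope; every
analysis operation is exercised on synthetic scaffolds that realize requested
order-parameter values exactly.

## Toy azobenzene and ground-state force field

Two variants: `minimal` (4 atoms, C–N=N–C) and `phenyl` (the core plus two
rigid 6-site rings of aggregated-CH sites, 16 atoms, with a single repulsive
ring–ring r⁻¹² term standing in for steric bulk). Terms: harmonic bonds
(k_b = 2·10⁵ kJ·mol⁻¹·nm⁻², r₀ = 0.142 nm C–N, 0.125 nm N=N), harmonic
angles (k_a = 500 kJ·mol⁻¹·rad⁻², θ₀ = 113°), and the central torsion

    V(φ) = (B/2)(1 − cos 2φ),   B = 100 kJ/mol (configurable),

a double well with minima at 0° (cis) and 180° (trans). B is not a published
number — the published ground-state surface is only schematic — so it is a
package choice: large enough that thermal crossing at 300 K is unobservable
on the tens-of-picoseconds timescales simulated here (measured: 0/20
replicates cross in 50 ps with the switch disabled), small enough that the
switching bias dwarfs it. Units are nm, kJ/mol, amu, ps internally; angles
are degrees at every public interface. The dihedral sign convention is the
standard IUPAC one (signed torsion in (−180°, 180°], anti = 180°).

Forces are analytic (the torsion gradient uses the two-plane-normal form)
and are validated against central finite differences to a relative error
below 10⁻⁵ on hundreds of random geometries; energies are validated against
an independent per-term evaluator; both are exactly invariant under rigid
rotation and translation.

## Switching potential

The forced isomerization applies

    V_sw(φ) = k · wrap(φ − φ_target)²

for a rectangular time window of 500 fs (no ramp), with φ_target = 0° for
trans→cis and 180° for cis→trans, k = 320.

**Units of k.** The source literature prints the force constant as
"320 kJ/mol deg²". Taken literally, activating that potential on a trans
geometry (Δφ = 180°) deposits k·180² ≈ 1.0·10⁷ kJ/mol into one torsion. A
Langevin bath at friction γ = 10 ps⁻¹ removes only a factor e^(−γt) ≈ e⁻⁵
of an underdamped oscillator's energy within the 500 fs window, leaving
~10⁴–10⁵ kJ/mol — two to three orders of magnitude above the 100 kJ/mol
ground-state barrier — so after switch-off the molecule free-rotates and its
final basin is a coin flip. We measured exactly that: with degree units,
0 of 9 replicates hold cis through a 50 ps follow-up. With the deviation
measured in radians (k = 320 kJ·mol⁻¹·rad⁻², ≈ 3.2·10³ kJ/mol deposited),
first passage into the cis basin takes ≈ 10 fs and all replicates hold the
new isomer indefinitely — the behaviour the protocol is documented to have
(switching completed well within the window, the new configuration
maintained after the bias is removed, fully reversible). The package
therefore defaults to `angle_unit="rad"` and treats the printed unit as a
misprint; `angle_unit="deg"` is available for the literal form. This is the
package's single substantive deviation from its sources and is flagged
prominently here and in the module docstring.

**No ½ factor.** The bias is k·Δφ², not ½k·Δφ²; with k this large relative
to both kT (≈ 2.5 kJ/mol) and the barrier, a factor 2 does not change any
qualitative outcome.

## Integrator

BAOAB Langevin (velocity Verlet with an Ornstein–Uhlenbeck velocity step),
dt = 0.5 fs during the switch window, temperature 300 K, friction 10 ps⁻¹.
With friction 0 the O-step is the identity and the scheme is plain velocity
Verlet; total-energy drift then scales as O(dt²) (measured ratio ≈ 4 when dt
is halved). The bias curvature (2k in rad² units, ≈ 640 kJ·mol⁻¹·rad⁻²;
≈ 2.1·10⁶ in the literal degree form) can exceed what 0.5 fs resolves, so
steps overlapping the switch window are automatically subdivided
(multiple-timestep integration) until the bias frequency satisfies
ω·dt_inner < 0.2. Unbiased phases (thermalization, follow-up) run at 2 fs,
which resolves the stiffest bond mode (ω ≈ 180 rad/ps, ω·dt ≈ 0.36).
Kinetic temperature uses 3N degrees of freedom (the Langevin bath conserves
neither momentum nor angular momentum). The kinetic-temperature estimator
carries the usual O(dt²) velocity-Verlet discretization bias (≈ −1.5% at
2 fs, ≈ −0.1% at 0.5 fs), which is why the quantitative 3-standard-error
temperature check runs at the protocol timestep.

A replicated switch experiment is: steepest-descent minimization →
thermalization in the start basin (5 ps) → 500 fs switch window (recorded
every step, so first-passage resolution is one timestep) → unbiased
follow-up (50 ps, recorded every 10 fs). *Success* means the target basin
(boundary at |φ| = 90°) is reached during the window **and** occupied at
every recorded follow-up frame. Replicate seeds are the caller's seed plus
the replicate index; every stochastic path is bit-reproducible given its
seed.

## Order parameters and classifiers

All distances are mass-weighted centre-of-mass (COM) separations in nm,
computed per frame and exactly invariant under rigid motion:

| metric | definition | thresholds |
|---|---|---|
| clamshell | COM(residue 451) – COM(residue 651) | none (reported raw; ~0.7 nm bound, ~1.1 nm opening) |
| gate | COM(E402 carboxylate: CD, OE1, OE2) – COM(T686 hydroxyl: OG1 [+HG1 if present]) | closed < 0.65 nm ≤ open |
| pocket | COM(azobenzene moiety) – COM(residues 403, 404, 405, 707, 711, 712) | position1 < 0.60 ≤ intermediate < 0.90 ≤ position2 |
| helix | backbone COM of helix H range – helix B range | ranges **must** be configured; no default exists |

The gate threshold 0.65 nm is the midpoint of the closed (0.55 nm) and open
(0.8 nm) population readings; the pose bounds (0.60, 0.90) bracket the
intermediate (≈0.75 nm) and position-2 (≈1.05 nm) readings, the lower bound
being a convention since no position-1 distance is published. "Functional
group" atom subsets (carboxylate/hydroxyl) and the azobenzene atom list are
configurable; defaults use heavy atoms, since hydrogens are often absent.
Boundaries classify upward (open / the more dissociated state) — a bare
convention, exercised in tests.

Transitions are state changes that persist for at least `min_dwell` frames
(default 10); single-frame noise spikes are debounced. The events of
interest dwell for hundreds of frames, so the default is conservative.

## Dimer projection

Only the monomer is simulated; channel opening is inferred by projection:
per frame, the reference dimer's chain-A domain-1 backbone is superposed
onto the trajectory monomer's domain 1 (Kabsch, SVD with the determinant
sign fixed to exclude reflections), the transform is applied to chain B, and
the series reports |COM(P632, monomer) − COM(P632, transformed chain B)|.
A trajectory identical to the reference monomer reproduces the reference
dimer's own linker distance exactly at every frame. Squared Pearson
correlations between series pairs use `scipy.stats.pearsonr`.

## Docking-pose filter

A pose is accepted iff (a) its COM lies within 1.2 nm of the COM of the
binding-site residues and (b) at least one ligand polar atom (N or O) lies
within 0.35 nm (inclusive) of a polar atom of one anchor: the R485 side
chain (NE, NH1, NH2), the E705 carboxylate (OE1, OE2), or the S654/T655
backbones (N, O). This heavy-atom distance criterion is a deliberate proxy
for a hydrogen bond with no angular term, appropriate for docking outputs
without hydrogens; the cutoff and subsets are configurable. Re-docking RMSD
is computed over heavy atoms in the common receptor frame (no
re-superposition), reported in Å, with optional symmetry-equivalent atom
mappings minimised over.

## Synthetic data: what it does and does not show

The toy LBD scaffold is a geometric fixture, not a protein: each order
parameter involves a disjoint residue cluster placed in its own region of
space, so every requested distance is realized exactly (≤ 10⁻⁹ nm; ≤ 10⁻⁴ nm
after a PDB round-trip, which is format precision and stays inside every
classifier band). Planted events move one controlled unit along the
inter-COM axis as a step function, with isotropic Gaussian coordinate noise
added afterwards so expected series values equal planted values. Correlated
series are exact bivariate normals. Pose sets are constructed with ≥ 0.02 nm
margins around the 0.35 nm cutoff so PDB-precision loss cannot flip a
verdict. Passing tests therefore demonstrate the *correctness of the
measurement and classification machinery*, not the realism of protein
conformational ensembles: nothing here generates physically plausible LBD
dynamics, and the published protein-scale observations (hundreds-of-ns
responses, the R² = 0.916/0.11 contrast between crystallographic and
photo-switching ensembles) are emulation targets for the generators, not
reproduced physics.

## Numerical choices and degenerate inputs

- Dihedral and angle gradients guard against collinear geometry (explicit
  degenerate-geometry errors; sin θ clamped at 10⁻⁸ in angle forces).
- Kabsch superposition requires ≥ 3 atoms and non-collinear references;
  rank-deficient inputs raise rather than return an arbitrary rotation.
- PDB residue numbering is the file's author numbering, verbatim; alternate
  locations keep the highest-occupancy conformer (tie → first encountered).
- Å↔nm conversion is an exact ×10/÷10; internal coordinates are always nm.
- Problem sizes in tests and drivers (9–50 replicates, 50 ps follow-ups,
  1 ns thermostat checks, 10⁴-point correlation series) are chosen as the
  smallest sizes at which each claim is statistically decidable.

## Known limitations

- The toy model is vacuum, chargeless and unconstrained; nothing here
  approximates solvated-protein kinetics.
- The rectangular switch window is one reading of "activated for 500 fs";
  a ramped activation would deposit less energy still, and is not modelled.
- Helix H/B and domain-1 residue ranges are user configuration by design;
  the scaffold's ranges (721–728, 741–748, 400–460) are fixture conventions.
- The pose filter has no hydrogen-bond angle term and no scoring; it only
  reproduces the published discard rules.
- The published flexible-side-chain set F1 lists "R405", presumably a typo
  for the anchor R485 named elsewhere; the filter uses R485. The F1/F2 set
  definitions are recorded here only and are not modelled.
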