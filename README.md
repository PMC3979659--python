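# azogate

Forced azobenzene photo-isomerization in a toy Langevin engine, with the
trajectory-analysis layer used to study how a photo-switchable ligand
controls the ligand-binding domain (LBD) of the AMPA-type glutamate receptor
iGluR2, and the docking-pose acceptance filter that selects credible ligand
placements.

## Who this is for, and the science in brief

Azobenzene-bearing ligands (e.g. ATA-3) are agonists in their dark-adapted
*trans* form (central C–N=N–C torsion φ ≈ 180°) and lose activity after
photo-isomerization to *cis* (φ ≈ 0°). Because the receptor's response
unfolds over timescales far longer than the femtosecond photo-reaction, the
photo-reaction can be replaced inside classical dynamics by a brief
**switching potential**

    V_sw(φ) = k · wrap(φ − φ_target)²,    k = 320 kJ·mol⁻¹·rad⁻²,

activated as a rectangular 500 fs window — a harmonic stand-in for the
excited-state surface that drags the torsion into the target basin (see
`docs/methods.md` for why k is interpreted per radian²). The package
provides:

- **toy_system** — a minimal (4-atom) or phenyl-ring (16-atom) azobenzene
  with harmonic bonds/angles and the ground-state double well
  V(φ) = (B/2)(1 − cos 2φ), B = 100 kJ/mol; analytic forces.
- **switch_dynamics** — BAOAB Langevin dynamics (300 K, friction 10 ps⁻¹,
  dt = 0.5 fs during the switch window with automatic substepping of the
  stiff bias), the switching potential, cis/trans classification,
  first-passage times, and replicated switch experiments.
- **structure_io** — a strict fixed-column PDB subset (Å↔nm at the
  boundary), a plain-text trajectory format, residue/atom selections.
- **traj_metrics** — the LBD order parameters: G451–S651 clamshell
  distance, the T686–E402 "gate" (functional-group COM distance, closed
  < 0.65 nm ≤ open), the azobenzene–pocket distance with
  position-1/intermediate/position-2 classification, helix–helix distances,
  Kabsch superposition, monomer→dimer projection of the P632–P632 linker
  separation (ion-channel opening proxy), squared Pearson correlations, and
  debounced transition detection.
- **pose_filter** — accept a docked pose iff it lies inside the binding
  site *and* makes a polar contact (≤ 0.35 nm) with an anchor (R485, E705
  side chains; S654/T655 backbones); re-docking ligand RMSD in Å.
- **synthetic_data** — toy LBD scaffolds that realize requested
  order-parameter values exactly, trajectories with planted step events and
  Gaussian noise, series pairs with planted correlation, labelled pose sets.
- **cli** — `azogate simulate | analyze | experiment | synth | filter-poses`
  over YAML configs with strict key checking and reproducible manifests.

## Worked example

Run the numbered analyses (each writes tables under `results/`):

```
$ python analysis/01_forced_switching.py
forward: 9/9 replicates switched and held the target isomer through the follow-up; median first passage 10.0 fs (min 9.0, max 10.5)
reverse: 9/9 replicates switched and held the target isomer through the follow-up; median first passage 9.0 fs (min 8.5, max 10.0)
conclusion: the 500 fs switching window is sufficient in both directions and the new isomer persists unbiased.
```

Nine independent replicates reach the cis basin ~10 fs after the switch is
activated — far inside the 500 fs window — and every one of them is still
cis at every recorded frame of a 50 ps unbiased follow-up; the reverse
(cis→trans) switch behaves symmetrically, i.e. the protocol is reversible.

```
$ python analysis/02_order_parameters.py
gate: closed -> open at frame 400
pocket: position1 -> position2 at frame 700
conclusion: both planted events recovered at the planted frames.

$ python analysis/03_channel_projection.py
projected linker distance: 2.500 nm at rest, 2.010 nm after the planted drift
planted r^2 = 0.916: measured 0.9178 (n = 10^4)
planted r^2 = 0.11: measured 0.1191 (n = 10^4)
conclusion: correlation estimates recover the planted couplings.

$ python analysis/04_pose_filter.py
filter: 5/15 poses accepted, 0 label mismatches
re-docking RMSD between the two best synthetic placements: 0.23 A (receptor frame, no re-superposition)
conclusion: accept/reject labels recovered with zero confusion.
```

The gate-opening event planted at frame 400 (0.55 → 0.80 nm) and the pose
transition at frame 700 (0.45 → 1.05 nm) are recovered exactly despite
coordinate noise; the dimer projection reproduces the reference linker
separation at rest; correlation estimates at n = 10⁴ recover planted
couplings within sampling error; and the pose filter reproduces all 15
construction labels.

The same machinery is available from the shell, e.g.:

```
azogate synth --seed 4 --out-dir synth_out            # writes scaffold.pdb
azogate simulate --seed 2 --out-dir sim_out           # switch + dihedral series
azogate experiment --seed 0 --out-dir exp_out         # replicated study
```

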