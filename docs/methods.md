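# Methods

## Scope and model

`ffbalance` operates on the GROMACS topology dialect and treats a force
field as data: the Lennard-Jones types (σ in nm, ε in kJ/mol), the
per-type-pair `[ nonbond_params ]` overrides, per-molecule atoms with
charges (e) and masses (amu), and periodic proper dihedrals with energy
k·(1 + cos(nφ − δ)). The parser covers the sections the refinement
workflow touches (`defaults`, `atomtypes`, `nonbond_params`,
`moleculetype`/`atoms`/`bonds`/`pairs`/`angles`/`dihedrals`, `system`,
`molecules`); any other section — settles, exclusions, virtual sites,
position restraints, `dihedraltypes` — is preserved verbatim so a
parse → transform → write cycle never drops content it does not model.
Indices stay 1-based throughout, as in the dialect. `#include` is
expanded by literal inlining of the referenced file. If the
`[ defaults ]` directive is absent, Lorentz–Berthelot combination
(arithmetic σ, geometric ε) is assumed, the convention of this
force-field family; comb-rule 3 selects geometric σ as well.

## Protein–water LJ scaling

The scaling schemes multiply the combined ε of protein-atom/water-oxygen
pairs by γ. Choices that were genuinely open and how they were fixed:

- **Realization by atom-type cloning.** The dialect expresses pair
  overrides per type pair, not per atom, so selectivity requires that
  targeted atoms have types of their own. Any type shared between
  targeted and untargeted atoms is cloned (suffix `_ws`, configurable;
  name collisions are an error) with identical σ/ε/mass/charge, the
  targeted atoms are re-typed, and one override per now-exclusive type
  is emitted. Untargeted interactions are therefore bitwise unchanged.
- **Water oxygen only.** In the four-site water model this force-field
  lineage uses, hydrogens and the charge-carrying virtual site have no
  LJ, so overrides against the oxygen type fully determine the
  protein–water dispersion. The oxygen type is auto-detected as the
  LJ-carrying O atom of a water moleculetype, or given explicitly.
- **Atom classes.** Backbone = {N, amide H, CA, HA (HA2/HA3 for Gly),
  C, O, terminal OXT/H1–H3}; everything else in a protein residue is
  sidechain; ACE/NME caps follow the backbone rule. Backbone scaling
  uses heavy atoms only; sidechain scaling includes sidechain
  hydrogens. Glycine has no sidechain and is never selected by the
  sidechain schemes.
- **Charged residues** (excluded by the `sidechain-uncharged` scheme)
  default to ASP, GLU, LYS, ARG plus the ionized variant names
  HIP/HSP, CYM and TYM when a file uses them; neutral His tautomers
  (HID/HIE/HSD/HSE) count as uncharged. The exclusion covers only the
  residue's sidechain atoms — charged *terminal* backbone groups follow
  the backbone rule. The set is configurable.
- Unrecognized residues classify as OTHER with a warning and are never
  scaled silently.

Hydrogen mass repartitioning reads "repartition to m amu" as the target
hydrogen mass (default 1.5 amu), subtracting the difference from the
unique bonded heavy atom; a hydrogen bonded to zero or multiple heavy
atoms, or a heavy atom driven non-positive, is a hard error. Water is
untouched. Total molecular mass is conserved by construction.

## ψ-torsion refinement

ψ dihedrals are located by atom names across consecutive residues
(N(i)–CA(i)–C(i)–N(i+1)), independent of term order in the file;
residue matching goes through residue names with an alias table for
protonation variants, because base atom types are shared across residue
types. Only the multiplicity-1 periodic term on a matched quadruple is
rewritten — the base files are expected to carry such a correction
term, and its absence is a hard error rather than a silent insertion.
Phase and multiplicity are read from the base topology and preserved:
the refinement is purely a force-constant change, so
V_new(ψ) − V_old(ψ) = Δk·(1 + cos(ψ − δ)) exactly, which the tests
verify against the energy oracle on arbitrary configurations. The
transformation is idempotent.

## Energy oracle

The oracle computes cutoff-free single-point energies: direct double-sum
12-6 LJ and Coulomb (k_e = 138.935458 kJ·mol⁻¹·nm·e⁻²), plus periodic
proper dihedrals. Intramolecular exclusions are derived from the bond
graph out to `nrexcl` bonds; `[ pairs ]` entries are re-added scaled by
fudgeLJ/fudgeQQ from `[ defaults ]`. There are no periodic boundary
conditions, cutoffs or reciprocal-space electrostatics: the oracle
exists to verify that a transformation changed exactly the interactions
it claims to change (ratios, deltas, invariances), not to reproduce
simulation-engine energies. Interacting atoms closer than 1e-6 nm are
an error.

## Observables

- **R_g**: mass-weighted RMS distance from the center of mass.
- **RMSD/RMSF**: Kabsch SVD superposition restricted to proper
  rotations (det = +1); RMSF is measured about the mean structure after
  two alignment passes (first frame, then the running mean). Collinear
  selections are rejected.
- **SAXS**: vacuum Debye double sum
  I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ), with the q→0 and i=j limits
  handled analytically via the sinc function. Form factors are
  constant, per-atom, or per-element q→0 electron counts; hydration
  shell and excluded-volume corrections (as applied by
  experiment-oriented predictors) are deliberately absent and must be
  treated as a systematic difference when comparing to measured curves.
- **Guinier fit**: linear fit of ln I vs q², R_g = √(−3·slope). The
  window is iterated to self-consistency with q·R_g ≤ 1.3 by default
  (the conventional limit for globular scatterers); the window actually
  used is reported. For compact scatterers the fit recovers the direct
  moment within ~3% at q·R_g ≤ 1; strongly elongated single
  conformations (e.g. one random-coil snapshot) can deviate slightly
  more, a property of the Guinier expansion itself.
- **DSSP**: Kabsch–Sander hydrogen-bond energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the
  −0.5 kcal/mol cutoff; the amide H is taken from the input when
  present, otherwise placed 0.1 nm from N along the preceding C=O
  direction. Two consecutive 4-turns define α-helix (H); bridges define
  E; 3₁₀ (G) and π (I) are assigned with standard priorities and
  reported separately — 3₁₀ counts toward "helix fraction" only on
  request. Against an independent reference implementation (mdtraj's
  DSSP) the assignments agree exactly on the generated ideal-helix and
  extended fixtures.
- **Secondary shifts**: per residue
  (Cα_obs − Cα_coil) − (Cβ_obs − Cβ_coil), positive = helical. Random
  coil values are user-supplied input; glycine (no Cβ) contributes its
  Cα secondary shift alone and is flagged. Tables are aligned on
  residue index with hard errors listing mismatched rows.
- **iRED S²**: the M×M matrix of time-averaged P₂(ûᵢ·ûⱼ) over N–H unit
  vectors is eigendecomposed; the five largest-eigenvalue modes carry
  overall reorientation, and S²ᵢ = 1 − Σ_internal λ_m|m_i|² (clipped to
  [0, 1]). This reproduces the degenerate limits exactly: rigid
  tumbling gives S² = 1 (the matrix has rank ≤ 5), uncorrelated vectors
  give S² ≈ 5/M, and a single repeated frame of identical vectors gives
  S² = 1. Fewer than 6 residues trigger a warning since the 5-mode
  separation is then ill-defined. Optional contiguous block averaging
  reports mean ± sd across blocks. Note that for independent
  per-residue wobble the iRED estimate exceeds the single-vector
  closed form by about (5/M)(1 − S²) — the projection of each residue
  onto the five reorientational modes — so closed-form comparisons use
  M = 50 vectors, where the bias is within 0.05 for cone semi-angles up
  to 30°.
- **Agreement statistic**: √(Σ(x_sim − x_exp)²/N) over matched labels.

## Synthetic data

The generators make every operation testable offline and define the
conditions the tests run under:

- **Toy topologies** carry full PDB-v3 atom naming for all twenty
  residues (hydrogens included), generic per-element LJ types, charges
  that sum exactly to each residue's formal charge, bonds/angles/1-4
  pairs derived from real connectivity, a multiplicity-1 ψ correction
  at the base 2.0 kJ/mol on every non-C-terminal residue plus
  untouched n=3 ψ and φ terms, and a four-site water with LJ on oxygen
  only. Parameters are deliberately *generic*, not published
  force-field values: tests assert relations (ratios, deltas,
  conservation laws), never absolute energies, so nothing here
  redistributes a real parameter set — real topology files remain
  first-class inputs.
- **Ideal geometries**: backbone chains grown in internal coordinates
  (NeRF) at (φ, ψ) = (−57°, −47°) or (180°, 180°) with ideal bond
  lengths/angles; measured torsions agree with targets to < 1°.
- **Gaussian chains**: freely jointed, ⟨R_g²⟩ = n·b²/6 asymptotically;
  default bond length 0.38 nm (Cα–Cα spacing).
- **Tumbling/wobble ensembles**: Haar-uniform global rotations from
  normalized random quaternions; wobble draws each vector uniformly
  within a cone about its mean (the equilibrium distribution of cone
  diffusion, closed form S = cos θ(1 + cos θ)/2) before the global
  rotation. All generators are bitwise deterministic under a fixed
  seed.

What the fixtures do *not* emulate: real force-field parameter values,
solvent structure, thermal ensembles from actual dynamics, or
experimental noise in shift tables. Passing tests therefore demonstrate
correctness of the transformations and estimators, not simulation
accuracy for real proteins.

## Problem sizes and numerics

The suite runs on peptides of 2–15 residues, 10⁴-frame vector ensembles
for iRED (10–50 residues), 300–500-point scattering curves, and
10⁵-point Monte-Carlo moment checks — sizes chosen so the whole suite
completes in about a minute while keeping stochastic assertions several
standard errors away from their thresholds. Floats are written with 12
significant digits, making parse → write round trips semantically exact
at the 1e-9 comparison tolerance. Topology transformations always
deep-copy their input; outputs are written atomically (temp file +
rename).

## Known limitations

- The energy oracle is a verifier, not a simulator (no PBC/PME/cutoffs).
- The topology writer normalizes formatting and section order;
  round-trip identity is semantic, not byte-for-byte of arbitrary
  third-party files.
- DSSP here covers H/G/I/E/C; bends and turns (S/T classes) are folded
  into coil, which does not affect helix fractions.
- SAXS form factors are q-independent (q→0 electron counts), adequate
  for the small-angle regime the Guinier analysis uses but not for
  wide-angle curves.
- `dihedraltypes`-based (unparameterized) dihedral lines pass through
  verbatim but cannot be refined; the ψ refinement requires explicit
  per-term parameters, as in the files this workflow targets.
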