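# ffbalance

Tools for refining the protein–water balance of an additive force field
at the topology level, together with the observables used to judge such
refinements.

Standard fixed-charge force fields paired with modern water models tend
to produce over-compact disordered ensembles and, once protein–water
attraction is strengthened to fix that, destabilized folded proteins and
residue-specific secondary-structure biases. `ffbalance` implements the
two parameter-level corrections for this trade-off as verifiable
transformations of GROMACS-dialect topology files:

1. **Selective protein–water Lennard-Jones scaling.** The combined well
   depth of protein-atom/water-oxygen pairs is multiplied by a factor
   γ (default 1.10, i.e. "10% stronger" hydration) for a selectable
   subset of atoms: all protein atoms, backbone heavy atoms only,
   sidechain atoms (glycine has none), or sidechains of uncharged
   residues only. Selectivity is realized by atom-type cloning plus
   `[ nonbond_params ]` pair overrides against the water oxygen, so for
   a targeted type T,

       ε(T, OW) = γ · √(ε_T · ε_OW),   σ(T, OW) = (σ_T + σ_OW)/2,

   and nothing else in the topology changes.
2. **Residue-specific ψ-torsion refinement.** The multiplicity-1
   correction term on the backbone ψ dihedral N(i)–CA(i)–C(i)–N(i+1),
   with energy k·(1 + cos(ψ − δ)), has its force constant rewritten per
   residue type: the STQ preset takes serine, threonine and glutamine
   from the base 2.0 kJ/mol to 1.0 kJ/mol; the STQ′ preset keeps S/T at
   1.0 kJ/mol but sets glutamine to the intermediate 1.5 kJ/mol, which
   balances helicity in polyglutamine stretches.

A third utility, hydrogen mass repartitioning, sets protein hydrogen
masses to a target (default 1.5 amu), moving the difference onto the
bonded heavy atom so each molecule's total mass is conserved exactly.

Every transformation is checked by a cutoff-free single-point **energy
oracle** (LJ + Coulomb + proper dihedrals, exclusions from the bonded
lists), and the package ships the **validation observables** such
refinements are judged by: radius of gyration, Kabsch RMSD/RMSF, vacuum
Debye SAXS curves with Guinier R_g fits, DSSP (Kabsch–Sander) helicity,
secondary chemical-shift differences ΔδCα − ΔδCβ, iRED S² order
parameters, and the agreement statistic √(Σ(x_sim − x_exp)²/N).

## Worked example

Generate a toy (AAQAA)-peptide topology, apply the STQ′ preset, and
scale uncharged-sidechain hydration by 10%:

```bash
ffbalance fixtures --make topology --sequence AAQAA --out toy.top
ffbalance refine-psi --preset stq-prime --in toy.top --out toy_stqp.top
ffbalance scale --scheme sidechain-uncharged --gamma 1.10 --in toy.top --out toy_sc.top
```

The refinement summary reports exactly one modified torsion — the ψ
term of the single non-terminal glutamine — rewritten from the base
2.0 kJ/mol to 1.5 kJ/mol:

```json
{
  "command": "refine-psi",
  "k_map": { "SER": 1.0, "THR": 1.0, "GLN": 1.5 },
  "modified_torsions": [
    { "molecule": "Protein", "residue": "GLN3", "k_old": 2.0, "k_new": 1.5 }
  ],
  "n_modified": 1,
  "output": "toy_stqp.top"
}
```

and the scaling step clones the four atom types shared between targeted
and untargeted atoms and writes one override per cloned type against
the water oxygen:

```json
{ "cloned_types": ["Cg_ws", "Hg_ws", "Ng_ws", "Og_ws"], "overrides_written": 4 }
```

`ffbalance check-energy --top A.top --top2 B.top --pdb conf.pdb` prints
per-term energy deltas between two topologies on one configuration;
`ffbalance analyze {rg,rmsd,rmsf,saxs,guinier,helix,shifts,ired,agreement}`
computes the observables from PDB/XYZ trajectories and TSV shift tables.

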