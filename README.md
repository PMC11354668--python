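# fcscreen

Virtual-screening analysis of single-stranded DNA functional ligands against
the Fc segment of an IgG antibody, plus 1:1 biolayer-interferometry (BLI)
kinetics.

The package post-processes rigid-docking poses of antibody–ssDNA complexes
and analyzes the binding interface:

- **`fcscreen.structure`** — PDB parsing into typed chains (protein / ssDNA
  ligand / glycan), author-numbered antibody region annotation
  (VH/CH1/CH2/CH3/VL/CL/hinge/glycan) from a user-overridable YAML region map.
- **`fcscreen.interface`** — heavy-atom contact detection at configurable
  cutoffs (default 4.5 Å, admissible band 3–6 Å; optional per-class map),
  per-site binding frequencies over a complex ensemble, and interface
  composition shares.
- **`fcscreen.propensity`** — base × structural-unit contact propensity
  `P_ij = (N_ij / Σ_j N_ij) / (T_j / Σ_j T_j)` with P ⋛ 1 classification,
  and per-family interface presence shares.
- **`fcscreen.screening`** — binding-mode classification (FAB / MODE1 =
  fully Fc-bound / MODE2 = hinge-touching / MODE3 = majority-Fc), Fc-binder
  filtering and score ranking, and before/after mutation comparison reports.
  Docking scores are consumed from a pose table, never computed.
- **`fcscreen.kinetics`** — closed-form 1:1 Langmuir association/dissociation
  curves, global (shared-parameter) nonlinear least-squares fitting across a
  concentration series, `K_D = k_dis / k_on`, pooled R², the ≥ 0.02 nm
  binding call, and the competition-assay decision rule.  The published
  per-ligand kinetic constants ship as package data
  (`fcscreen/data/affinity_constants.tsv`).
- **`fcscreen.synth`** — deterministic generators for every input: toy
  complexes with planted contacts/modes (unambiguous ground truth by
  construction), pose-score tables, and noisy sensorgrams with known
  kinetic truth.

## CLI

```bash
# generate a synthetic docked ensemble (PDBs + pose table + planted truth)
fcscreen simulate complexes --n 140 --seed 1 --out work/sim

# run interface analysis, mode classification, frequencies, propensities
fcscreen screen --complexes work/sim/complexes --poses work/sim/poses.tsv \
    --out work/report        # add --regions my_regions.yaml to override

# generate and fit sensorgrams
fcscreen simulate sensorgrams --seed 2 --out work/grams
fcscreen kinetics --sensorgrams work/grams --out work/kin
```

`screen` writes `screening.tsv`, `frequency.tsv`, `composition.tsv`,
`propensity.tsv` and `summary.json`; `kinetics` writes one row per ligand
with k_on, k_dis, K_D, R² and the binding call (`No response` rows for
ligands below the 0.02 nm signal threshold at the top concentration).

Sensorgram CSVs use columns
`step_index, phase, concentration_mg_ml, time_s, response_nm`; pose tables
are TSV with `ligand_id, pose_rank, zdock_score`.

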