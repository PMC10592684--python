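# cageforge

Fragment-based design toolkit for two-component tetrahedral protein cages
(T:{C3}{C3} architecture: two distinct C3 trimers, twelve copies of each
chain). The package covers the computational pipeline from rigid-body
fragment docking through amino-acid profile construction to interface
metrics and weighted pose selection, plus a synthetic-fixtures module that
generates parametric trimers, planted fragment databases and docking
scenarios with known ground truth.

## Modules

| module | contents |
| --- | --- |
| `cageforge.structure` | atom/residue/chain data model, PDB read/write |
| `cageforge.geometry` | rigid transforms, Kabsch superposition, LDDT, 6-D transform hashing, C-beta neighbor queries |
| `cageforge.symmetry` | point groups (C3, T), asymmetric-unit expansion |
| `cageforge.fragdb` | fragment-pair clustering, per-position amino-acid frequencies and interaction weights, TSV-backed database |
| `cageforge.fragments` | fragment typing, ghost-fragment generation, observation matching, continuous-ghost filtering, normalized pose score (bounded by 2) |
| `cageforge.docking` | 4-DOF grid enumeration, overlap search, transform-hash pose clustering, local grid optimization (5% relative-improvement stop) |
| `cageforge.profiles` | fragment / evolutionary (.hhm) / tertiary-blend profiles (max fragment weight 0.5), cross-entropy, profile losses, sequence accounting |
| `cageforge.metrics` | Shrake-Rupley SASA, buried surface area with polar/apolar split, core/rim/support classes, composition similarity, secondary structure, hydrogen bonds, buried-unsat density, hydrophobic collapse sites (FMILYVW, threshold 0.48), spike ratio, C-beta separation stats |
| `cageforge.selection` | min-max normalization, weighted ranking (both built-in weight schemes), filter cascades with attrition logs |
| `cageforge.fixtures` | ideal helical trimers, planted fragment training sets, planted docking scenarios, perturbation utilities |

## Command line

```bash
cageforge fixtures --scenario docking --seed 7 --out fixtures/
cageforge dock fixtures/oligA.pdb fixtures/oligB.pdb --entry T33 \
    --db fixtures/db --minimum-matched 3 --match-value 0.5 --out poses/
cageforge metrics poses/pose_0.pdb --out metrics.json
cageforge select table.tsv --scheme t33fn-pose
cageforge expand monomer.pdb cage.pdb --symmetry T
cageforge pipeline --seed 7 --out run/
```

`cageforge pipeline` chains dock → profile → metrics → select on a planted
fixture scenario and writes per-stage artifacts plus a manifest with
per-stage counts.

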