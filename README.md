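# molforge

Systematic generation of small-molecule structure datasets for force-field
training, at desk scale:

1. **Chemical graphs** — SMILES sanitisation/canonicalisation, systematic
   enumeration of small chemical graphs (connected simple graphs → bond
   orders → element labels under valency constraints), and enrichment
   generators: protonation states, stereoisomers, amons (hydrogen-saturated
   connected heavy-atom subgraphs), and tripeptides with disulfide-bridged
   and peptide-bond-split variants.
2. **Conformations** — distance-geometry embedding, two-stage local
   optimization (steepest-descent pre-optimization + BFGS to a max-force
   threshold), genetic conformer search over rotatable-bond torsions, and
   symmetry-aware RMSD deduplication that also removes mirror-image
   conformers.
3. **Normal-mode sampling** — finite-difference Hessians (six-point
   stencil on forces), saddle-point check, normal-mode analysis with
   rigid-mode removal, equipartition-based uniform-temperature energy
   draws, random energy partitioning over modes, and displacement
   application in mass-weighted Cartesian or Z-matrix (internal)
   coordinates.
4. **Quality control** — bond-order consistency against the parent graph,
   formation energy, and four outlier criteria (positive formation energy,
   max per-atom force, normalized minimum inter-atomic distance, bond-order
   dissociation) combined into an `is_outlier` flag; NPR shape descriptors.
5. **Records** — a hierarchical store (graph → conformation → calculation)
   with stable hash keys, JSONL and extended-XYZ export (positions in a0,
   energies in E_h, forces in E_h/a0), and an end-to-end pipeline driver.

Quantum-chemistry engines are abstracted behind a calculator contract
(`energy`, `forces`, optional `bond_orders` / `partial_charges`). A
built-in analytic toy force field (harmonic bonds with well depths, 1-3
angle surrogates, periodic 4-body cosine torsions, exponential nonbonded
repulsion, distance-decay bond orders) makes the whole pipeline runnable
and testable without external codes; its forces and Hessians are exact.

## CLI

```sh
forge enumerate --max-vertices 5 --out graphs.smi
forge enrich --in graphs.smi --generators protonation,stereo,amons \
      --max-heavy 8 --out enriched.smi
forge peptides --out peptides.smi --report peptides_report.json
forge conformers --in enriched.smi --calc toy --out confs/ --seed 7
forge sample --smiles CCO --calc toy --tmax 1000 --seed 7 --out store/
forge flag --in store/ --out flagged/ --report qc_report.json
forge export --in store/ --out frames.extxyz
forge audit --in store/
```

## Layout

```
src/molforge/
  chemgraph.py    SMILES handling, valency tables, electronic states,
                  enantiomer representatives
  graph_enum.py   systematic graph enumeration cascade
  enrichment.py   protonation / stereoisomers / amons / tripeptides
  calculator.py   calculator contract, toy force field, quadratic PES
  conformer.py    embedding, optimizer, GA search, symmetry-aware RMSD
  zmatrix.py      internal-coordinate construction and rebuild
  nms.py          Hessians, normal-mode analysis, off-equilibrium sampling
  qc.py           consistency checks, outlier criteria, NPR descriptors
  records.py      hierarchical store, JSONL/extended-XYZ I/O, pipeline
  fixtures.py     toy molecules and planted-defect corpora for testing
  cli.py          `forge` command-line interface
  data/           valency tables, protonation rules, amino acids (JSON)
```
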