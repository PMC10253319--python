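# allosom

Comparative analysis of molecular-dynamics ensembles for two-state
(e.g. ligand-free vs ligand-bound) studies of protein and protein–DNA
complexes: geometry, displacement-correlation networks and self-organizing
maps, behind one importable API and a thin command line.

## Who this is for

Structural bioinformaticians comparing MD simulations of a complex in two
conditions — typically the apo and holo forms of a receptor such as a
bHLH-PAS transcription-factor dimer bound to its DNA response element —
who want to answer three questions:

1. **Where does the geometry diverge?** Per-frame RMSD with independent fit
   and measurement atom sets (align on a scaffold domain, measure a mobile
   subdomain), essential-dynamics PCA in a pooled eigenvector basis, and
   Shrake–Rupley SASA / interface ΔSASA.
2. **How does the coupling change?** The dynamic cross-correlation matrix

       c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)

   over Cα displacements, thresholded at |c| > 0.5 into a residue network
   with path weights −log|c|, Walktrap communities (walk length 4, cut at
   maximum modularity) and the 50 shortest simple paths pooled over
   source×sink residue pairs (Yen's algorithm).
3. **Which interface interactions discriminate the conditions?** A 10×10
   toroidal hexagonal SOM trained on monitored salt-bridge distances
   (charged-group centroids, DNA phosphate P atoms), with complete-linkage
   neuron clustering under a silhouette scan, per-condition population
   maps, a per-feature contrast ranking over condition-exclusive neurons,
   and a cyclic torus unrolling for display.

A synthetic-ensemble module generates inputs with planted ground truth
(block-correlated fluctuations, a one-condition subdomain rotation,
two-condition distance features), so the entire pipeline is testable
without any trajectory download. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

`examples/` contains one narrative script per capability. The full pipeline
(`examples/04_full_pipeline.py`) writes a self-contained synthetic study —
an apo-only 25° subdomain rotation, a scaffold↔subdomain correlation
present only in holo, and 4 discriminating distance features among 25 —
then runs the comparison from its config:

```bash
$ python examples/04_full_pipeline.py
stages: load -> rmsd -> pca -> dccm -> network -> distances -> som -> report
apo  : subdomain RMSD median 3.20 Å | scaffold-mobile correlation -0.008 | 3 communities | 0 paths (disconnected)
holo : subdomain RMSD median 0.55 Å | scaffold-mobile correlation +0.334 | 2 communities | 50 paths (ok)
SOM: silhouette-selected k = 2; top contrast features: d03, d04, d02, d01
artifacts in study_example/results/ (config digest b2aab6f7be0f...)
```

Reading: the apo-like condition shows the large subdomain displacement
(3.20 vs 0.55 Å median RMSD after scaffold alignment), its
scaffold–subdomain correlation collapses to ≈0 (holo keeps +0.33), its
network fragments into an extra community and loses every
subdomain→scaffold communication path, and the SOM contrast ranking
recovers exactly the four planted discriminating distances (d01–d04).
Every artifact (CSV/JSON/GraphML + a manifest with seeds and the config
hash) lands in the study's `results/` directory.

The same run from the shell:

```bash
allosom simulate --out study --seed 11
allosom compare --config study/config.yaml
```

Single-stage subcommands (`rmsd`, `pca`, `dccm`, `network`, `communities`,
`paths`, `distances`, `som`) run one analysis from the same config.

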