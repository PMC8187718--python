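# allotrace

Trajectory analysis of long-range allosteric propagation in multi-helix
membrane transporters — built around the question of how a point mutation on
the extracellular face of an ABC exporter such as MRP1/ABCC1 re-shapes
helix packing, nucleotide-binding-domain (NBD) structure, and the
salt-bridge network coupling the transmembrane domain (TMD) to the NBD,
tens of Ångström away.

The package implements the complete analysis pipeline such a study needs,
plus a synthetic-trajectory generator that plants known ground truth into a
toy multi-helix protein so every stage is verifiable without running
molecular dynamics:

- **Structure I/O** — multi-model PDB read/write (the trajectory
  interchange format), a small deterministic atom-selection language
  (`backbone`, `calpha`, `resid 560-570`, …).
- **Geometry** — Kabsch superposition (SVD, reflection-corrected), RMSD
  time series, all-pairs 2D-RMSD matrices between two trajectories, signed
  torsions, minimum residue–residue distances.
- **Conformational clustering** — the GROMOS (Daura) greedy
  neighbour-count algorithm at an RMSD cutoff (default 3 Å), cluster
  occupancies and timelines.
- **Essential dynamics** — Cα covariance about an iteratively refined
  mean, eigendecomposition (eigenvalues reported in nm²), porcupine
  displacement fields filtered at 4 Å.
- **Helix geometry** — the three-anchor interhelical opening angle
  (Cα571−Cα574 vs Cα577−Cα574 by default) and flanking-axis kink angles at
  a pivot residue (window 6).
- **Secondary structure** — Kabsch–Sander H-bond assignment collapsed to
  {H, E, T, C}, residue × frame maps, motif-unraveling reports.
- **Interactions** — contact scans by trajectory-mean minimum heavy-atom
  distance, the ≤ 4 Å salt-bridge rule, screened Coulomb (ε = 20 default)
  + Lennard-Jones residue-pair energies from a bundled parameter table.
- **Statistics** — Mann–Whitney U (exact for small untied samples),
  replica mean ± SD aggregation, circular recentring for dihedral
  distributions.

## Worked example

Generate a "wild-type-like" and a "mutant-like" synthetic trajectory and
compare them end to end:

```sh
allotrace simulate --scenario wt     --seed 1 --frames 30 --out wt.pdb
allotrace simulate --scenario mutant --seed 4 --frames 30 --out mut.pdb
printf 'wt: [wt.pdb]\nmutant: [mut.pdb]\ndiscard_fraction: 0.1\n' > cfg.yaml
allotrace report --config cfg.yaml --out results.json
```

Individual stages are also commands. On the WT-style trajectory above:

```
$ allotrace cluster wt.pdb --cutoff 3.0
2 clusters; top occupancy 0.917
$ allotrace helix-angle wt.pdb
mean 85.52 ± 1.86 deg over 12 frames
$ allotrace bend wt.pdb --pivot 553
mean 18.73 ± 2.62 deg at pivot 553
$ allotrace contacts wt.pdb --group-a 521 --group-b 1358-1371 --cutoff 3.5
521     1364    2.463
521     1367    3.252
$ allotrace energy wt.pdb --pair 521:1364
energy -20.37 kJ/mol, distance 2.46 Å, occupancy 1.00, bonded: True
```

Reading the output: the WT-style ensemble sits almost entirely in one
conformational cluster (a stable trajectory), its helix-10/11 opening
angle is wide (~85°), helix 10 is kinked (~19°) at the pivot, and the
contact scan discovers exactly the planted acidic/basic communication
pairs, both salt-bridged (distance ≤ 4 Å) with negative interaction
energies. The mutant-style scenario inverts each signature: fragmented
clusters, closed angle, straighter helix, a broken His–Glu bridge, and
four NBD motifs whose helix/strand structure unravels mid-run.

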