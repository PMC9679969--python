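# ligmodes

Binding-mode analytics for protein–ligand molecular-dynamics trajectories,
built around the question of **how a PET (polyethylene terephthalate)
hydrolase engages a PET-chain analogue**: which residues touch the ligand,
by which interaction types, how those per-frame interaction patterns group
into recurring *binding modes*, and how the enzyme's crystal structure
(disulfides, catalytic triad, monovalent-ion sites) underpins that picture.
It is aimed at structural bioinformaticians and enzyme engineers who have
trajectories (or want seeded synthetic stand-ins) and need reproducible,
testable numbers rather than one-off analysis notebooks.

## What it computes

**Interaction fingerprints.** Each frame is reduced to a boolean vector over
(residue, type) descriptors with five geometric interaction types:
hydrophobic (C/S⋯C ≤ 4.5 Å), π-stacking (ring-centroid distance ≤ 5.5 Å at
interplanar angle ≤ 35°, or ≤ 6.5 Å at ≥ 50° for edge-to-face), heavy-atom
hydrogen bonds (N/O⋯O ≤ 3.5 Å, roles from standard chemistry; ester oxygens
accept only), and OH–π (hydroxyl O ≤ 4.5 Å from a ring centroid, ≤ 40° off
the ring axis). All thresholds are configurable (`InteractionCriteria`).

**Binding modes.** For frames *i, j* with fingerprint rows *x_i, x_j*, the
Tanimoto (Jaccard) coefficient

&nbsp;&nbsp;&nbsp;&nbsp;T(x_i, x_j) = |x_i ∧ x_j| / |x_i ∨ x_j|

(1 = identical interaction pattern, 0 = no shared interaction) fills the
frame × frame similarity matrix. Modes are found by kMeans on the 0/1 rows,
with the cluster count k chosen as the argmax of the mean Silhouette score
over k = 2…10; each cluster's *representative* is the frame nearest its
centroid and its *specificity* is the mean intra-cluster Tanimoto.

**Statistics.** Contact frequencies are shares of frames; their errors are
the sample standard deviation of 5 consecutive block means (block
averaging). Distance distributions are summarized by the mode of a
Gaussian-KDE (Silverman bandwidth).

**Trajectory QC.** A run is admitted only if the ligand stays bound
(minimum protein–ligand heavy-atom distance ≤ 4.5 Å in every frame) and a
partially bound ligand (< 3 contact residues) never self-stacks
(non-adjacent repeat-unit rings in π-stacking geometry).

**Crystal characterization.** Disulfide bridges (CYS S–S ≤ 2.3 Å),
the Ser-His-Asp catalytic triad (hydrogen-bond distance criteria, exhaustive
over candidate triples), octahedral ion coordination shells, and pairwise
chain RMSD by Kabsch superposition on shared heavy atoms.

**Synthetic complexes.** A seeded generator builds a pocket of
pseudo-residues facing a rigid 4-repeat-unit aromatic ligand
(methyl-ester-capped PET-tetramer analogue) and samples frames from K
planted rigid poses with Markov dwell, Gaussian jitter, and Bernoulli
contact realization — ground-truth mode labels included, so every pipeline
stage is testable without running MD.

## Worked example

```
$ python examples/binding_mode_discovery.py
fingerprint: 500 frames x 24 (residue, type) descriptors
selected k = 3 (planted: 3)
cluster sizes: [153, 256, 91]
specificity (mean intra-cluster Tanimoto): [0.905, 0.9, 0.874]
representative frames: [2, 106, 0]
label agreement with planted truth (ARI): 1.000
```

A 500-frame synthetic trajectory with three planted poses is fingerprinted
and clustered; the Silhouette criterion selects k = 3, the cluster sizes
reflect how long the ligand dwelt in each pose, specificity ≈ 0.9 says each
mode's interaction pattern is strongly conserved, and the adjusted Rand
index of 1.0 confirms the frame labels match the generative truth. The
other scripts in `examples/` demonstrate crystal characterization,
trajectory QC and contact statistics the same way.

The same pipeline is scriptable from the shell:

```
ligmodes simulate --modes 2 --frames 500 --seed 1 --out traj.pdb
ligmodes fingerprint traj.pdb --ligand PTE --out fp.csv
ligmodes cluster fp.csv --seed 0 --out-prefix modes
ligmodes structure-report my_crystal.pdb --json report.json
```

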