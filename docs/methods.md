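# Methods

## Scope and data model

The package analyses protein–ligand trajectories with constant topology:
a `Structure` (one PDB model, author residue numbering, coordinates in Å)
plus a frame stack. Multi-model PDB is the canonical trajectory format;
any reader producing the same `Trajectory` contract can substitute.
Hydrogens are accepted everywhere but every geometric detector is defined
on heavy atoms, so crystal structures and hydrogen-free fixtures behave
identically to protonated MD frames. Alternate locations are resolved at
read time (highest occupancy by default, ties by altloc letter; a
first-seen policy is available). Elements are taken from the PDB element
column and inferred from atom names when absent, with two-letter ion
symbols (NA, CL, …) recognized from HETATM records — the ion-site analysis
depends on correct element assignment.

## Interaction fingerprints

Per frame, five interaction types are detected between protein and ligand
and recorded as boolean (chain, residue, type) descriptors. The
thresholds live in `InteractionCriteria` and follow widely used
fingerprinting conventions; they are deliberately declared, not fitted:

| parameter | default | meaning |
|---|---|---|
| `hydrophobic_d` | 4.5 Å | protein C/S to ligand C contact |
| `pi_centroid_d_parallel` / `pi_angle_parallel` | 5.5 Å / 35° | face-to-face stacking |
| `pi_centroid_d_tshaped` / `pi_angle_tshaped_min` | 6.5 Å / 50° | edge-to-face stacking |
| `hbond_da_d` | 3.5 Å | donor–acceptor heavy-atom distance |
| `ohpi_d` / `ohpi_axis_angle` | 4.5 Å / 40° | hydroxyl O over a ring face |

Interplanar angles are folded to [0°, 90°]; the gap between 35° and 50°
is intentionally reported as no stacking. Protein aromatic rings come
from residue templates (PHE/TYR six-ring, HIS five-ring, TRP both rings);
ligand rings are 6-membered all-carbon cycles of a distance-inferred bond
graph (single-bond covalent radii + 0.4 Å slack) that pass a planarity
check (max deviation from the best-fit plane ≤ 0.3 Å). Ring centroids and
normals are recomputed every frame from the member atoms.

Hydrogen bonds use the heavy-atom criterion so that structures without
hydrogens are analysable; donor/acceptor roles follow standard chemistry
(backbone N-H and side-chain N-H/O-H donate; carbonyl, carboxylate and
ester oxygens accept; ligand ester oxygens are acceptors only —
the modelled PET tetramer is end-capped as methyl esters, representing a
neutral continuation of a longer chain, so it has no donatable ligand OH).
When explicit hydrogens are present an optional D–H⋯A ≥ 130° filter can
tighten the call (`hbond_angle_filter`); it is off by default for
uniformity. Ionic and cation–π types are omitted because the modelled
ligand is neutral.

A fingerprint matrix contains a column only for descriptors observed in at
least one frame, sorted by (chain, resseq, type) for determinism;
concatenating trajectories concatenates rows on the union column set.

## Trajectory admission

Two filters decide whether a production run enters the pooled statistics.
*Bound throughout*: the minimum protein–ligand heavy-atom distance must be
≤ 4.5 Å in every frame. *No partially-bound self-stacking*: in frames
where fewer than 3 protein residues touch the ligand, no two non-adjacent
repeat-unit rings of the ligand may satisfy the π-stacking criterion with
each other (adjacent rings cannot reach stacking geometry without bond
strain). Offending runs are rejected whole, not trimmed: mixing segments
of a partially detached run into mode statistics would bias cluster sizes.
The "partially bound" threshold of 3 contact residues is the one genuinely
soft parameter here and is exposed as `partial_threshold`.

## Binding modes

Pairwise Tanimoto coefficients over fingerprint rows (both-empty rows
count as identical, T = 1) give the similarity matrix. Clustering runs
kMeans on the raw 0/1 rows in Euclidean geometry with `n_init` restarts
and a fixed seed; the Silhouette score that selects k uses the same
Euclidean metric as the clusterer, so the model selection criterion
matches the objective being optimized. k ranges over 2…min(10, F−1);
ties go to the smallest k (parsimony). All-identical rows are the
degenerate single-mode case: k = 1 by definition (Silhouette is undefined
there), specificity 1. Clustering the rows of the Tanimoto matrix instead
of the raw fingerprints is available via `feature_space="similarity"`;
on planted-mode data both conventions recover the truth, and the raw-row
convention is the default.

Per cluster, the representative frame minimizes the Euclidean distance to
the cluster centroid (ties → lowest frame id) and the specificity is the
mean off-diagonal intra-cluster Tanimoto (singletons → 1).

**Known limitation.** Mean-Silhouette model selection can over-split
binary fingerprints whose rows contain large blocks of exact duplicates:
a cluster of identical rows has zero within-distance, so carving flip
variants into their own clusters can raise the mean Silhouette above the
planted partition. This occurs when modes carry only a handful of
descriptor bits (≲ 6 per mode) or when one mode dominates heavily; with
realistically sized interaction sets (~8–10 engaged residues per mode,
which is what binding regions of PET hydrolases show) recovery is
reliable, and the synthetic generator's default contact sets are sized
accordingly. This is a property of the clustering criterion itself, not
of its implementation.

## Statistics

Contact frequency is the column mean of the boolean matrix; an
interaction-type *share* is the fraction of frames in which any descriptor
of that type is set. Errors come from block averaging: the series is
split into 5 consecutive blocks (remainder frames join the last block)
and the sample standard deviation (n−1) of the block means is reported.
With 5 blocks this estimator is itself noisy (≈ 35 % relative sd), which
is the price of respecting temporal correlation without modelling it;
autocorrelation-aware estimators are out of scope.

Distance distributions (e.g. hydroxyl O to ring centroid for OH–π
geometry) are summarized by the mode of a Gaussian-kernel density
estimate, Silverman's rule by default with the bandwidth exposed. The
density is evaluated on ≥ 512 grid points (odd count, so a symmetric
sample peaks exactly on the grid) spanning [min − 3h, max + 3h].

## Crystal-structure characterization

Disulfides: all CYS SG–SG pairs within 2.3 Å (typical bond ≈ 2.05 Å),
intra- or inter-chain, each reported once. Catalytic triad: among all
Ser × His × Asp triples of a chain, the one minimizing
d(Ser Oγ, His Nε2) + d(His Nδ1, nearest Asp Oδ) subject to both being
≤ 3.5 Å (hydrogen-bond distance); absence is a result, not an error.
Ion coordination: protein/ligand heavy atoms and water oxygens within
3.0 Å of the ion (Na–O ≈ 2.4 Å; the cutoff is per-call configurable for
larger ions). Chain RMSD: for each chain pair, heavy protein atoms are
matched by (resseq, atom name) on the intersection of the two chains and
superposed by Kabsch (SVD with determinant correction, delegated to
`scipy`'s `Rotation.align_vectors`); "all-atom" is read as all modelled
non-hydrogen atoms. Whether a common-residue trimming convention would
change the third decimal of the RMSD is an accepted ambiguity.

## Synthetic data

The generator emulates the *logical* structure of a bound-complex
trajectory, not its physics: a line of pseudo-residues (N, CA, C, O, CB)
at 4 Å spacing faces a rigid ligand of four planar all-carbon hexagons
(1.39 Å sides) joined by carboxyl-ester/glycol linkers with methyl-ester
caps — bond distances respect covalent radii so ring perception and
oxygen-role classification run on realistic geometry. Binding modes are
K rigid poses, each centred under a disjoint window of 8 pocket residues
(default; realistic binding regions engage ~8–10 residues). The mode
sequence is a Markov chain with mean dwell 20 frames and uniform switch
targets (stationary distribution uniform); the ligand gets rigid-body
Gaussian jitter (σ = 0.25 Å default, plus a ~0.01 rad rotational wobble),
and each contact-set residue of the active mode reaches the ligand
(side-chain C at 3.8 Å below the nearest ligand carbon) with a Bernoulli
probability per frame — contact_prob 0.95 models 5 % fingerprint flip
noise, and per-residue probabilities allow planting known contact
frequencies. An optional serine probe places its hydroxyl O on a ring
axis at a per-frame distance drawn from a chosen normal law, to exercise
the OH–π detector and the KDE mode estimator.

What this does *not* emulate: force-field energetics, solvent, partial
unbinding dynamics, correlated contact loss, protein flexibility, or
overlapping/ambiguous binding modes (overlap can be planted explicitly
via custom contact sets). Passing recovery tests on this generator
therefore demonstrates the correctness of the pipeline's geometry,
bookkeeping and statistics under known ground truth — not that real MD
binding modes are always as separable as the planted ones.

Toy structures for the crystal detectors plant features in ideal
geometry on a poly-alanine helix: CYS pairs at S–S 2.05 Å, a triad at
Oγ–Nε2 3.0 Å / Nδ1–Oδ1 2.8 Å, and octahedral Na⁺ sites at 2.4 Å with a
chosen split of carbonyl-oxygen and water ligands. The synthetic
asymmetric-unit stand-in assembles three rigidly transformed copies of
one such chain with per-atom Gaussian noise σ = 0.65/√6 Å on non-feature
atoms, which puts the pairwise all-atom RMSD near 0.65 Å by construction
(for two chains with iid noise σ per coordinate the expected RMSD is
σ√6); feature atoms stay exact so the planted geometries survive. It is
a generated object standing in for a deposited crystal structure and is
labelled synthetic wherever it appears.

## Problem sizes and determinism

The shipped tests and the acceptance script use 500-frame trajectories
(20 seeds per planted K) for mode recovery, 5 000 frames for frequency
recovery, and 500/5 000/50 000 frames for the 1/√F block-error scaling;
these sizes put the sampling noise of each check well below its decision
threshold. Every stochastic step takes an explicit seed (NumPy
`default_rng`); identical seeds give bit-identical trajectories, labels
and cluster assignments.
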