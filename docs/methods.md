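# Methods

`flexdock` docks a flexible ligand into a receptor whose selected side
chains are also flexible. This note records the model, the numerical
choices, and what the synthetic benchmark systems do and do not
demonstrate.

## Representation

A docking solution (an *individual*) is a genotype over the genome

    translation (x, y, z)  |  rotation (unit quaternion)  |
    one torsion per rotatable ligand bond  |  one chi block per flexible residue

Angles are degrees in (−180, 180]. The ligand torsion tree comes from the
PDBQT ROOT/BRANCH records; each branch carries the set of atoms it moves,
and moved-sets nest along the tree. Side-chain chi angles follow the IUPAC
heavy-atom quadruples for the 18 chi-bearing residue types; PRO is in the
table but cannot be made flexible because its side chain closes a ring onto
the backbone. Movable atoms are those beyond CB; the per-chi moved-sets are
derived by cutting the rotated bond in the residue's covalent graph
(inferred from covalent radii), so hydrogens follow their heavy atoms
automatically.

The phenotype (Cartesian coordinates) is built deterministically: torsion
rotations are applied from the root outward, then the rigid rotation about
the root atom and the translation placing the root atom at the translation
gene; receptor side chains are rotated chi1..chiN about the current axis
positions. Same genotype, bit-identical coordinates.

## Scoring

The pairwise model is the AutoDock4 energy function: a 12-6 van der Waals
term (12-10 for donor-H/acceptor pairs; the angular hydrogen-bond factor is
set to 1 for explicit pairs — a documented simplification, since grid maps
can bake directionality in at build time), a screened Coulomb term with the
Mehler–Solmajer sigmoidal distance-dependent dielectric, and a
Gaussian-damped pairwise desolvation term with charge-augmented atomic
solvation parameters (sigma = 3.6 Å). Parameters and the free-energy
weights (w_vdW = 0.1662, w_hbond = 0.1209, w_elec = 0.1406,
w_sol = 0.1322) ship as a packaged data file. The vdW term is clamped at
+1e5 kcal/mol so clash arithmetic stays finite during the search.

The total score splits interactions over ligand (L), rigid receptor (RR)
and flexible receptor (FR) atoms:

    S = E_LL + E_LRR + E_LFR + w_rec (E_FRFR + E_FRRR)

* E_LL, E_LFR, E_FRFR: explicit pairwise sums with an 8 Å cutoff. 1-2 and
  1-3 pairs are excluded; 1-4 pairs are excluded unless a rotatable bond
  mediates them.
* E_LRR: trilinear interpolation of affinity maps. Three grid families are
  computed by direct summation over rigid atoms: one per probe atom type
  (vdW/H-bond plus the charge-independent desolvation part), an
  electrostatic grid (per unit probe charge) and a desolvation grid (per
  unit |q|), so that map_t + q·map_e + |q|·map_d equals the explicit sum
  *exactly* on grid nodes. Ligand atoms leaving the box incur a smooth
  penalty (1000 × (1 + overshoot in Å) per atom) rather than an error, so
  the search can recover.
* E_FRRR: an explicit pairwise sum over movable-atom/rigid-atom pairs,
  using a rigid neighbour list precomputed per side chain (cutoff + 8 Å
  reach around CB) and honouring the same exclusion rules exactly. An
  earlier design interpolated E_FRRR from the maps and subtracted the
  excluded bonded-pair terms; that is unsound here because the
  post-processed maps no longer contain the interior clash potential the
  subtraction assumes, which produced runaway negative receptor energies.
  The explicit sum is exact, and for side-chain-sized movable sets it costs
  little.
* w_rec = 1/NFS (NFS = number of flexible side chains) down-weights the
  receptor internal energy so that receptor relaxation cannot swamp
  ligand-receptor interactions as flexibility grows; it is overridable
  (1.0 reproduces unweighted scoring) and is applied consistently during
  the search and in reported totals, with the raw terms reported alongside.

## Affinity-map post-processing

Raw maps fluctuate wildly inside the receptor. A 6-connected flood fill
from the box boundary through nodes outside the reduced atomic spheres
(radius scale 0.85 of the vdW radius, configurable; reduced radii keep
narrow grooves exterior) classifies nodes exterior/interior; enclosed
cavities are interior by construction. Interior node values are replaced,
in increasing burial depth, by

    value = max(E_surface, min over already-processed 6-neighbours) + k_grad

with E_surface = 1 kcal/mol and k_grad = 1 kcal/mol per grid step. When
surface-adjacent exterior values are below E_surface this reduces to
E_surface + depth × k_grad; unlike that fixed formula, the neighbour-min
form guarantees that *every* interior node has a strictly smaller
6-neighbour even where the adjacent exterior value is large and positive
(just outside the reduced spheres), so a steepest-descent walk from any
interior node provably reaches the exterior. Electrostatic and desolvation
grids are zeroed on interior nodes; the gradient is carried by the type
maps alone. Exterior values are untouched.

## Focused sampling

* Translational points: exterior nodes of the 3×-downsampled lattice
  (1.125 Å at the default 0.375 Å spacing) with carbon affinity ≤ −0.3
  kcal/mol. If the filter retains nothing the extractor falls back to all
  exterior strided nodes with a warning. Initial ligand translations are
  drawn uniformly from these points; the local search moves translations
  continuously thereafter.
* Soft rotamers: chi-block mutation replaces the block with a library row
  drawn by prior probability, each chi perturbed by that row's standard
  deviation. The packaged backbone-independent table carries representative
  modal values in the style of the Dunbrack library with priors summing to
  1 per residue; it is a compact synthetic stand-in, and the documented
  file format (residue, prior, chi means/sds) lets users substitute a full
  library.
* Flexible side chains are *not* randomized at initialization: every
  individual starts from the input receptor conformation.

## Search

Per generation: score, sort, cluster the individuals within 2 kcal/mol of
the best (greedy energy-ordered seeding; members within 2 Å ligand RMSD of
their seed). The best of each cluster is copied into the next generation
(adaptive elitism) and, with all unclustered individuals, forms the mating
population. Parent selection is linear-rank on ascending energy (weight
N − rank + 1) — a scale-free, sign-safe realization of "selection
proportional to score" for energies where lower is better. Matings apply
crossover with probability 0.8 (gene-level uniform; chi blocks swap
atomically per residue), otherwise the parents pass through; offspring are
mutated (Gaussian moves of 0.5 Å / 10° / 30° for translation / rotation /
torsions; soft rotamers for chi) and quick-minimized. Offspring beating
the best-seen score get an aggressive minimization and become the new
reference. The best two offspring of a generation are inserted if no
identical genotype (per-gene agreement within 1e-6) is present.

Minimization is Solis–Wets: perturb all genes by a Gaussian step of width
rho in gene-scaled units (1 Å translation, 0.2 quaternion, 30° angles),
retry the mirrored step on failure, double rho after 4 consecutive
successes, halve it after 4 consecutive failures; quick mode runs ≤ 30
steps to rho ≥ 0.1, aggressive ≤ 300 steps to rho ≥ 0.01. The returned
individual never scores worse than the input.

Termination: if the cluster set is unchanged (same count, per-cluster best
energies within 1e-3 kcal/mol) for 3 consecutive generations the whole
population is aggressively minimized; 5 unchanged generations end the run
as converged (the stall counter is not reset by the generation-3
minimization). Caps on generations (default 200) and evaluations (default
2.5 million) guarantee termination.

A docking performs 50 independent runs (per-run seed = base seed + run
index), pools per-run bests, clusters those within 1 kcal/mol of the
overall best and reports cluster bests ranked by energy. Per-generation
clustering uses fast index-matched ligand RMSD; final reporting and all
analyses use the symmetry-corrected Hungarian RMSD (per-type minimum-cost
assignment, no superposition). Population size defaults to 50 + 10·L_v
with L_v = 7 + number of rotatable ligand bonds.

## Analyses

Rank = position of the first reported solution within the RMSD cutoff of
the reference (2.0 Å for re-docking, 2.5 Å recommended for apo
cross-docking, both flags); N − 1 better-scoring solutions are false
positives. Clashes are heavy-atom pairs closer than half the sum of their
vdW radii (radii = Rii/2 from the parameter table). Flexible-residue
selection returns residues with a beyond-CB heavy atom within 4 Å of a
ligand heavy atom. Contact recovery tabulates ligand/movable-atom pairs
within 5 Å in the reference complex and counts those reproduced in the
docked pose under the same per-type Hungarian correspondence as the RMSD;
docked-only contacts are flagged novel. A side chain counts as having
changed rotameric state when any chi differs from the input by ≥ 50°
(circular, boundary inclusive).

## Synthetic benchmark systems

No external structures are used. The fixtures build spherical shells of
carbon pseudo-atoms (Fibonacci lattice, radius 4 Å, ~110 atoms, small
alternating charges, 0.03 Å seeded jitter) with an opening (open pocket),
sealed (buried cavity for mask tests), or with one or two idealized serine
side chains anchored at the rim. The serine CB→CA axis is deliberately
tilted sideways so chi1 genuinely sweeps OG toward/away from the pocket
centre; the apo-clash template then rotates the serine so its *input* chi1
parks OG over the best translational point — the side chain must rotate
≥ 60° (verified at construction) to admit the single-atom ligand, and the
enumerated flexible optimum beats the enumerated rigid-receptor optimum by
a construction-checked gap (≥ 0.5 kcal/mol). Boxes are 19³ nodes at 0.5 Å.

The brute-force oracle enumerates translations over the translational
points and torsion/chi angles on regular grids (orientation at the
identity — exact for the single-atom ligands used in enumerable fixtures),
scoring through the *same* scorer as the GA; it adds enumeration control
only, never a second energy implementation, and refuses grids above 1e6
genotypes.

What these fixtures show: the search machinery (clustering, elitism,
focused sampling, local search, induced-fit resolution, receptor-term
weighting) behaves as specified on landscapes whose global optima are
known exactly. What they do not show: performance on real protein
surfaces — realistic chemistry (typed H-bond networks, buried polar
groups), rugged torsional landscapes of drug-like ligands, or scoring
accuracy against experimental affinities.

GA problem sizes in the test-suite configurations (population 30, quick
minimization 15 steps, ≤ 30–40 generations, 8–50 runs) are the package's
choices for the enumerable fixtures, where convergence is typically
reached in well under 30 generations; production defaults remain the
heuristic population and full step counts.

## Known limitations

* Explicit-pair hydrogen bonds are distance-only (E(t) = 1); full angular
  directionality is an extension point.
* Charges and atom types are read from PDBQT and never recomputed;
  structure preparation is out of scope.
* Backbone motion, rotatable terminal hydrogens, explicit waters and
  ensemble (multi-receptor) docking are not implemented.
* The torsional-entropy free-energy term is not part of the score; totals
  are interaction energies, not binding free energies.
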