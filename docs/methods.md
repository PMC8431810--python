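# Methods

## Scope and model

`gelscan` analyzes multi-frame Cartesian trajectories of N rigid copies of
an Fmoc-phenylalanine monomer (parent, 3,4-difluoro or 3,5-difluoro) in an
orthorhombic periodic box, and the packing geometry of a solved crystal
structure in CIF form.  It does not perform molecular dynamics: the
trajectories it consumes come either from external simulations or from the
package's own synthetic generators.

The monomer is an idealized rigid template: planar fluorene and phenyl
rings with aromatic C–C 1.39 Å, C–F 1.35 Å, a tetrahedral Cα, a trans
carbamate, and Bondi van der Waals radii (C 1.70, N 1.55, O 1.52, F 1.47,
H 1.20, S 1.80 Å).  Only relative geometry matters for the analyses, so
standard bond lengths and angles are used throughout; φ and ψ can be
re-posed by rigid rotation about the N–Cα and Cα–C bonds.  The local frame
is deliberately "stacking-friendly" — fluorene and phenyl planes parallel
to z = 0, carbamate C=O toward +z, amide N–H toward −z — so that a
β-sheet-like stacked, hydrogen-bonded dimer can be generated from two
copies by a rigid motion.  The exact placement constants of the phenyl
ring and carboxyl group were chosen (once, by a feasibility search over
the layout) so that both the parallel and the antiparallel dimer
construction admit clash-free solutions; they are idealized design
choices, not fitted quantities.

## Interaction criteria

All pairwise analyses share one uniform criterion: two atom groups
interact when their minimum heavy-atom distance, under the minimum-image
convention, is at most **4.0 Å**.  On top of this cutoff:

* **Stacks** additionally require the two ring centroids within
  **d_stack = 5.5 Å**; the pair is *face-to-face* when the best-fit-plane
  interplanar angle is ≤ **30°**, otherwise *offset/edge*.  An edge-on
  atom contact whose centroids are farther than d_stack is not counted as
  a stack event.  Ring planes come from an SVD plane fit; rings with RMS
  out-of-plane deviation above 0.2 Å are rejected as non-planar.
* **Hydrogen bonds** use D···A ≤ **3.5 Å** and ∠(D–H···A) ≥ **120°** for
  N/O donors, and the looser D···A ≤ **3.7 Å**, ≥ **110°** for weak
  C–H···F contacts.  The donor hydrogen must be explicit; for crystal
  structures without H, hydrogens are placed at idealized geometry
  (N–H 1.01 Å, O–H 0.96 Å, opposite the mean heavy-neighbour direction).

Only the 4.0 Å cutoff is stated by the study design this package serves;
the stacking and hydrogen-bond gates are conventional crystallographic
values and are exposed in the taxonomy configuration.

An interaction is counted once per (frame, monomer pair, label)
regardless of how many atom pairs satisfy it; per-atom-pair counting is
available (`counting="atom_pair"`) because the alternative reading of
"instances" cannot be excluded.  Percent frequency divides each label's
count by the total number of interactions observed in the same replicate;
replicates with zero events are excluded from the across-replicate mean
and SD with a logged warning.

## Clusters, Rg, motifs

Clusters are connected components of the monomer contact graph (edge iff
minimum heavy-atom distance ≤ cutoff); components of size one are tracked
as singletons, since the cluster definition presupposes at least one
neighbour.  Before measuring, a cluster is unwrapped: each monomer is
first made whole relative to its own first atom, then members are placed
by breadth-first traversal of the contact graph, each at the minimum
image of its parent — so Rg is measured on one contiguous aggregate.

Rg is the plain root-mean-square deviation of member heavy atoms from
their unweighted geometric centre (no mass weighting; hydrogens excluded
by default, switchable).  The β-sheet-like dimer motif requires both a
backbone hydrogen bond — amide N–H of one monomer to a carbonyl oxygen
(carbamate *or* carboxyl C=O) of the other — and a face-to-face stack of
the two Fmoc ring systems or the two phenyl rings; parallel vs
antiparallel is the sign of the dot product of the monomers' carbamate-C →
carboxyl-C vectors.  The carboxyl carbonyl is admitted as an acceptor
because an antiparallel pair aligns the N-terminal end of one monomer
with the C-terminal end of the other; restricting to the carbamate oxygen
would make the antiparallel geometry unrealizable for rigid monomers
whose chain extends away from the fluorene.

## SASA and moiety exposure

Solvent-accessible surface area is computed by Shrake–Rupley quadrature:
each atom's sphere of radius r_vdw + probe (probe 1.4 Å, water) is
sampled with a deterministic Fibonacci-spiral point set (default 960
points; seedless and reproducible), and a point survives if it lies
outside every neighbour's expanded sphere.  The quadrature error is ~0.2%
against the closed-form two-sphere cap area and < 0.5% under point
doubling; because the point set is fixed in space, results are invariant
under rigid motion only to within that quadrature error.  Hydrogens are
excluded by default (heavy-atom Bondi radii, switchable).

Moiety exposure is SASA/TSA as a percentage: the accessible area of the
moiety's atoms with all heavy atoms of the cluster (including the host
monomer) as occluders, divided by the accessible area of the same atoms
in the same conformation with everything else removed.  TSA is read as an
accessible (not Connolly/molecular) area so the ratio lies in [0, 100];
the fluorinated-Phe side-chain moiety includes its ring fluorines.

## Crystal geometry

CIF syntax (cell, symmetry operators, atom sites) is parsed with gemmi;
all geometry is computed in-package: the standard orthogonalization
matrix (a along x), symmetry expansion over ± shell unit-cell
translations with deduplication by rounded fractional coordinates,
molecule partition by covalent connectivity (single-bond covalent radii
+ 0.45 Å), DMSO identified as the S-containing molecule, six-membered
all-carbon rings from the cycle basis of the carbon subgraph, torsions in
the IUPAC sign convention, and ring stacks / hydrogen bonds with the same
gates as the trajectory module.  ψ of the single residue is reported
against the carbonyl-type oxygen, with the value against the hydroxyl
oxygen also returned, since single-amino-acid ψ is convention-dependent.

The bundled reference crystal is **synthetic**: one idealized
Fmoc-3,4F-Phe conformer posed at φ = −130°, ψ = 165°, plus one DMSO
molecule, in P2₁2₁2₁ with c chosen so that the fluorene centroid sits on
the c-axis 2₁ screw and its symmetry image stacks face to face at exactly
c/2 = 4.983 Å, and the carboxyl O–H donating to the DMSO oxygen at
2.77 Å.  Every descriptor measured from this file is therefore known by
construction: it validates the measurement code end to end (CIF → cell →
symmetry → geometry), not any experimental deposition.  Pointing
`gelscan crystal` at a downloaded deposition runs the identical code
path.

## Synthetic data

The generator produces three kinds of fixtures, all deterministic for a
fixed seed:

* **Planted scenarios** lay out groups (contact-chained clusters, motif
  dimers, labelled contact chains, singletons) on a grid with bounding-box
  gaps of at least cutoff + margin (margin default 1.0 Å), while
  intra-cluster contacts are placed at exactly cutoff − margin by an
  anchor-alignment construction; frames differ only by small per-group
  rigid translations, so the ground truth holds in every frame.  Motif
  dimers are found by a seeded search over vertical-axis rotations
  (± tilts ≤ 26° to stay within the face-to-face gate), acceptor choice
  and hydrogen-bond placement, accepting the first candidate that the
  package's own detectors classify correctly with ≥ 2.2 Å inter-monomer
  heavy-atom clearance.
* **The Metropolis simulator** is a square-well fluid of rigid monomers:
  centroid hard core 5.5 Å, attraction −ε within 11 Å, a −0.5ε bonus
  for Fmoc-ring centroids within 8 Å, single-particle translation
  (±1.8 Å) and rotation (±25°) moves at kT = 1.  It reproduces only the
  phenomenology the analyses must detect — gradual aggregation, and
  denser clusters at stronger attraction — and is explicitly not a
  physical model: no water, no electrostatics, no conformational
  flexibility.  The compactness-contrast study conditions are 20 monomers
  in a 60 Å box, 40 frames of 20 sweeps, ε = 1.2 vs 4.0, three replicates,
  second half of each run analyzed; sizes are chosen so shared cluster
  sizes 4–8 occur on one CPU in about a minute.
* **Exposure fixtures** place monomers on a spherical shell with the Fmoc
  moiety oriented inward or outward (residual spin random), giving
  known-direction burial contrasts.

Passing tests on these fixtures demonstrates that the analysis operators
recover planted structure exactly and reproduce closed-form values; it
does not demonstrate anything about real force-field trajectories, whose
conformational flexibility, solvent effects and density the generator
does not emulate.

## File formats

Multi-model PDB (MODEL/ENDMDL) with two documented conventions — a
`REMARK 250 TIME_NS=` line per model and the moiety tag in the segment-id
column — and extended XYZ with `time_ns`/`box` in the comment line.  The
snapshot schedule places frames at t = k·Δt for k = 1…T/Δt (the t = 0
configuration is not analyzed), so 5 replicates × 80 ns at 0.2 ns give
2000 snapshots.  Coordinates are Å everywhere.

## Known limitations

* Rigid monomers: no intramolecular flexibility anywhere in the synthetic
  data; analyses themselves are conformation-agnostic.
* The SASA quadrature is deterministic but orientation-dependent at the
  ~0.2% level; exposure comparisons across rigid motions are good to
  ~0.5 percentage points at 960 points.
* Cluster analysis assumes orthorhombic boxes.
* The simulator's cluster-size statistics are noisy at small sample
  sizes; the strict per-size compactness ordering is reliable under the
  frozen study conditions but fluctuates for very rare sizes.
* Hydrogen placement in crystals handles single missing H on N/O donors
  only (no methyl/ammonium geometry).
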