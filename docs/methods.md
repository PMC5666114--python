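# Methods

## Scope and model

`openring` determines the quaternary geometry of a symmetric protein
oligomer from a solution scattering profile by exhaustive construction and
scoring of candidate rigid-body models.  The object of inference is a single
rigid transform — the *step* from one subunit (here: one dimer) to the next —
parameterized by three intrinsic Z–Y–Z Euler angles (degrees) and a
translation (Å).  A candidate assembly of n units places copy k at the k-th
power of the step; closed C_n rings are the special case of a pure rotation
by 360/n about the symmetry axis applied to a unit displaced by a radius.
Scoring is reduced χ² between the candidate's Debye profile and the data,
with a free multiplicative scale.

Assumptions: the subunit is rigid (a single conformation for all copies);
the assembly is perfectly symmetric (one generator; the real crystal helix
shows inter-dimer variability up to ~1.6 Å RMSD, which this model averages
away); the scattering of the particle is adequately described by constant
per-atom (or per-residue) excess scattering lengths.

## Conventions

* Coordinates Å, momentum transfer q in Å⁻¹ (q = 4π sin θ / λ).
* Euler angles: intrinsic Z–Y–Z, degrees (`ZYZ-intrinsic-degrees`, stated in
  every serialized transform).  At gimbal lock (β ≈ 0 or 180°) the reported
  γ is 0 and the degeneracy is folded into α.
* `compose(a, b)` applies b first; placements are generator powers.
* Screw parameters: axis = rotation eigenvector with the sign making the
  angle ∈ (0, 180]; rise = translation·axis (signed); units per turn =
  360/angle.
* Twist–swing decomposition: R = R_swing ∘ R_twist with the twist about the
  declared main axis (the "shear" between protomers) and the swing about a
  perpendicular axis (the "closing hinge"), computed by quaternion
  projection.
* Superposition RMSDs for published-figure-style comparisons use CA atoms of
  matched residues; the selection is configurable.
* Interface area: full ΔSASA = SASA(a) + SASA(b) − SASA(a∪b), not halved,
  Shrake–Rupley with golden-spiral sampling (default probe 1.4 Å, 960
  points/atom); van der Waals radii tabulated per element, 3.5 Å for
  one-per-residue beads.

## Scattering model

Form factors are q-independent reduced scattering lengths: f = Z − ρ_s·V
with solvent electron density ρ_s = 0.334 e/Å³ and Fraser-style displaced
volumes (C 16.44, N 2.49, O 9.13, S 19.86, Se 28.73, P 5.73 Å³).  Hydrogens
are not tabulated in the reduced table (their reduced f is negative); use
heavy-atom selections or the vacuum table.  Bead models use one effective
residue scattering length (14 e, the excess of an average residue).
Adjustable excluded-volume and hydration-shell parameters (the c₁/c₂ of
full-featured profile predictors) are deliberately fixed at neutral: the
package's validation surface is synthetic-data recovery and model *ranking*,
where a global intensity scale is absorbed by the χ² scale factor anyway.
This is the main declared deviation from experimental-profile predictors
such as FoXS/CRYSOL.

The Debye sum is evaluated either exactly or on a pair-distance histogram.
Each bin stores Σw, the weighted mean distance and the weighted distance
variance, and the sinc kernel is corrected to second order
(sinc(qr̄) + ½·sinc″(qr̄)·q²·Var(r)), making the histogram error O(h⁴) in the
bin width h; at the default h = 0.1 Å the maximum relative error on 500-bead
sets is below 10⁻⁴ for q ≤ 0.5 Å⁻¹ (asserted against the brute-force double
sum).  For symmetric assemblies the scorer exploits that the pair-distance
multiset decomposes into intra-unit distances (multiplicity n) and
unit-0-to-unit-k cross blocks (multiplicity n−k), reducing a 6-unit model
evaluation to five small cdist blocks.  Grid scans score on a coarser
0.5 Å histogram (relative error ~10⁻⁵ with the variance correction, still
three orders of magnitude below the 2% noise floor), which makes the
transcendental kernel the same factor cheaper; profile-facing computations
keep the 0.1 Å default.

χ² uses the N−1 divisor and the closed-form optimal scale; model intensities
are interpolated onto the experimental grid linearly in (q, log I), and
extrapolation is an error.  Under the synthetic noise model the χ² of the
generating model calibrates to E[χ²] = 1 (asserted over 200 seeds).

Guinier fits iterate a weighted regression of ln I on q² to the q·Rg < 1.3
range.  The Porod exponent is the magnitude of the log–log slope over a
configurable range (default: the last decade of q where I > 10σ); note that
for oscillatory sphere-like profiles the fitted slope depends on the window
phase, and for bead models the incoherent self-term (Σf², flat in q) floors
the profile above u = qR ≈ (4.5·N)^¼ — the test fixes a window below that
crossover covering ~2 oscillation periods.

## Grid search

The grid covers (α, β, γ) at 1° steps over ±5° and (tx, ty, tz) at 1 Å
steps over ±3 Å around a starting transform (all configurable).  Candidate
models with any inter-unit atom pair closer than the clash cutoff (2.5 Å
heavy atoms, 3.5 Å CA beads — the short end of nonbonded contact distances,
so only genuine overlap counts) are excluded from ranking but counted, so
the filtering is auditable.

Three deterministic search modes are provided.  `product` enumerates the
full Cartesian grid (capped at 10⁶).  `sweep` iterates axis-aligned 1-D
scans from the running best point.  The default, `frontier`, is a best-first
lattice search: the lowest-χ² evaluated point is expanded by its
neighborhood moves (single-axis ±1, all two-axis ±1 diagonals, and the ±1
diagonals of the angle and translation triples), and expansion proceeds in
χ² order until `patience` expansions bring no improvement.  The reason is
the structure of the χ² surface: a screw generator conjugated by a small
rigid motion produces a nearly congruent assembly, so the surface has
curved, strongly coupled valleys — nearly flat along combinations such as
(Δα ≈ −Δγ at moderate β) and along translation directions (I−R)d with d
tangent to the ring — on which axis-aligned sweeps and even alternating full
3-D angle/translation block scans stall a few steps from the optimum.
Best-first expansion traverses slightly uphill intermediates in order and
reliably walks these valleys; on synthetic data at 2% noise it recovers the
true generator exactly at a few-thousand-model cost instead of the 4.6·10⁵
of the full product grid.  The frontier is warm-started by iterated axis
sweeps (every swept point seeds the heap), which cheaply positions the
expansion near the basin and removes traversal stalls across broad shallow
plateaus.

Identifiability note: exactly because of the conjugation structure, χ²
distinguishes lattice points only through the residual misplacement of the
*fixed* seed relative to the screw axis.  With the axis near the Euler
gimbal lock (β ≈ 0), α and γ are individually unidentifiable; synthetic
ground truths are therefore tilted by a fixed generic rotation before
recovery experiments.  Along the azimuthal/tangential conjugation family
the six raw parameters are not identifiable at realistic noise at all (a
tangential axis shift changes the seed-to-axis radius only to second
order), so recovery is judged on the conjugation-invariant screw
description — rotation angle, rise, axis direction, and the seed centroid's
distance from the axis (`screw_discrepancy`) — with the one-grid-step
equivalents 1° and 1 Å as tolerances.  A dense q grid matters for the same reason: model
discrimination scales as √N_q, and the default grid (201 points to
q = 0.5 Å⁻¹, typical of modern beamline binning) makes one grid step
statistically resolvable at 2% noise.

Continuous local refinement runs shrinking-step coordinate descent followed
by a Powell direction-set polish (scipy); plain coordinate descent zigzags
on the same curved valleys and can stagnate ~0.2° from the optimum.  The
refined χ² never exceeds the starting value.  Along near-flat conjugation
directions, parameter-space convergence is ill-conditioned even when the
model converges in coordinate space to < 0.2 Å; tests therefore assert
model-space convergence.

Model-class comparison scores the best open-helix model against closed 6-
and 7-ring radius scans (1 Å intervals; per-unit rotations 60° and
360/7 = 51.43°), ranking classes by best χ².  The open-ring termination
property is checked on the winning model: placing one more unit by the
recovered step must clash with the existing units while the rise per turn
stays below the unit height.

## Synthetic data

The generator emulates the study system at adjustable scale:

* Protomers: 230 beads (one per residue) in a triaxial ellipsoid of 40 Å
  long dimension (semi-axes 0.40/0.30/0.55 of the extent; Rg ≈ 0.33·extent),
  generically chiral; a four-rod "helix-bundle" variant exists.  Dimers pair
  an antiparallel copy (180° about x) at a ~4 Å closest-approach gap,
  giving a realistic contact patch for contact-based pairing.
* Assemblies: 6 units, 55° per unit, 2 Å rise, 40 Å radius.  These defaults
  are the open single-turn regime: construction is clash-free, six units
  span 330°, and the seventh unit clashes with the first across seeds at the
  default bead density.  Parameter-recovery experiments use 40-bead
  protomers (480-bead assemblies) so that thousands of grid models score in
  seconds; the model-selection and termination experiments run at the full
  230-bead scale.
* Noise: Gaussian with σ(q) = a·I(q) + b (default a = 0.02, b = 0) — the
  way third-column uncertainties behave in standard 3-column SAXS files, and
  analytically χ²-calibrated.  It does not emulate inter-point correlations,
  buffer-subtraction systematics, or concentration effects of real data, so
  passing recovery tests demonstrates correctness of the machinery, not
  robustness to real-data systematics.
* Alignments: i.i.d. per-column substitution (uniform over the 19 other
  residues) and gap insertion from a known consensus.  Real alignments are
  phylogenetically correlated; the recovery guarantee (exact consensus at
  10% substitution, 50 sequences; Hoeffding-type bound in the property
  tests) applies to the i.i.d. model.

All generator outputs depend only on (parameters, seed).

## Consensus design

Identity between aligned sequences counts matches over columns where at
least one sequence has a residue (dual-gap columns excluded).  Redundancy
filtering is greedy in input order: keep a sequence iff its identity to all
previously kept sequences is ≤ the threshold — deterministic, and the output
provably contains no pair above the threshold (the published filtering
utility's traversal order is unrecorded).  The consensus takes the most
frequent residue per column among non-gap symbols; columns with an absolute
gap majority are dropped (configurable); ties break by the fixed order
ARNDCQEGHILKMFPSTWYV and are flagged so designed sequences are auditable.
Support = winning residue count / non-gap count per column.

## Structure I/O

PDB/mmCIF reading and writing delegate to gemmi (gzip-transparent).  Only
the highest-occupancy alternate conformer is kept; waters always excluded
and other non-amino-acid heteroatoms excluded by default; MSE is renamed MET
(selenium element retained for scattering).  Assemblies are written as
distinct chains with a recorded copy→chain map; the fixed-column PDB dialect
is limited to 62 single-character chain ids (beyond that, mmCIF is
required).  Coarse-graining places one bead per residue exactly on the CA.

## Problem sizes and determinism

Default experiment sizes were chosen so the full test suite and the
acceptance script each run in minutes on one CPU: 500-bead Debye oracles,
200 χ²-calibration replicates, 20 recovery seeds on 480-bead assemblies
(~1–2·10³ scored models each), one full-scale (2760-bead) model-selection
run, 50-sequence alignments.  Every stochastic step is seeded; grid searches
are deterministic by construction, so identical inputs give identical ranked
outputs.

## Known limitations

* No hydration shell or excluded-volume fitting; absolute intensities are
  not modeled, only shapes up to scale.
* No P(r) inversion, ab initio bead reconstruction, or flexible/ensemble
  fitting; the subunit is strictly rigid and the assembly strictly
  symmetric (no multi-body refinement with contact restraints).
* Printed experimental values that depend on the non-deposited measured
  profile (a best-fit χ² of 2.83, a Porod exponent of 3.8) are context, not
  reproducible targets; the synthetic-data properties above are the
  package's validation surface.
* Crystal-symmetry expansion from CRYST1/space-group records is out of
  scope; assemblies are always built explicitly.
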