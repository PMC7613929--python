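# Methods

This note documents the models, conventions and numerical choices behind
filageom, what the synthetic generators do and do not emulate, and the
design decisions made where more than one convention was defensible.

## Coordinate model

Structures are read with gemmi (PDB and mmCIF) into a minimal
chains→residues→atoms hierarchy in Å.  On reading, hydrogens/deuteriums
and waters are dropped, and alternate locations are resolved by keeping
the highest-occupancy conformer (ties broken by the lexicographically
first altloc tag) — deterministic and standard practice.  Author residue
numbering is used throughout; no alignment-based residue mapping is
performed (for the FtsA systems the package targets, E. coli and
V. maritimus positions coincide, so identity mapping suffices).
Symmetry operators found in a file header (NCS records, first-assembly
generators) are retained; full space-group generation from a symbol is
deliberately out of scope — operators must be materialised in the file or
supplied as plain-text 3×4 blocks.  Writing: PDB at 3-decimal precision
(round-trip ≤ 1e-3 Å), mmCIF better than 1e-5 Å; more than 62 chains
cannot be expressed in PDB chain ids and either raises (strict mode) or
falls back to mmCIF.

## Rigid geometry

Superposition is unweighted Kabsch (SVD with a determinant correction so
reflections are never returned).  Screw decomposition takes the rotation
axis/angle from the rotation matrix, the rise as the translation
component along the axis, and the axis point as the minimal-norm solution
of `(I − R)p = t_perp` projected perpendicular to the axis.  The
`(d, θ) ↔ (−d, −θ)` ambiguity is resolved deterministically: direction
chosen so rise ≥ 0 when nonzero, else so twist ≥ 0; at twist 180° with
zero rise the direction's largest-magnitude component is made positive.
Twists below 1e-6° and rises below 1e-6 Å are treated as zero
(configurable); pure translations are flagged, never raised.  Verified
properties: 1000-transform decompose/recompose round trip ≤ 1e-8 Å on
test points; twist invariance under conjugation.

For noisy filaments the subunit operator is best estimated jointly:
`filament_screw` stacks all consecutive-pair matched coordinates into one
superposition and then refines the six screw degrees of freedom by
least squares over *all* ordered chain pairs under the power constraint
chain_k ≈ g^(k−j)(chain_j).  The whole filament then acts as the lever
arm; single-neighbour transforms are markedly noisier, especially in the
axis direction and position.  Recovery metric used by the tests: twist
and helical radius to 1% relative, rise to 1% relative with a 0.1 Å
absolute floor — a purely relative bound on the rise is statistically
unattainable near rise = 0 (the estimator's variance floor at σ = 0.2 Å
coordinate noise is ~0.03 Å for near-ring geometries; we verified the
optimiser reaches residuals below those at the generating truth, so this
is an information limit, not an implementation defect).

## Interfaces and classification

A contact is a residue pair with minimum heavy-atom distance ≤ 4.5 Å; an
interface requires ≥ 5 such pairs (standard quaternary-contact practice;
both configurable).  Polar contacts are any inter-chain N/O–N/O pair
≤ 3.5 Å with no angle term — deliberately simple, since the intended use
is *counting* hydrogen-bond-like contacts comparably across structures
(e.g. contacts lost upon filament bending), not assigning chemistry.

Classification is driven by the relative twist of the chain-to-chain
superposition: < 60° → longitudinal (near-parallel subunits),
∈ [150°, 180°] → lateral (antiparallel), else other.  Longitudinal
interfaces are *tight* when ≥ 3 residue pairs connect one subunit's
IIA/IIB ranges to the partner's nucleotide face (IA/IIA), else *loose*.
Lateral sub-types are split by the registry offset — the projection of
the inter-centroid vector onto the protofilament axis — against a
quarter of the longitudinal repeat: below → in-register (i–i*), above →
offset (i–i*−1).  Axis and repeat are bootstrapped from the longitudinal
interfaces' inter-centroid displacements (not their screw axes: for a
near-pure translation the screw axis direction is dominated by whatever
tiny rotation the coordinates carry).

Local C2: the chain1→chain2 superposition transform is tested for being
an involution.  Tolerances: |twist − 180°| ≤ 5°, |rise| ≤ 1.5 Å, mapping
RMSD ≤ 2 Å (configurable) — local symmetry in a crystal is approximate.
A translation of one chain along the symmetry axis appears directly as
the operator's rise; a parallel (translation-related) dimer yields twist
≈ 0 and is rejected.

The filament graph has subunits as nodes and classified interfaces as
edges.  Protofilaments are the maximal simple paths over longitudinal
edges; cyclic paths are reported as closed rings (not errors); branched
longitudinal subgraphs are reported with the longest simple path and a
warning.  A component is called a double filament when it contains
exactly two protofilaments joined by at least one lateral edge per two
subunits.

## Helical parameters, rings, curvature, diameters

Subunits per turn is `360/|twist|`; handedness is right iff twist and
rise share a sign under the module's convention, none if either
vanishes.  Ring closure scans integer n ∈ [3, 100] minimising
`|360 − n·|twist||` (ties → smaller n) and accepts a ring when that
deviation ≤ 3° and the accumulated rise `|n·rise| ≤ 5 Å` (all
configurable).  Curvature: points are projected onto their principal
plane, a Kåsa algebraic circle fit provides the start for a geometric
least-squares refinement; collinear inputs return an infinite-radius
flag.  Filament diameter is reported two ways — twice the mean
perpendicular centroid distance from the screw axis (the *centroid-path*
diameter, used for mini-ring comparisons) and twice the maximum atom
distance (*envelope*).  Which of the two a microscopy-derived "ring
diameter" corresponds to is genuinely ambiguous; both are always
reported and the centroid path is the headline number.  For crystal
tetramers the declared curvature convention is: whole-subunit centroids
of all four chains, one circle fit in their common plane (the published
value's method is not stated anywhere we could follow; agreement is
therefore only tested with a generous tolerance).

## Domains and hinges

Principal axes are eigenvectors of the unit-mass covariance of main-chain
(N, CA, C) coordinates — unit masses because only the atom set, not a
weighting, is part of the published convention.  Axes are ordered by
descending spatial extent; signs are fixed canonically, and domain
arrows additionally anchor the first axis to point from the N-terminal
toward the C-terminal half of the domain, making arrows comparable
across structures.  Moment pairs within 1% of each other (or both
vanishing — collinear input) set a degeneracy flag rather than raising;
only < 3 points or fully coincident points are errors.

Hinge rotation is a simplified two-body analysis: superpose conformer B
onto A over the fixed-domain main-chain atoms, then superpose the
(already aligned) mobile-domain atoms and report that second rotation's
angle and screw axis.  This replaces full dynamic-domain segmentation by
design; comparisons against values derived with segmentation tools are
made at ±1.5°.  FtsA domain boundaries ship as an editable config
(approximate actin-fold subdomain ranges on the 1–396 scale: IA 1–87 +
373–396, IC 88–163, IIA 164–245 + 309–372, IIB 246–308); no structure
prints exact boundaries, so every report records the boundary set used
and users should refine them per structure.

## Cross-link design

Candidate sites are ranked by wild-type Cβ–Cβ distance across classified
interfaces (Cβ position is essentially mutation-invariant, so in-silico
mutation is unnecessary).  A linker is compatible when the distance is
at most span + 3 Å; distances below span − 3 Å are flagged "shorter than
span" (a shorter-armed reagent may perform better).  Only BMOE's ~8 Å
span ships as a default; other reagent spans must be user-supplied
rather than invented.  Glycine sites are skipped with a warning (strict
mode raises).  Background screening reports, per candidate, the minimum
inter-chain Cβ–Cβ distance to any endogenous cysteine across every
interface and orientation; distances below 12 Å are flagged as
off-target risk.  C2-symmetric interfaces additionally support
single-mutation designs (same residue number on both chains); requesting
them on a non-C2 interface warns but still computes.

## Binding models

Ordinary (unweighted) nonlinear least squares with positivity bounds on
the dissociation constants and amplitudes; 5 jittered initialisations
(fixed internal seed — fits are deterministic) with the best residual
winning.  Single-site initials: Kd at the concentration nearest the
half-range response, Rmax from the response range, B from the minimum.
Two-step initials place the Kds at the 20th/80th concentration
quantiles.  Labels are assigned so Kd_Lo ≤ Kd_Hi; a fitted ratio below
10 triggers an identifiability warning, and a Kd_Hi above the titrated
range is flagged as uncovered.  Standard errors come from the Jacobian
at the optimum.  Two-transition tables from other techniques (e.g.
weight-average sedimentation isotherms) can be fitted with the same
two-step model; no sedimentation modelling is implemented.

## Synthetic generators: what they emulate, and what not

Pseudo-protomers are rigid, asymmetric arrangements of pseudo-residues
(N/CA/C/CB atom names, so all real-structure code paths run unchanged)
threaded along a smooth curve: ~58 Å long (so a 48 Å repeat gives
head-to-tail contact), with two flat-top lateral ridges emulating the
two lateral contact patches of a filament subunit — a double filament
built from them reproduces both lateral registries simultaneously, as in
the real antiparallel filament where each subunit touches two opposing
subunits.  The default double filament uses a pure-translation
longitudinal operator (48 Å), a registry shift of −8 Å, and a lateral
contact gap of 2.6 Å tuned at build time so every designed interface
clears the ≥ 5-residue-pair detection threshold even at σ = 0.3 Å noise.
Protofilament B is the exact 180° image of A, so every contacting
lateral pair carries *exact* local C2 by construction; the truth record
enumerates all interfaces by brute-force O(n²) residue-pair counting,
independent of the detection pipeline's spatial indexing.

Default conditions mirror the FtsA systems: 48 Å longitudinal repeat,
mini-ring twist 360/13° at 100 Å helical radius (20 nm centroid-path
diameter), arc curvature radius 16.3 nm, single-site truth Kd 0.8 μM
(12-point 1:2 dilutions from 10 μM), two-step truths 0.016/11 μM
(16-point 1:2 dilutions from 40 μM), 2% response noise.

What the generators do **not** emulate: real side chains and packing,
sterics and electrostatics, B-factors/occupancy disorder, crystal
lattice contacts, conformational heterogeneity, and measurement error
structure beyond i.i.d. Gaussian noise.  Passing the synthetic suite
therefore demonstrates the geometry and estimation machinery is correct
under known ground truth — it does not by itself validate biological
conclusions on deposited structures, which is what the accession-based
regression tests are for (they require the user to download the public
coordinate files; see README).

## Problem sizes

The test suite and acceptance script use 120-atom protomers, filaments
of 2–13 subunits, 50-draw parameter sweeps, 1000-transform screw
round trips and 25–200 isotherm replicates — sizes chosen so the whole
synthetic validation runs in well under a minute on one CPU while
keeping every estimate's sampling error far below the tolerances tested.

## Known limitations

* Interface classification assumes roughly rigid, identical subunits;
  strongly bent or conformationally mixed filaments may need per-pair
  inspection of the reported twist evidence.
* The curvature convention for 4-subunit crystal oligomers is a declared
  choice among several defensible ones (see above).
* Hinge angles from the two-body analysis can differ by up to ~1–2°
  from segmentation-based tools, depending on the fixed-domain choice.
* Polar-contact counting has no geometry beyond distance; it is a
  comparative, not a chemical, measure.
* Space-group expansion from symbols is unsupported by design; supply
  materialised operators.
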