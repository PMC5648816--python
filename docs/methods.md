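# Methods

## The measurement model

A weak alignment medium (filamentous phage, or a C12E5/hexanol liquid
crystal) gives a dissolved protein slightly anisotropic tumbling, which
re-introduces the ¹H–¹⁵N dipolar coupling in attenuated form.  The residual
coupling for the amide of residue *i* is

  *D*ᵢ = uᵢᵀ *A* uᵢ ,

with uᵢ the unit N→H bond vector and *A* the Saupe alignment tensor — a
symmetric traceless 3×3 matrix with five independent elements, handled
directly in Hz (the dipolar prefactor is absorbed into *A*; no gyromagnetic
constants appear anywhere in the package).  In the principal frame the same
coupling reads *D* = *D*ₐ[(3cos²θ−1) + (3/2)*R* sin²θ cos 2φ] with axial
magnitude *D*ₐ = *S*zz/2 and rhombicity *R* = (2/3)(*S*xx − *S*yy)/*S*zz
∈ [0, 2/3] under the ordering |*S*zz| ≥ |*S*yy| ≥ |*S*xx|.  Principal axes
are reported as z-y-z Euler angles; exact eigenvalue degeneracies are
broken deterministically (lexicographic eigenvector comparison, largest
component made positive) so repeated runs decompose identically.

Couplings are static-structure idealizations: measured RDCs are time
averages over thermally accessible conformers, so refined structures
represent averaged positions of secondary-structure elements, not unique
conformations.

## Tensor fitting

Five or more couplings with sufficiently diverse bond orientations
determine *A* linearly.  `fit_tensor_svd` solves the least-squares system
in the basis (Axx, Ayy, Axy, Axz, Ayz) by singular value decomposition,
refusing rank-deficient geometry (smallest singular value below 10⁻⁸ of the
largest — e.g. all bond vectors parallel).  Quality is summarized by the
Q-factor, rms residual and per-record residuals.  A practical consequence
used throughout the validation experiments: an α-helix contributes
essentially one N–H orientation family, so helix-only record sets pin the
tensor poorly; mixed helix/strand topologies are needed to condition the
fit.

## Restraint energy

Each record contributes a linear flat-bottom penalty

  *E*ᵢ = *k* · max(0, |Δ*D*ᵢ| − τ),  Δ*D*ᵢ = *D*obs − *D*calc,

with tolerance τ = 3 Hz (matching the stated measurement uncertainty) and
force constant *k* in kcal mol⁻¹ per Hz of violation.  The linear form
follows from the units of the published constants (0.001 → 0.01
kcal mol⁻¹ Δ*D*⁻¹); a harmonic variant is available behind the ``form``
switch for sensitivity checks.  Records flagged as persistent violators or
excluded contribute zero energy but remain in every report.

## The annealing engine

The refinement engine is a deliberately simplified, deterministic surrogate
for solvent-phase restrained molecular dynamics.  Each increment:

1. perturbs all coordinates with seeded Gaussian noise whose amplitude
   cools geometrically across the run (default 0.05 Å → 0.0025 Å);
2. minimizes (L-BFGS) the sum of per-medium RDC terms — tensors held fixed
   within the increment — and a harmonic stereochemical reference energy;
3. refits each medium's tensor to the relaxed coordinates;
4. records a snapshot (structure, tensors, restraint energies, Q-factors).

The RDC force constant ramps geometrically from 0.001 to 0.01
kcal mol⁻¹ Hz⁻¹ across increments; "gradually increased" is realized as
geometric spacing because it covers the decade evenly on a log scale.
Both alignment media are restrained simultaneously, one tensor each, with
equal weight, and tensors are refit per increment (whether the original
computations refit per snapshot or jointly is not stated; per-increment
refitting is this package's choice and is reported as such).

### Stereochemical reference model

Instead of a force field, local geometry is held by harmonic restraints to
the start structure's internal coordinates:

| term | pairs | k (kcal mol⁻¹ Å⁻²) |
|------|-------|-----|
| bonds | N–H, N–CA, CA–C, C–O, peptide C–N | 100 |
| angles (1-3 distances) | across every backbone angle | 30 |
| peptide-plane impropers | amide H and carbonyl O out-of-plane height | 30 |
| torsion regularizers (1-4 distances) | C(i−1)–C(i), N(i)–N(i+1), CA(i)–CA(i+1) | 2 |
| hydrogen bonds | start-structure O(i)···N(i+3/4) pairs within 3.5 Å | 10 |

The improper and 1-4 terms exist because a pure distance network has exact
floppy modes: the amide H and carbonyl O out-of-plane coordinates are
second-order in every pairwise distance, and unregularized torsions drift
under the per-increment noise, both of which reorient N–H vectors and put a
floor under the attainable Q.  The 1-4 constant is kept small so that
hinge-like motions — which change only a few torsions — remain soft modes
the RDC restraints can drive.

### Centering term and the method's resolution limit

A flat-bottom penalty exerts no force once every record is within τ, so the
refined structure stalls anywhere inside a force-free plateau whose width is
the method's intrinsic resolution: for a rigid-body rotation the stall
angle is roughly τ divided by the largest |d*D*/dθ| among the moving
records, further degraded because the per-increment tensor refit absorbs
part of any collective motion (in proportion to the moving records'
share of the fit leverage).  Under the hinge-recovery conditions below
this plateau is ±4–5°.

To let refinement settle at the data's least-squares optimum rather than at
the plateau edge, the minimizer adds a weak harmonic data term
*w*·*k*·Δ*D*²/(2τ) per active record (``centering_weight`` *w* = 0.1 by
default) — at the tolerance edge its force is one tenth of the violation
force.  This term exists only inside the minimizer: all reported violation
energies, the trajectory log and persistent-violator detection use the
exact flat-bottom form, and *w* = 0 restores a pure flat-bottom drive.

### Violator bookkeeping

A record is a persistent violator when its flat-bottom violation is
positive in at least 80 % of the last 10 increments (both fraction and
window are configurable; the criterion distinguishing measurement error
from genuine local-alignment effects is not derivable from the data, so
flagging is by persistence only and interpretation is left to the user).
Flagged records keep their Δ*D* in every report but stop contributing
energy and leave the tensor fits.  Detection is run iteratively (two
rounds by default): a single round inherits false positives from the
outliers' own drag on the least-squares tensor, which re-fitting without
the flagged records removes.

### Ensemble and representative

`select_ensemble` takes the *n* snapshots of lowest total violation energy
(both media summed — whether the published per-structure violation energies
sum both media is not stated; summing is this package's choice), ties
broken toward the earlier increment; the default ensemble size is 10.
`representative` superposes all members on the first over Cα, averages the
coordinates, and returns the member of minimal Cα RMSD to that average —
the analogue of choosing a representative conformer closest to the
ensemble mean.

## Comparison analytics

* **Superposition** — Kabsch SVD with determinant correction; refuses
  < 3 or collinear matched atoms; the mobile structure is never mutated.
* **Screw axis** — the rigid transform best mapping a selection between
  two states (after the caller superposes the anchor region) decomposed
  into rotation axis, angle, axial translation, and the axis point closest
  to the selection centroid.  Rotations under 0.5° are flagged unreliable.
* **Helix-axis rotation** — the target helix is locally superposed onto
  the source over Cα, the helix axis is the principal inertia axis of the
  source Cα trace (oriented N→C), and the mean reorientation of the
  Cα→O carbonyl vectors about that axis is reported, positive = clockwise
  viewed from the N-terminus.  Note that a *rigid* rotation of the whole
  helix is removed by the local superposition; the quantity measures
  crankshaft-like reorientation of the peptide planes relative to the Cα
  trace, which is what distinguishes the two states of a helix whose
  backbone barely translates.
* **H-bonds** — for acceptor *i* the candidates C=O(*i*)→NH(*i*+3) and
  C=O(*i*)→NH(*i*+4) qualify when O···N ≤ 3.5 Å and, where an amide proton
  exists, the N–H···O angle ≥ 120° (no geometric criterion is inherited
  from the source data; these are standard backbone values and are
  configurable).  Each donor is classified by its shortest qualifying
  candidate; both candidate distances are always reported.
* **Identity** — sequence identity uses a BLOSUM62 affine-gap alignment
  (open 11, extend 1; global or local), identity = identical / aligned
  columns with gap columns excluded from the denominator.  Positional
  identity scores an explicitly supplied residue-pair correspondence; a
  correspondence is never inferred silently.
* **Morphs** — linear Cartesian interpolation between superposed states
  (rotational "corkscrew" interpolation is out of scope).

## Synthetic data

`make_structure` builds backbone-only (N, H, CA, C, O) chains from ideal
internal coordinates — α: φ=−57°, ψ=−47°; 3₁₀: φ=−49°, ψ=−26°; strand:
φ=−119°, ψ=113°; coil: φ=−75°, ψ=145° (polyproline-II-like) — with
standard bond lengths/angles, ω = 180°, the amide H on the external
bisector of C(i−1)–N–CA at 1.02 Å (none on the chain-initial residue), and
the carbonyl O trans to the next amide nitrogen.  `simulate_rdc_sets` adds
per-medium Gaussian noise and plants a seeded subset of outliers with a
15 Hz offset whose sign inflates the coupling magnitude by default
(emulating increased local alignment at exposed sites; a switch randomizes
the sign).  `apply_hinge` rotates a residue range rigidly about an axis
through its first Cα.  All outputs are deterministic under a fixed seed.

Default generator media are *D*ₐ = 10 Hz (*R* = 0.25) and −7 Hz
(*R* = 0.45) — mid-range amide alignment strengths.  What the generator
does **not** emulate: side chains, realistic loop geometry, solvent,
dynamic averaging, or medium–protein interactions; passing tests therefore
demonstrate the correctness of the restraint logic and analytics on rigid
idealized systems, not performance on experimental data.

## Canonical validation experiments

**Hinge recovery** (`hinge_recovery_spec`): a 47-residue two-body toy —
anchor helix+strand+helix (residues 1–32), mover strand+helix (33–47), both
mixing secondary-structure kinds so each body conditions all five tensor
degrees of freedom — with a planted 10° rotation of the mover and 1 Hz
noise in two media.  The alignment tensors (*D*ₐ = 25 Hz, *R* = 0.3;
*D*ₐ = −18 Hz, *R* = 0.5) sit at the strong end of amide RDC practice
because of a detectability condition fixed before running the experiment: a
10° rotation must move couplings beyond the ±3 Hz flat bottom *after* the
refit tensor absorbs its share of the motion, which requires a
principal-value spread of order 90 Hz.  The refined structure recovers the
hinge to within ~2° across seeds; the screw-axis decomposition alone
(structure-to-structure, no refinement) recovers the planted transform to
better than 0.1°.

**Outlier screen** (`outlier_screen_spec`): 101 residues, one medium, 100
couplings, five planted 15 Hz magnitude-inflating outliers on 1 Hz noise.
Two-round iterative detection recovers all planted outliers with at most
one false positive per seed.

Problem sizes (47–101 residues, 15–30 increments, 300–400 minimizer steps
per increment, five seeds per experiment) are chosen so the full validation
suite and the acceptance script each complete in minutes on a single core
while leaving every measured margin comfortably clear of its threshold.

## Numbering, formats, limitations

Author (PDB) residue numbering is authoritative everywhere; a global
numbering offset utility maps between conventions (e.g. a solution
structure numbered −4 relative to the crystal structure), shifting
annotation ranges along with residues.  PDB I/O is fixed-width via biotite;
insertion codes are rejected, heteroatoms are parsed but excluded from all
vector and superposition selections, and no hydrogen building is attempted
(residues lacking an amide H are skipped and counted).  RDC tables are
whitespace-delimited text (`medium residue atom_pair observed_hz
[uncertainty_hz]`, `#` comments, default uncertainty 3 Hz).  Only backbone
¹⁵N–¹H couplings are supported; multi-nucleus RDCs, order-parameter
averaging and paramagnetic effects are out of scope.
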