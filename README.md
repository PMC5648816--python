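# rdcrefine

Residual dipolar couplings (RDCs) measured on a weakly aligned protein
report the orientation of each amide N–H bond relative to a molecular
alignment frame.  For cytochrome P450s such as MycG and CYP101A1, RDC sets
measured with and without substrate resolve the solution conformers on
either side of substrate binding — free of crystal-packing constraints —
and make the substrate-dependent conformational change itself measurable:
domain rotations, helix displacements, and switches between α-helical
(*i*,*i*+4) and 3₁₀ (*i*,*i*+3) backbone hydrogen bonding.

`rdcrefine` implements that workflow as a reusable Python library:

* **Alignment-tensor mathematics** — the coupling back-calculated from a
  Saupe tensor *A* (symmetric, traceless, in Hz) is *D*(u) = uᵀ*A*u;
  equivalently *D* = *D*ₐ[(3cos²θ−1) + (3/2)*R* sin²θ cos2φ] in the
  principal frame.  Five or more couplings with diverse bond orientations
  determine *A* by SVD least squares; fit quality is the Q-factor
  Q = rms(*D*obs − *D*calc)/rms(*D*obs).
* **Restrained annealing** — a desk-scale surrogate of RDC-restrained
  molecular dynamics: perturb–minimize increments under a linear
  flat-bottom penalty *k*·max(0, |Δ*D*| − 3 Hz) per coupling with the
  force constant ramped 0.001 → 0.01 kcal mol⁻¹ Hz⁻¹, per-increment
  tensor refitting, persistent-violator detection with iterative
  correction, lowest-violation ensemble selection, and a
  closest-to-average representative conformer.
* **Conformational comparison** — Kabsch Cα superposition, per-residue
  displacement profiles, screw-axis (axis/angle/pivot) decomposition of
  domain motions, rotation of a helix about its own long axis, backbone
  H-bond pattern classification, pairwise sequence and positional
  identity, and linear morph export.
* **Synthetic data** — toy proteins built from ideal backbone internal
  coordinates, couplings simulated from known tensors with Gaussian noise,
  planted magnitude-inflated outliers, and planted rigid-body hinges, so
  every stage can be validated against exact ground truth.

## Worked example

```python
import numpy as np
from rdcrefine import compare, rdc, refine, structure, synthetic

# a 47-residue toy with a known 10-degree hinge in residues 33-47
spec = synthetic.hinge_recovery_spec(seed=1)
start = synthetic.make_structure(spec)
lo, hi = synthetic.HINGE_RECOVERY_RANGE
target = synthetic.apply_hinge(start, (lo, hi),
                               synthetic.HINGE_RECOVERY_AXIS, 10.0)

# couplings measured on the *moved* state, 1 Hz noise, two media
rdc_sets, truth = synthetic.simulate_rdc_sets(target, spec)

# refine the unmoved start structure against those couplings
sched = refine.RestraintSchedule(n_increments=30, steps_per_increment=400,
                                 anneal_noise=0.05, seed=1)
traj = refine.run_soft_annealing(start, rdc_sets, sched)
final = traj.snapshots[-1].structure

# quantify the recovered motion
sup = compare.superpose(final, start, selection=set(range(1, lo)))
screw = compare.screw_axis(start, sup.transformed, set(range(lo, hi + 1)))
print(f"recovered hinge angle: {screw.angle_deg:.2f} deg")
print(f"final Q-factors: { {m: round(q, 3) for m, q in traj.snapshots[-1].q_factors.items()} }")
```

Output:

```
recovered hinge angle: 8.20 deg
final Q-factors: {'pf1': 0.025, 'c12e5': 0.031}
```

The refinement, driven only by the simulated couplings, rotates the
C-terminal body to within 2° of the planted 10° hinge; the residual
Q-factors reflect the 1 Hz measurement noise against couplings of tens of
Hz.  With ±3 Hz flat-bottom restraints this ~2° residual is at the
method's intrinsic angular resolution (see `docs/methods.md`).

A command-line interface wraps the same stages
(`rdcrefine make-fixtures | fit-tensor | refine | compare`).

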