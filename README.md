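# hbquat

Trajectory analysis of the quaternary (T ↔ R) and tertiary (t ↔ r)
transitions of tetrameric human hemoglobin A.

Hemoglobin's cooperative oxygen binding rests on a quaternary transition
between the deoxy **T** state (PDB 2HHB) and liganded **R**-like states
(**R** 1IRD, **R2** 1BBB, **RR2** 1MKO, **R3** 1YZI): to first order a
12–15° rotation of one αβ dimer relative to the other, accompanied by
internal (tertiary) rearrangements of the four subunits. `hbquat`
provides the reaction-coordinate machinery to detect and characterize
these transitions in conformational ensembles — molecular-dynamics
trajectories stored as multi-model PDB, or synthetic morphs with exact
ground truth — for structural biologists and simulation groups studying
allosteric mechanisms.

## What it computes

* **X-ray PCA subspace** — principal components of the positional
  covariance of the T, R and R2 crystal structures over Cα + heme atoms.
  With three references exactly two eigenvalues are nonzero; projections
  onto these "X-ray eigenvectors" place any conformation in the R–R2–T
  plane.
* **rotRMSD** — superpose only the α1β1 dimer backbone onto the
  reference, then evaluate the backbone RMSD of the α2β2 dimer without
  refitting. A pure inter-dimer rotation survives the anchoring, making
  this distance far more sensitive to the quaternary state than the
  conventional fitted RMSD (0.53 nm vs 0.24 nm between R and T).
* **Normalized difference-vector coordinates** — project a conformation
  x onto the unit displacement between two endpoint structures,

      q(x) = ( (x_fit − x_mid) · d ) / h,   d = (x_T − x_R)/|x_T − x_R|,

  scaled so the endpoints map to +1 (T/t) and −1 (R/r); h is the
  half-span, half the coordinate-space distance between the endpoints.
  The quaternary coordinate uses the whole Cα + heme selection; the
  per-subunit tertiary coordinates use one subunit with subunit-internal
  superposition. Values beyond ±1 are legitimate outputs.
* **Rigid-body rotation** — the α2→β2 center-of-mass axis and the full
  optimal rotation (axis + angle) of the α2β2 dimer after anchoring
  α1β1, recovering the classic quaternary rotation angle.
* **Quaternary-state populations** — frames with normalized quaternary
  projection < −0.5 are assigned R, > +0.5 T (strict inequalities);
  tertiary-coordinate histograms are accumulated per quaternary state.
* **Mutual information** — coupling between reaction coordinates via
  I(X,Y) = Σ P(x,y) ln[P(x,y)/(P_X(x)P_Y(y))] on 2-D histograms, with
  the finite-sample bias removed by computing the MI on random
  subsamples and extrapolating linearly in k = 1/n to k = 0.
* **Synthetic generator** — abstract four-chain tetramers whose
  endpoints differ by a pure dimer rotation plus subunit-internal
  deformations, morphed with tunable per-subunit coupling, lag and
  noise, so every stage of the pipeline can be validated against exact
  ground truth.

## Worked example

```python
import numpy as np
from hbquat import (make_toy_tetramer, MorphSpec, make_transition_trajectory,
                    build_difference_vector, project_series,
                    assign_quaternary_state, rot_rmsd, classify_transition,
                    mi_matrix)
from hbquat.subspace import ProjectionSeries

toy = make_toy_tetramer(n_res_per_subunit=12, quat_angle_deg=14.0,
                        tert_amplitude=0.1, seed=3)
frames, truth = make_transition_trajectory(toy, MorphSpec(seed=42))

dv_quat = build_difference_vector(toy.endpoint_T, toy.endpoint_R)
quat = project_series(frames, dv_quat, "quat")

rr = ProjectionSeries(quat.frame_times,
                      [rot_rmsd(f, toy.endpoint_R) for f in frames],
                      "rotrmsd", kind="nm")
print(f"quaternary projection: {quat.values[0]:+.3f} -> {quat.values[-1]:+.3f}")
print(f"rotRMSD to R: {rr.values[0]:.3f} nm -> min {rr.values.min():.3f} nm "
      f"=> transition: {classify_transition(rr, cutoff=0.3)}")

coords = {"quat": quat}
for s in ("alpha1", "beta1", "alpha2", "beta2"):
    dv = build_difference_vector(toy.endpoint_T, toy.endpoint_R,
                                 "tertiary", subunit=s, labels=("t", "r"))
    coords[s] = project_series(frames, dv, s)
for (a, b), est in mi_matrix(coords, [("quat", s) for s in
                                      ("alpha1", "beta1", "alpha2",
                                       "beta2")], seed=0).items():
    print(f"MI({a}, {b}) = {est.value:.2f} nats")
```

prints

```
quaternary projection: +0.892 -> -0.961
rotRMSD to R: 0.345 nm -> min 0.031 nm => transition: full
MI(quat, alpha1) = 0.27 nats
MI(quat, beta1) = 1.24 nats
MI(quat, alpha2) = 0.31 nats
MI(quat, beta2) = 1.28 nats
```

The morph starts at the T endpoint (+1 on the quaternary coordinate),
ends at R (−1), and dips below the 0.3 nm rotRMSD cutoff that defines a
full transition. With the default generator couplings (β 0.9, α 0.1)
the mutual information correctly reports the β subunits as far more
strongly coupled to the quaternary transition than the α subunits — the
asymmetry the analysis is designed to expose.

A command-line interface mirrors the library:
`hbquat simulate`, `hbquat project`, `hbquat rigidbody`,
`hbquat populations`, `hbquat mi`, `hbquat run --config analysis.cfg`,
and `hbquat anchors --pdb-dir data/xray` for the crystal-structure
benchmark numbers.

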