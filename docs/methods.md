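# Methods

This note records the models, estimators and numerical conventions
implemented in `hbquat`, the choices made where several defensible
options existed, and what the synthetic validation does and does not
demonstrate about real data.

## Structures, selections and units

Coordinates are handled in nanometres throughout; PDB files (Å) are
converted on read and write. Chains are mapped to subunits as
A→α1, B→β1, C→α2, D→β2 (the convention of the 2HHB/1IRD/1BBB entries),
overridable per analysis. HETATM residues named HEM are labeled as the
heme group of their chain's subunit; all other heteroatoms are labeled
`other` and never selected. Hydrogens are dropped on read; alternate
locations are resolved by highest occupancy (ties by altloc
identifier). Three selection modes exist: `calpha_heme` (the Cα trace
plus heme atoms — the atom set of the PCA subspace and the
difference-vector coordinates), `backbone` (N, Cα, C, O — used for
superpositions and rotRMSD), and `all` (every heavy atom — used for
centers of mass). Before any cross-structure comparison, selections are
intersected on the key (chain, residue number, atom name), so
structures that resolve slightly different atom sets still yield
equal-length coordinate arrays.

Superpositions are weighted Kabsch fits (proper rotations only,
`scipy.spatial.transform.Rotation.align_vectors`); the residual RMSD is
re-evaluated from the transformed coordinates rather than taken from
the solver, which loses precision near zero. For degenerate (e.g.
collinear) point sets the rotation about the degenerate axis is
underdetermined and the solver's representative is returned — a
documented fallback rather than an error.

Centers of mass are mass-weighted over the heavy atoms of one polymer
subunit; hemes are excluded so the COM tracks the globin chain itself.

## rotRMSD

The rotation-sensitive distance to a quaternary state: superpose the
α1β1 dimer backbone of the frame onto the reference, then evaluate the
backbone RMSD of the α2β2 dimer against the same reference *without*
refitting. A pure rotation of one dimer relative to the other survives
the anchoring, so this measure separates quaternary states that the
conventional fitted RMSD compresses (0.53 nm vs 0.24 nm between the R
and T crystal structures). Both superposition and evaluation use one
and the same reference structure; hemes are excluded from the backbone
selection. A trajectory is classified as a *full* transition when its
rotRMSD to the target dips below 0.3 nm, as *partial* when it at least
halves its initial value without reaching the cutoff (the halving rule
is a package convention — no published definition of "partial" exists),
and *none* otherwise.

## The X-ray PCA subspace

The positional covariance of the reference crystal structures (Cα +
heme atoms, common-atom intersected) is diagonalized after iterative
superposition of the references onto their running mean. The iteration
is run to its fixed point (each structure optimally aligned to the mean
of the aligned set, max coordinate shift < 1e-12 nm) rather than a
fixed small number of rounds: at the fixed point, re-aligning any
reference onto the stored mean reproduces the stored coordinates
exactly, which makes the reference projections exactly isometric (k
centered configurations span at most k−1 dimensions, so three
references lie exactly in the plane of the two leading eigenvectors).
Eigenvalues use the covariance divisor k. Eigenvector signs are fixed
so the T reference projects non-negatively — a plotting convention
only. Frames are superposed onto the basis mean over the whole
selection before projection, making projections invariant under rigid
transformation of the frame.

## Difference-vector reaction coordinates

A reaction coordinate is defined by two endpoint structures: the plus
endpoint (T or t, mapped to +1) is superposed onto the minus endpoint
(R or r, mapped to −1) over the coordinate's selection; the unit 3N
displacement is the direction, half the displacement norm is the
half-span h, and the endpoint midpoint defines zero (the endpoints are
symmetric about 0 by construction). A frame is superposed onto the
minus endpoint's coordinates (the coordinate's fit frame) and its
centered projection divided by h. The quaternary coordinate uses the
Cα + heme atoms of all four subunits; each tertiary coordinate uses the
Cα + heme atoms of one subunit with subunit-internal superposition, so
it measures internal rearrangement only. The half-spans of the real α
and β subunits (≈0.76 and ≈0.92 nm between the t and r crystal forms)
quantify the larger internal rearrangement of β.

Quaternary states are assigned from the normalized quaternary
coordinate with strict thresholds: R below −0.5, T above +0.5, boundary
values unassigned. Conditional tertiary populations are unit-area
histograms per (subunit, quaternary state); the default grid is 40 bins
on [−2, 2], since subunits demonstrably populate states beyond the
crystal-structure endpoints (|q| > 1). Empty state classes yield
zero histograms flagged by their frame count, not errors.

## Rigid-body rotation analysis

Two descriptions are provided, both computed after anchoring the α1β1
backbone onto the reference: (i) the angle between the frame's and the
reference's α2→β2 center-of-mass axes — a cheap one-vector marker whose
minimal rotation axis is the normalized cross product (undefined and
flagged for parallel axes; ambiguous, hence an error, for antiparallel
ones); and (ii) the full optimal rotation mapping the frame's α2β2
backbone onto the reference's, extracted as axis + angle from the
Kabsch rotation matrix via the rotation vector, with the angle reported
in [0°, 180°]. On synthetic morphs the axis-angle series correlates
with the normalized quaternary projection at |r| > 0.99, supporting the
interpretation of the projection as a rigid-body rotation coordinate.

## Mutual information

Couplings between reaction coordinates are measured with the Shannon
mutual information estimated from 2-D histograms (plug-in estimate over
occupied bins, natural logarithm, reported in nats; exactly zero for a
constant coordinate). The plug-in estimate is biased upward at finite
n, so the reported value extrapolates to infinite data: the MI is
computed on random subsamples (without replacement, fractions 1, 1/2,
1/4, 1/8, ten replicates each, histogram ranges frozen from the full
data), a least-squares line is fit to MI versus k = 1/n, and the
intercept at k = 0 is returned. The smallest subsample must contain at
least 10 × max(bins per axis) points. All subsampling is seeded and
reproducible. MI matrices over multiple trajectories average the
per-trajectory extrapolated values, and transition trajectories are
truncated at their closest rotRMSD approach to the target state
(earliest minimum on ties) so that post-transition equilibrium
fluctuations do not dominate the transition coupling.

Binning: trajectory reaction coordinates default to 10×10 equal-width
bins over the data range — coarse bins keep the small-sample bias
manageable at typical trajectory lengths. For validating the estimator
against the closed-form Gaussian MI, −½ln(1−ρ²), a 10×10 grid is
inadequate for a different reason: the *discretization* loss of the
binned Gaussian at ρ = 0.9 is ≈0.17 nats, and the k→0 extrapolation
corrects sampling bias, not binning bias. The Gaussian suite therefore
uses a 32×32 grid (bin width ≈ 0.25 σ over the sample range), for which
the residual discretization bias is below 0.02 nats across
ρ ∈ {0, 0.3, 0.6, 0.9} while the inflated sampling bias (≈ +0.026 at
n = 20,000) is removed by the extrapolation. The bias-reduction
property of the extrapolation is assessed against its proper target —
the infinite-data MI of the *binned* variables, computed exactly from
the bivariate normal CDF — not against the continuous formula.
Absolute MI values from published trajectory analyses are not
comparable across binning conventions and are not reproduced here.

## Synthetic data

The generator builds an abstract four-chain tetramer — helix-like Cα
traces of 12 residues per subunit plus 5-atom dummy heme groups, *not*
a hemoglobin model — in two endpoint conformations: the R endpoint
equals the T endpoint with the α2β2 dimer rotated 14° about a fixed
axis through its center of mass (the magnitude of the real quaternary
rotation) and each subunit internally deformed by a smooth random field
of 0.1 nm per-atom RMS amplitude. Morphing trajectories follow a
schedule s ∈ [0, 1] (linear, sigmoidal, or a piecewise ramp; optionally
stopping short for partial transitions); each subunit's tertiary
coordinate is c = coupling·s(lagged) + (1−coupling)·u with u a
stationary Ornstein–Uhlenbeck walk (mean 0.5, sd 0.3, relaxation
n/20 frames — smooth enough that its MI with the schedule reflects
coupling, not the noise floor), and isotropic Gaussian noise (default
0.02 nm) is added to every coordinate. Defaults — 1000 frames, β
coupling 0.9, α coupling 0.1, no lag — emulate the empirically observed
pattern of β subunits transitioning with the quaternary coordinate and
α subunits lagging behind it; 1000 frames also keep the smallest MI
subsample (125) above the estimator's minimum.

Two constructions make the pipeline exactly verifiable. First, the
tertiary deformation fields carry no rigid-body component relative to
their subunit: the net translation is subtracted and the residual
rotation is removed by adding the linear field Ω·r solving
SΩ + ΩS = 2·antisym(M₀), where S is the subunit's coordinate scatter
matrix and M₀ the cross-moment of coordinates and field. This makes the
Kabsch cross-covariance between deformed and undeformed subunits
exactly symmetric, so the subunit-internal superposition is exactly the
identity and the tertiary half-span equals half the field norm; on
noiseless rotation-composed morphs the normalized tertiary projection
of every subunit equals 1 − 2c to machine precision. Second, two
quaternary interpolation modes exist because no single rule makes both
coordinate families exactly linear: composing the dimer rotation per
frame (`rotation`, the default — physically meaningful, tertiary
coordinates exact) leaves the quaternary projection on the rotation
arc, deviating from 1 − 2s by at most θ²/8 ≈ 3·10⁻³ at 14°; linear
Cartesian interpolation between the mutually superposed endpoints
(`linear`) makes the quaternary projection exactly 1 − 2s but deforms
the rotating dimer along the chord, so it is reserved for quaternary
linearity checks. The default is `rotation`: chord deformation would
leak a deterministic quaternary signal into the tertiary coordinates of
α2/β2 and corrupt the coupling ground truth that the MI validation
relies on.

What passing the synthetic suite shows: the geometry, projection,
state-assignment and MI machinery recover known ground truth under the
generator's statistical assumptions (rigid quaternary motion, additive
subunit-internal deformations, isotropic Gaussian noise, stationary
uncoupled components). What it does not show: real trajectories have
anharmonic, state-dependent fluctuations, correlated noise, partial
unfolding and sampling far from equilibrium; population shapes,
transition counts and absolute MI values from real simulations are not
reproduced by the synthetic conditions and are out of scope here.

## Validation problem sizes

The self-contained validation (test suite and
`scripts/acceptance.py`) uses: 200 random 12-point clouds against a
10⁴-rotation brute-force Kabsch oracle; Gaussian MI recovery at
n = 20,000 over ρ ∈ {0, 0.3, 0.6, 0.9} (five seeds each); 50 seeded
1000-frame morphs for the β-versus-α coupling ordering; 100 random-axis
14° rotations for rigid-body recovery. The crystal-structure anchors
(rotRMSD 0.53 nm / RMSD 0.24 nm, half-spans 0.76/0.92 nm, β–β COM
shifts +1.1 Å and −3.1 Å, dimer rotation ≥ 12°) run whenever the PDB
entries 2HHB/1IRD/1BBB/1YZI are provided under `data/xray/`.

## Known limitations

* No trajectory formats beyond multi-model PDB are bundled; binary MD
  formats can be converted upstream or adapted via the documented
  `TetramerModel.from_arrays` constructor.
* Salt-bridge detection treats His as protonatable (positive) and uses
  a single 0.4 nm heavy-atom cutoff; no hydrogen-bond geometry.
* The PCA subspace is built from a handful of crystal structures, not
  from trajectory covariance; it spans the reference states by
  construction and nothing more.
* No free-energy estimation, kinetic modeling or pathway optimization
  is attempted from the populations.
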