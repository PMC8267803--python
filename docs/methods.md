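# Methods

This note describes the models and numerical choices behind `boneload`:
what is computed, under which assumptions, and where the genuinely open
design decisions were made.

## Problem setting

Trabecular bone adapts to its mechanical environment: bone is deposited
where the local tissue loading is high, maintained where it is moderate,
and resorbed where it is low. Time-lapsed imaging (in-vivo micro-CT or
HR-pQCT) shows these remodelling events directly — overlaying two
registered binary bone images labels every surface voxel as formation,
quiescence or resorption. The inverse question is the subject of this
package: given the observed remodelling pattern and the structure's
mechanics, what organ-scale load was acting on the bone?

All volumes are 3D scalar grids, isotropic spacing in mm, densities in
mg HA/cm³, indexed `(x, y, z)` with `z` the axial (proximal→distal)
axis. Mechanics uses mm / N / MPa, moments in Nmm.

## Micro-FE unit loads

Each bone voxel of the binarised image becomes one 8-node trilinear
hexahedral element (2×2×2 Gauss quadrature, isotropic linear
elasticity). Bone tissue uses a single modulus (6,800 MPa for the human
distal radius, 14,800 MPa for the mouse vertebra; ν = 0.3); marrow
cavities fully enclosed by bone are meshed at 2 MPa so the model stays
connected; exterior voxels are absent. Six canonical displacement load
cases are solved on the same stiffness matrix: axial compression (C),
two transverse shears (SX, SY), axial torsion (MZ) and two bending
moments (BX, BY). Forces apply a 1 % displacement of the axial length,
moments a 1° small-rotation displacement `u = θ × (p − c)` about the
axis through the reference point `c`, the centre of the minimal bounding
box of the bone. Both end faces are bonded platens (proximal fully
fixed, distal fully prescribed): one mechanism that makes all six cases
well posed and admits exact analytic oracles (uniaxial compression at
ν = 0; simple shear on one-element-thick slabs, where every node lies on
a platen — for thicker blocks the traction-free lateral faces relax the
field, a Saint-Venant effect, so the general solver is validated against
an independent dense direct-stiffness reference instead).

Per-element strain energy density SED = ½ ε:σ is evaluated at the
centroid. Each case is rescaled so its distal reaction equals exactly
1 N (forces) or 1 Nmm (moments): displacements scale with λ = 1/|R|, SED
with λ². These *unit-load SED fields* `U_i(x)` are the basis of every
estimator; compound loads are formed by superposing SED fields (not
displacements) — the deliberate linear simplification `Σ s_i U_i(x)`,
where `s_i` absorbs both magnitude and duty cycle of case i.

The linear systems are solved by mixed-precision sparse LU: the reduced
stiffness is factorised in single precision (symmetric-mode
minimum-degree ordering, roughly half the fill of a plain LU) and the
solution refined against the double-precision matrix to a 1e−10
relative residual — machine-precision results at a fraction of the
factorisation cost, with a double-precision factorisation as fallback
if refinement stalls. One factorisation per mesh is shared by all six
right-hand sides; a Jacobi-preconditioned conjugate gradient (relative
tolerance 1e−8) takes over for systems too large to factor. At the
package's desk scale the direct solve is exact, deterministic and
several times faster than iterative solves.

When a mesh carries solid end plates (the phantom's load-transfer
"discs"), `platen_layers` extends the rigid platen prescription over
those node layers: the plates then move rigidly with the platen and
their degrees of freedom leave the system. This treats the plates as
what they are — grip plumbing, not bone.

### Load magnitude convention

The per-direction scale `s_i` relates to a physical magnitude through
`α_i = √(6 s_i)` (N or Nmm): the six unit cases are assumed to act
sequentially, each for one sixth of the time, so a pure compression of
α newtons corresponds to `s_C = α²/6`. The simulator applies scenario
loads with the same convention: a scenario with composition `c` at
magnitude `m` produces the compound field `Σ c_i (m²/6) U_i`, i.e. the
ground-truth magnitudes are `α_i = m √c_i`. SED scales with the squared
load, which is used throughout (e.g. one FE solve serves every probe
magnitude of the homeostatic search at a fixed geometry).

## The MR estimator

Mechanoregulation-based load estimation runs in two steps on the event
voxel set — (surface of t0) ∪ formation ∪ resorption, each voxel
carrying exactly one label. Resorption/quiescence voxels read the SED
fields directly; formation voxels are background at t0 and read them
through a one-voxel von Neumann maximum dilation (they inherit the
signal of the adjacent surface).

**Step 1 (composition).** Find `c ∈ [0,1]⁶` maximising Spearman's
rank-order correlation between the event ranks (resorption=1 <
quiescence=2 < formation=3, mid-ranks for ties) and the mid-ranked
compounded SED `Σ c_i U_i`. The objective is scale-invariant in `c` and
multimodal — on small geometries the six unit fields are strongly
rank-correlated with one another — so Nelder–Mead (tolerance 1e−4, at
most 2,000 iterations per start) is restarted from three informed
points: the LH solution rescaled into the unit box, the uniform mixture,
and the best single unit load; the best restart wins. The box constraint
is a clip plus quadratic out-of-bounds penalty.

**Step 2 (magnitude).** Find the single scale `r` matching the
predicted net remodelling response to the measured one:
`k(r) = |NRR_SED(r) − NRR_GT|`, where a ternary classifier predicts
formation where `r·SED > T_f`, resorption where `r·SED < T_r` and
quiescence between, and `NRR_SED` is (formation − resorption count) ×
voxel volume / bone volume. The thresholds implement a narrow 4 %-wide
lazy zone about the homeostatic tissue load of 0.02 MPa: `T_f = 0.0204`,
`T_r = 0.0196` MPa. `k(r)` is piecewise constant with breakpoints at
`r = T/SED(x)`, so the minimisation is done exactly on the breakpoint
grid (vectorised; one probe per interval): the optimal plateau's
midpoint is returned, or its left edge when the optimum is the unbounded
right tail (a target beyond any achievable response). Finally
`s = r·c`, `α_i = √(6 s_i)`.

Reported diagnostics: achieved Spearman ρ, step-2 residual, surface
voxel count, iteration counts. `summary()` prints the per-direction
composition, scale and magnitudes.

Known bias: with overlay-derived labels, the high-SED source voxel next
to each formation event remains labelled quiescent (the new bone forms
*beside* it), so step 2's classifier predicts more formation than
observed at the true scale and settles slightly low. This reproduces the
reference behaviour of the method (magnitudes somewhat underestimated in
silico) and is visible in the validation study.

## The LH estimator

The morphology-based load-history benchmark solves the non-negative
least-squares problem `s = argmin_{s≥0} Σ_x (Σ_i s_i U_i(x) − k)²` over
the bone-surface voxels, i.e. the unit-load scaling whose compounded SED
is closest to a homogeneous tissue load `k = 0.02 MPa`. It encodes the
assumption that the *morphology* is fully adapted to the cumulative load
history. The calibrated variant subtracts the baseline estimate
(`α_t − α_{t−1}`, possibly negative) to remove pre-study history.

Both estimators accept an optional trabecular region mask restricting
events, surfaces and bone volume; embedding plates or fixation artefacts
outside the region then cannot bias the fit. The synthetic study always
excludes the phantom's end plates this way.

## Synthetic ground truth

### Phantoms

Baselines are smoothed Gaussian random fields (anisotropic smoothing,
longer correlation along the loading axis, as in load-adapted
trabecular bone) thresholded at the level that yields a target interior
bone volume fraction of 0.12 after keeping only structure that
percolates between the end faces; one solid plate is added at each
axial end so the FE model is always well posed. BV/TV is measured on
the interior slices (the plates are excluded, as is the plate region in
all analyses). Densities map into a plausible mineral range — bone
between ~460 and 720 mg HA/cm³, background below the 320 mg HA/cm³
binarisation threshold — with a smooth ramp across the interface so the
implicit surface has a sub-voxel position. Default spacing is 30.5 μm.
Generation is deterministic per seed (bisection on the threshold, with
deterministic retries if a realisation fails to percolate).

### Advection remodelling

The simulator adapts a geometry toward an applied load. Per step:

1. **Regularise** the density against its binary mask: interior bone to
   full density (720), surface voxels keep their greyscale (clipped to
   [threshold, full]), the one-voxel background shell adjacent to bone
   keeps its sub-threshold greyscale, everything else is zero.
   Binarising the output reproduces the mask exactly. Keeping the shell
   matters: it is where the advancing front accumulates density between
   steps — zeroing it would make formation on flat surfaces impossible
   at the capped speed (the front could never cross a voxel's threshold
   in one step) and leave only a pore-filling corner artifact.
2. **Solve** the scenario SED with density-derived moduli (linear
   density→modulus mapping, slope tissue_modulus/full_density by
   default) on the binarised mask; cavities at 2 MPa.
3. **Sense**: dilate the SED field with a spherical maximum filter of
   radius 50 μm (≥ 1 voxel) — the reach of the osteocyte network.
4. **Move** the surface along its normal at
   `v = gain · (SED_dilated − set point)` with gain 8,000 μm/year/MPa
   (666.7 μm/month/MPa), zero inside the ±2 % lazy zone, clamped to
   ±12 μm/month. The density field itself is the implicit surface: a
   first-order Godunov upwind level-set update moves the threshold
   crossing (exact for linear profiles, monotone in general). Densities
   are clamped to [0, 720]. The configuration is rejected when
   cap × step ≥ voxel size (CFL).

Surface motion is frozen on the end plates. One step is one month, so
the 12 μm cap is sub-voxel at ≥ 30 μm spacing. The loop is fully
deterministic.

### Homeostatic magnitude

The applied magnitude is rescaled per phantom and scenario so formation
and resorption balance, as in the reference experiment. The net
remodelling response is monotone in the magnitude, so the search is a
bisection (geometric midpoints) on short probe simulations, using the
post-transient mean of NRR (the first steps of an unadapted random
phantom are a reorganisation transient — unloaded struts resorb,
load-bearing ones thicken — and are excluded, as the first eight steps
are excluded from every analysis window). The initial guess scales the
mean of the top-30 % tail of the dilated surface SED to the set point;
much of an unadapted phantom's surface is mechanically dead, which makes
plain quantiles unreliable. A run that resorbs past the percolation
limit counts as an overwhelmingly negative response. In the full study
each 40-step run's realised balance is checked and the magnitude nudged
once along the probe-estimated sensitivity if needed.

### Subsampling

Six time points are selected from each 40-step run to emulate sparse
in-vivo follow-up: the first eight steps are excluded and the largest
uniform stride (anchored at the final step) is chosen such that the
Pearson correlation between consecutive selected greyscale volumes stays
≥ 0.95; the wording "until a correlation of at least 0.95 is reached"
is read as this largest-admissible-stride rule. Consecutive selected
pairs feed the estimators.

## Evaluation

**Force vectors.** Estimates mix forces (N) and moments (Nmm); for
comparison the moments divide by lever arms — half the axial extent for
bending, half the dorsal (y) extent for torsion — giving a 6-D force
vector. Errors are 6-D Euclidean distances, optionally as a percentage
of the applied magnitude.

**Multiclass ROC.** Each estimate scores every scenario class as the
negative Euclidean distance to that scenario's canonical force vector
(negation makes "closer = more positive"). One-vs-all curves per class
with trapezoidal AUC; macro = unweighted mean of per-class AUCs; micro =
AUC of the pooled (score, binary label) pairs, prevalence-weighted by
construction. The common threshold is the Youden-J optimum on the
macro-averaged curve; sensitivity, specificity and pooled accuracy are
reported there.

**CP curves and CCR.** The per-voxel signal is normalised by its 99th
percentile, clipped to [0, 1] and binned at 1 % steps. Group-wise
normalisation gives each event's histogram unit mass (equalising class
priors; chance level is then ⅓), bin-wise normalisation makes each
non-empty bin a conditional probability over events. The CCR classifies
each voxel as the argmax-CP event of its bin (empty bins borrow the
nearest non-empty one) and reports the fraction matching the observed
labels. A maximum-CCR variant over ternary-threshold classifiers is also
provided for comparability with threshold-based summaries; argmax-CP is
primary.

**SED errors by region.** Voxelwise estimated-minus-reference SED
grouped by remodelling event; mean absolute error per region, histogram
samples truncated at the 98th percentile of |error|.

## The validation study

`boneload.study.run_insilico_study` ties everything together at desk
scale: 2 phantoms (24³ voxels, BV/TV 0.12, seeds derived from the study
seed) × 9 scenarios (six uniaxial, CS = 0.5C+0.25SX+0.25SY,
CB = 0.5C+0.25BX+0.25BY, 6DoF = equal sixths), homeostatic rescaling,
40 advection steps, subsampling, MR and LH fits on all consecutive
pairs, ROC in force-vector space (per-phantom canonical vectors at the
phantom's own homeostatic magnitudes) and per-pair CP/CCR, with the
simple-compression benchmark (unit C field as the signal) on the
compression-adapted runs. These problem sizes are the package's chosen
desk scale; the reference experiment used five patient-derived radius
geometries at far higher resolution, so levels transfer only
approximately (in particular, on 24³ phantoms the six unit-load fields
are strongly mutually rank-correlated, which compresses the contrast
between MR- and LH-derived local signals; the scenario *classification*
contrast survives, the CCR contrast is smaller than at full scale).
Two further desk-scale effects are worth knowing: the phantoms are
statistically symmetric in x and y, so the two bending directions are
near-exchangeable — real anatomy is not, which is part of why bending
classification is easier at full scale — and the sensing dilation spans
whole trabeculae at this resolution, putting a ceiling on how well any
voxelwise signal (even the generating one) can classify the events.

What passing the synthetic suite does and does not show: the generator
exercises the full pipeline with known ground truth, realistic
structure sizes, sub-voxel interface motion and controlled remodelling
rates, but it contains no scanner noise, no motion artefacts, no
registration error, no physiological (non-mechanical) remodelling, and
its mechanoregulation rule is the same family the MR estimator assumes
— in-vivo performance is a separate question the synthetic study cannot
answer.

The closed-loop magnitude check builds labels by thresholding the true
SED of a known 8 N compression on the surface of a phantom whose
spacing (55 μm) makes that load physiological, then requires the MR fit
to return a dominant α_C within the step-2 plateau width of 8 N. (An
overlay-realised mask pair cannot represent these labels exactly — see
the step-2 bias note above.)

## Degenerate inputs and numerical edges

- Binarisation is inclusive (≥ threshold), so calibrated-density ties
  count as bone. Out-of-grid neighbours are background for surface
  extraction.
- Single-label remodelling maps make the rank correlation undefined and
  raise; an all-zero compound SED makes the magnitude undefined and
  raises. A constant image has no defined Pearson correlation.
- Gaussian filtering uses symmetric (half-sample) reflection, which
  conserves total mass for the truncated, renormalised kernel.
- Meshes drop floating element groups that touch neither end face and
  reject masks whose end faces are not bridged.
- The homeostatic search raises on a bracket without a sign change; a
  degenerate bracket is rejected outright.

## Limitations

- Linear elasticity and SED superposition of unit cases — no contact,
  no large deformation, no failure.
- A single tissue modulus per compartment for estimation (the simulator
  uses density-derived moduli; this deliberate model mismatch mirrors
  the estimation situation in practice).
- Rigid registration is assumed done upstream; inputs share one grid.
- The advection model is phenomenological: linear speed law with cap,
  maximum-filter sensing, monthly steps. Its parameters are fixed to
  the reference values, not fitted.
- Desk-scale phantoms (24³–48³) keep every test and the full study
  within interactive budgets; absolute statistic levels at clinical
  image sizes will differ.
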