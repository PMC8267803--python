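# boneload

Inverse estimation of the organ-scale loads acting on trabecular bone,
from time-lapsed 3D density images.

Bone remodelling is mechanoregulated: between two registered scans of the
same bone, new tissue appears where the local mechanical signal is high,
nothing changes where it is moderate, and tissue disappears where it is
low. `boneload` turns that observation into a load estimator. It is aimed
at researchers working with in-vivo micro-CT / HR-pQCT follow-up series
(mouse loading studies, distal radius imaging) who need subject-specific
boundary conditions for micro-finite-element analysis instead of the
usual one-size-fits-all uniaxial compression.

## What it computes

Six canonical unit load cases — compression `C`, shears `SX, SY`, torsion
`MZ`, bendings `BX, BY` — are solved on a voxel hexahedral micro-FE model
of the baseline image (one voxel = one trilinear element; bonded platens;
SED = ½ ε:σ per element, rescaled to a 1 N / 1 Nmm reaction). Any applied
load is modelled as a superposition Σ sᵢ·Uᵢ(x) of these unit SED fields,
with the physical magnitude per direction αᵢ = √(6 sᵢ).

Two estimators solve the inverse problem:

* **MR (mechanoregulation-based).** Step 1 finds the load composition
  c ∈ [0,1]⁶ maximising Spearman's rank correlation between the observed
  remodelling events on the bone surface (resorption=1 < quiescence=2 <
  formation=3, mid-ranks for ties) and the compounded SED. Step 2 scales
  the compounded signal by the single factor r at which a ternary
  classifier (formation above T_f = 0.0204 MPa, resorption below
  T_r = 0.0196 MPa — a 4 %-wide lazy zone about the homeostatic tissue
  load of 0.02 MPa) reproduces the measured net remodelling response
  NRR = BFR − BRR.
* **LH (load history).** The morphology-based benchmark: non-negative
  least squares for the sᵢ bringing the surface SED closest to a
  homogeneous 0.02 MPa, plus a calibrated variant (α_t − α_{t−1}).

For validation the package also ships an advection-based remodelling
simulator (surface speed ±8,000 μm/year/MPa about the 0.02 MPa set
point, capped at ±12 μm/month, 50 μm signal dilation, density-as-level-set
upwind transport), a seeded trabecular phantom generator (BV/TV ≈ 0.12),
and the evaluation statistics: one-vs-all multiclass ROC (macro/micro
AUC, Youden common threshold), conditional-probability curves, the
correct classification rate (CCR) of remodelling events, and SED error
by remodelling region.

## A worked example

Fit both estimators to a synthetic follow-up pair with a known answer
(a phantom adapted under pure compression by the built-in simulator):

```python
import numpy as np
from boneload import (
    AdvectionConfig, MechanoregulationModel, LoadHistoryModel,
    binarise, build_mesh, generate_phantom, homeostatic_magnitude,
    run_simulation, subsample_series, solve_unit_loads, trabecular_region,
)

cfg = AdvectionConfig()
phantom = generate_phantom((24, 24, 24), seed=10)      # 30.5 um voxels
m = homeostatic_magnitude(phantom, "C", cfg)           # balanced load, N
sim = run_simulation(phantom, "C", m, cfg)             # 40 remodelling steps
i, j = subsample_series(sim)[-2:]                      # last follow-up pair

mask0, mask1 = sim.mask(i), sim.mask(j)
mesh = build_mesh(mask0, tissue_modulus=6800.0, poisson=0.3)
units = solve_unit_loads(mesh, platen_layers=1)
region = trabecular_region(mask0.shape, 1)

mr = MechanoregulationModel.from_masks(units, mask0, mask1, region=region).fit()
print(mr.summary())
```

```
Load estimate               method: MR
==========================================================
dir            c           s       alpha  unit
----------------------------------------------------------
C         0.9140      2.9936      4.2381  N
SX        0.0008   0.0026588     0.12631  N
SY        0.0004   0.0013287    0.089287  N
MZ        0.0000           0           0  Nmm
BX        0.0000           0           0  Nmm
BY        0.0000           0           0  Nmm
----------------------------------------------------------
magnitude scale r = 3.2754   surface voxels n = 1256
Spearman rho (step 1) = 0.2925
|NRR_SED - NRR_GT| (step 2) = 1.301e-18
```

The fit identifies compression as the dominant loading (c_C = 0.91, the
shear components thirty times smaller) and recovers a magnitude
α_C = 4.24 N against the applied 3.69 N; the vanishing step-2 residual
shows the classifier reproduces the measured net remodelling exactly.
The same unit loads drive the LH benchmark,
`LoadHistoryModel.from_mask(units, mask0, region=region).fit()`, which
on this compression-adapted geometry agrees (α_C = 4.12 N, all other
components below 0.14 N) — on strongly adapted geometries the two agree
on direction and differ mainly in how sharply they localise the signal
(see `docs/methods.md`).

A `boneload` command-line workbench wraps the same pipeline
(`boneload phantom / simulate / unitloads / estimate / evaluate / study`),
with a JSON manifest in every output directory so each stage is
reproducible from its inputs, seed and config alone.

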