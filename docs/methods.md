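# Methods

This note documents the models, numerical choices and limitations behind
`bromolb`. It describes what the code computes; every number quoted here is
produced by the test suite, the `analysis/` drivers or
`scripts/acceptance.py`, not asserted by hand.

## Coordinate and imaging conventions

Volumes are `(z, y, x)` arrays: `z` axial (cranio-caudal), `y` anterior →
posterior, `x` patient right → left; world positions are voxel index ×
spacing in mm, and the NIfTI writer transposes to the on-disk `(x, y, z)`
order with the spacing on the affine diagonal. All attenuation values are
Hounsfield units clipped to [−1024, 3071]. Patient position maps to the
gravity unit vector: supine `+y`, prone `−y`, lateral `+x`.

## MinIP and display transforms

The sliding-slab MinIP assigns each voxel the minimum over a centred window
of `round(thickness / spacing)` voxels along the viewing axis (default
axial, 10 mm). Windows truncate at the volume boundary — no padding value —
so edge voxels use smaller support; for an even window the extra voxel lies
on the low-index side. `scipy.ndimage.minimum_filter1d` with edge
replication implements exactly this semantics, and the suite checks it
voxel-for-voxel against a brute-force triple loop.

The lung-window transform maps `[level − width/2, level + width/2]` (default
width 1500, level −500) linearly onto [0, 1] with clipping; it is monotone
in HU inside the window and never alters measured values. Display
enhancement — unsharp masking (amount 0.35, 1-voxel Gaussian radius) and a
symmetric linear stretch of the intensity range by 0.20 about its midpoint —
exists for ROI-placement guidance only. The vendor's exact filters are not
knowable, so the contract enforced throughout is that enhanced images never
feed an HU measurement.

## Phantom model

The phantom is a statistical stand-in for a 1-mm-reconstruction planning CT,
not an anatomical model (no airways, vessels, fissures or motion). Two
superellipsoidal lungs (quartic in z and y) sit in soft tissue of +40 HU;
the quartic profile keeps axial cross-sections wide near the anterior and
posterior faces so that gravity-level-matched comparison ROIs exist wherever
a needle can enter — with pointed ellipsoids the route reference can land on
a lung tip that has no same-level counterpart, which is a geometry artifact
rather than a property of the measurement.

Parenchymal attenuation is

```
HU(v) = −750 + g_v · h(v)/10 + g_r · d(v)/d_max + ε(v)
```

with `h` the mm height above the least-dependent lung voxel along gravity,
`g_v` the vertical gradient (default 10 HU/cm, the gravity-dependent
densification), `d` the distance-to-pleura transform normalised by its
maximum, `g_r` the central-to-peripheral offset (default 10 HU, central
denser), and `ε` i.i.d. Gaussian noise (default SD 20 HU, no spatial
correlation — CT noise is mildly correlated, so phantom noise is slightly
pessimistic at ROI scale). Emphysema clusters are unions of spheres
(radius 3–6 mm) blended toward −940 HU through a Gaussian-smoothed edge
(σ = 1 mm); optional ground-glass clusters blend toward −350 HU. The target
lesion is a +30 HU sphere (default radius 6 mm) placed so the along-needle
pleura-to-lesion distance exceeds the 10-mm margin (18 mm required by
default, to leave room for a corridor ROI); infeasible requests raise a
geometry error. The needle enters anteriorly and runs along +y through the
right lung. Cluster placement modes `on_route` / `off_route` plant one
cluster centred on the intrapulmonary segment, or keep all clusters at
least `route_clearance + radius` (≈ 12 mm + r) from it; these modes give the
end-to-end tests a known ground truth. Everything is a pure function of the
parameter set including the seed.

`normal_parenchyma` is the lung minus a 3-mm dilation of all abnormal
tissue, mirroring the prohibition on measuring in distorted or ground-glass
parenchyma.

## The measurement implementation

ROIs are 5-mm spheres rasterised by centre-in-sphere voxel inclusion on the
1-mm grid (≈ 81 voxels). Candidate centres for the reference are all voxel
centres within `corridor_radius` (5 mm, the lateral needle tolerance) of
the intrapulmonary segment whose ROI fits inside the lung and clear of the
lesion; the reference minimises the ROI mean, with ties broken toward the
pleural entry and then lexicographically. The reference is found on the
source-HU image; its MinIP value is read at the same centre from the
unenhanced MinIP.

Comparison placement is deliberately deterministic and geometry-first:

- **1.H** — candidates within ±2 mm of the reference's gravity level,
  ordered by exact level match then proximity to the reference.
- **2.PD** — candidates whose distance-to-pleura matches the lesion's
  (±3 mm), preferring the same vertical band, then the same gravity tercile
  of the lung, then level match and proximity. The lesion's pleural
  distance is measured with the same distance transform as candidate depth.
- **3.P** — candidates whose ROI lies fully inside normal parenchyma,
  ordered by gravity-level match first and, at equal level, preferring the
  contralateral lung near the mirrored reference position (1.H has already
  sampled same-level parenchyma in the needle's lung). Matching the level
  controls the dominant gradient; mirroring is the closest contralateral
  analogue of the reference location.

All comparisons keep one ROI diameter of centre separation from each other
and the reference, stay outside the corridor, and keep
`roi_radius + 3 mm` clearance from abnormal tissue *including its MinIP
shadow* — the slab projects a cluster's darkness up to half a slab along
the viewing axis, so clearance is computed on the slab-dilated abnormal
mask. Without this, a comparison ROI 6 mm above a cluster reads normal on
the lung window but emphysematous on the MinIP, and repositioning thrashes.

The 20-HU consistency rule is applied to the three comparison means (each
within 20 HU of their common mean), on both the lung-window and MinIP
readings; the alternative reading (reference vs comparisons) would collide
with the positivity criterion itself, while comparison agreement matches the
rule's stated purpose of controlling attenuation errors. On failure the
worst offender is repositioned to the next candidate in its ordering, up to
10 attempts, after which the case is flagged unevaluable with the violated
rule as the reason — unevaluable cases are excluded and counted by the
pipeline, never silently dropped.

The positivity vote is strict: the reference mean must be lower than at
least 2 of 3 comparison means; ties count against positivity. MinIP
positivity uses ROI means on the MinIP by default; ROI minima ("across the
entire slab") are available via `minip_statistic="min"` — both are exposed,
neither silently substituted. The absolute classifier is inclusive
(≤ −850 HU). Because the MinIP is a pointwise lower envelope, the MinIP
reference value never exceeds the lung-window value; the suite asserts this
per case.

## Cohort simulator

Covariates are drawn from summary-statistic-matched distributions: route
densities bivariate normal (MinIP −866.9 ± 132.78 HU, LW −745.9 ± 130.49 HU,
correlation 0.95, `LW = max(LW, MinIP)` enforced, clipped to valid HU —
the normal form is an assumption, as only means ± SD are known), procedure
time 27.72 ± 8.46 min, lesion size 20.51 ± 9.80 mm, position
supine/lateral/prone at 25/40/35%. Binary positivity calls are thresholded
at the quantiles matching the observed positivity rates (44.4% MinIP, 40.3%
LW); access-route emphysema is nested within general emphysema
(P = 29/72 and 22/29), matching the subgroup arithmetic of the source
cohort. Outcomes are Bernoulli draws from the two logistic models; the
intercepts (−2.428 and −6.92) are calibrated so the marginal event rates
match the source cohort (pneumothorax 45.8%, grade ≥ 2 hemorrhage 27.8%)
at the covariate means. Hemorrhage grades split events 2/3/4 at 85/10/5%
and non-events 0/1 at 1/51 parts. Emphysema flags are independent of the
density values; real cohorts couple them, which only matters for analyses
this package does not perform.

## Validation design and problem sizes

- **Printed-count statistics** (deterministic): every 2×2 summary is checked
  against values that follow exactly from published group counts.
- **Oracle equivalence** (deterministic): MinIP vs brute force on random
  20³ volumes; Youden/top-left vs exhaustive threshold search; Fisher exact
  vs full fixed-margin enumeration (totals ≤ 40); φ vs the Pearson
  correlation of 0/1 encodings (exhaustive totals ≤ 20 plus random tables
  to 50).
- **Parameter recovery** (stochastic): 200 replicate cohorts of n = 5,000
  per model; the replicate geometric-mean OR and the 95% Wald CI coverage
  (nominal 95%, required ≥ 93%) are checked. The multivariable OR point
  estimate is reproducible only in this distributional sense because the
  individual-level source data are unavailable; the same applies to the ROC
  optima (−868 HU MinIP / −769 HU LW in the source data; the simulated
  cohort places them near −886/−762).
- **End-to-end phantoms**: 200 randomized constructions alternating
  on-/off-corridor clusters across patient positions; the BROM-OLB call
  must match the planted truth in ≥ 99%. These run with noise SD 0 and the
  vertical gradient only: the strict majority vote carries no tie
  tolerance, so with measurement noise the route *minimum* is biased low by
  selection (winner's curse) and even a homogeneous lung votes positive —
  the noise-free check isolates the placement logic, which is what the
  phantom can meaningfully validate. Passing it therefore shows the
  procedure's internal consistency on known geometry, not reader-level
  performance on real, noisy CT.

The per-case seeds of every replicated study derive from the master seed via
`SeedSequence` spawn keys, so case order never changes results and a run is
reproducible byte-for-byte from its configuration.

## Known limitations

- The phantom's anatomy is schematic; lobes are not modelled, so "same
  lobe" degrades to "same lung" and the contralateral fallback.
- The strict-inequality vote makes the noise-free call sensitive to ±1 HU
  gradient mismatches when no exactly level-matched comparison spot exists
  (needles through an extremely shallow lung rim); this accounts for the
  rare residual mismatch in the end-to-end study.
- Fisher's exact test uses the sum-of-smaller-probabilities two-sided
  convention; Mann–Whitney is exact only below a combined n of 21 without
  ties; "R²" for logistic models is Nagelkerke's (the variant is an
  assumption); Wald rather than profile-likelihood CIs are reported. No
  multiple-testing correction is applied anywhere.
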