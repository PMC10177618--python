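# Methods

## Scope and model

`psmflow` treats the elongating axolotl tail bud as a pair of paraxial
mesoderm streams flowing around the neural tube/notochord. One stream (the
grafted, labelled side) is modelled explicitly as a tube of cells around an
arc-length-parameterized centerline; the statistics the package computes are
the ones used to characterize this flow on fixed, cleared embryos. The
generator is a *kinematic* emulator: it places cells with configured
statistical structure, it does not solve tissue mechanics, simulate optics,
or model gene expression.

Coordinate frame: x = anteroposterior (positive posterior), y = mediolateral
(positive right), z = dorsoventral (positive dorsal), origin at the
anterior-most body point; all lengths in µm. The grafted side is the left
(y < 0). Arc length along the stream is measured from the posterior tip.

## Strand geometry and regions

The centerline is a unit-speed planar curve: straight along AP with a dorsal
hook (150 µm arc, 0.6 rad peak pitch) at the posterior tip, approximating the
tail-bud silhouette. Per stage the configured arc lengths are 350/500/950/
1200 µm for the four tail-bud stages, matching the observed ~500 → ~1200 µm
elongation. Regions are half-open arc intervals, posterior to anterior: PZ
(the whole bulge at the early stages, a 120 µm cap later), then the PSM split
into equal thirds (posterior/medial/anterior — the regional split is by
convention, mirroring how the regions are drawn on reconstructions), then
70 µm somite blocks (4 at the last stage; somite 1 is the most posterior).
A cell exactly on a breakpoint belongs to the more posterior region.

The tube cross-section radius follows from the configured envelope-volume
schedule V(22) = V(28) = 9.2 × 10⁶ µm³, V(30) = 2 V(28): r = sqrt(V / (π L)).
This realizes both the two-phase growth classification (reshaping, then
volumetric growth) and a stage-30 strand height of ~140 µm. Mean single-cell
volume is 8000 µm³ in the early PZ and half that in all later PSM/somite
regions (yolk consumption), with lognormal scatter (CV 0.25).

## Cell-level sampling

**Shape.** Long/short aspect ratios are lognormal, parameterized to the
configured mean/SD per region (PZ 2.33 ± 0.70, posterior PSM 2.78 ± 0.67,
medial PSM 2.26 ± 0.68, anterior PSM 2.37 ± 0.71, somites 3.03 ± 1.31) and
truncated below at 1 (configurable lower bound). The mid semi-axis b is
uniform in [c, a]; semi-axes then follow from the drawn cell volume.

**Orientation.** Each cell draws an orientation class from the configured
per-region probabilities (AP/ML/DV/unclassified); axis classes get a long
axis uniform over the spherical patch where that frame axis dominates,
'unclassified' is isotropic. Shape and direction are independent, so the
configured class fractions are recovered exactly only when the shape
distribution sits above the classifier threshold (generate with the lower
truncation at 1.3 for orientation-recovery studies); with the default
truncation at 1, a few percent of cells fall below the threshold and classify
as unclassified regardless of direction. Class probabilities not printed per
region were completed to sum to 1 while preserving the printed values (e.g.
PZ: ML 0.48, AP 0.28, DV 0.24).

**Classifier.** Cells with a/c < 1.3 are unclassified: near-spherical cells
have numerically unstable long axes, and reported per-region percentages do
not sum to 100%, implying such a bin. The threshold is configurable.

**Spindles.** Division events place two centrioles 8 µm apart. With the
configured per-stage probability (5.9/1.4/12.1/4.4% across the four stages)
the spindle direction is uniform *inside* a 30° AP cone (angle folded to
[0°, 90°]), otherwise uniform outside it. Generation and classification share
the cone, so the configured fraction is the true fraction. 30° was chosen
because its isotropic baseline (1 − cos 30° = 13.4%) is consistent with the
observed 1.4–12.1% range being called low, whereas an argmax-over-axes rule
(33% baseline) is not; the angle is configurable.

**Filopodia.** Counts are Poisson (region means 0.9–3.5, highest in the
anterior PSM), lengths gamma with shape 2 and the configured regional mean
(6 µm from PZ through medial PSM, 4 µm in anterior PSM and somites),
truncated to the observable (0, 40] µm range.

## Cohesion groups and calibration

Focally labelled groups (the lifeact-style clumps used for cohesion
analysis) are generated as *substreams*: k sub-clumps spaced one section
thickness (80 µm) apart along AP, each an isotropic Gaussian of scale σ
about its anchor. σ is solved numerically (common-random-number Monte Carlo
inside Brent root bracketing, cached) so that the expected in-section median
pairwise distance equals the configured regional cohesion scale — the
sectioning truncates the AP spread of co-sectioned pairs, and for loose
groups cross-anchor pairs contribute, so no closed form applies. Each
sub-clump's displacement draws are moment-matched (centered, rescaled to the
exact Gaussian mean-square displacement) so that small groups realize the
configured spread exactly rather than only in expectation; this is a
variance-reduction choice in the synthetic truth, keeping recovery studies at
realistic pair counts (~150–450 pairs pooled over three embryos) informative.

The true spatial point process of PSM cells is unknown; the
Gaussian-substream construction is a stand-in chosen for tractable
calibration, not a biological claim.

## Density groups

Printed cell counts, strand dimensions and ~25–30 µm nearest-neighbour
medians are mutually inconsistent under homogeneous placement (≈2000 cells
in a 140 µm × 1200 µm strand imply ~11 µm NN spacing). The density analysis
in the emulated study grouped labelled cells "inside a sphere", i.e. on a
subset. The pipeline therefore emulates sphere grouping by seeded uniform
thinning of each region's cells to the intensity implied by the configured
NN scale (median = (3 ln 2 / 4πλ)^(1/3) for a Poisson process; retention
q = λ_target/λ_current). Thinning preserves relative comparisons exactly —
the epidermis-removal contrasts and the somite-vs-PSM ordering — while
absolute thinned medians carry a positive boundary bias of order 10–30% in
short regions (finite tube vs. the unbounded-process formula).

## Graft series and timecourse

Focal grafts (median/paramedian/lateral posterior-neural-plate origins) place
labelled cells in origin- and stage-specific arc intervals with an anterior
"handicap" of 0/30/60 µm; the anterior-most cell is pinned to the interval
bound so the anterior-reach ordering median > paramedian > lateral is strict
for every seed. Only median (and whole-plate) grafts seed contralateral
cells (10%/50%); paramedian and lateral series cross only within the PZ and
only at the late stage, so their contralateral fraction outside the PZ is 0.

Whole-embryo displacement uses a shallow-arc ventral contour whose length
follows the staging series (2.1 mm at neurulation to 9.3 mm at the
pre-hatching stage). A label at initial arc position a₀ keeps a constant for
epidermis, scales as a₀·(b₀/b) for paraxial mesoderm (strongest anterior
shift), as a₀·sqrt(b₀/b) for lateral plate, and stays constant until stage 30
for endoderm. These are kinematic schedules reproducing the observed
ordering of shifts, not mechanical predictions.

## Epidermis removal

Removal of the lateral epidermal barrier is modelled as deterministic ML
spreading: PZ and posterior-PSM cells on the deprived side(s) have their ML
coordinate scaled away from the midline by the spread factor (default 1.5);
anterior PSM and the contralateral side are untouched, and cell count is
conserved. All pairwise ML differences scale up, so NN medians increase
deterministically on the treated side.

## Numerical choices

- Ellipsoid fit: second-central-moment eigendecomposition; semi-axis
  = sqrt(5λ) (exact for solid uniform filling — voxelized cells carry a
  small +O(voxel²/12) inflation, <1% at 2 µm voxels for 8 µm axes);
  deterministic sign convention (largest-magnitude component positive);
  coplanar inputs (smallest eigenvalue ≤ 10⁻¹² of the largest) are rejected.
- Rasterized re-fitting refines the voxel size per cell so the shortest
  semi-axis spans ≥ 5 voxels; very thin cells would otherwise digitize to a
  coplanar set.
- Sections are half-open slabs [k·t, (k+1)·t) by centroid membership — exact
  partition, a deliberate simplification of physical sections that can cut
  cells in two.
- Pair distances are full 3D Euclidean between co-sectioned cells (a
  2D in-plane mode is available behind a flag); no normalization is applied
  to "relative" distances.
- Label-image extraction supports isotropic voxels only; centroids use voxel
  centers; overlapping cells in a shared label stack lose voxels to the
  higher id (the per-cell re-fitting path avoids this).
- Union tissue volume is voxel counting at 2 µm default; halving the voxel
  changes a 200-cell snapshot volume by <2%.
- Growth-phase tolerance 0.15 on |ΔV|/V separates "constant" from "doubled";
  configurable.
- Projection ties (outline and centerline) resolve to the smallest arc
  length; outline vertex 0 is the anterior tip by contract.
- Group comparisons: one-way ANOVA from explicit sums of squares (degenerate
  all-equal input gives F = 0, p = 1), pairwise t tests with Holm adjustment
  (distribution-free step-down control; the method id is recorded in the
  result).
- Determinism: every entry point takes an integer seed; internal streams are
  decoupled via `SeedSequence` spawning, and identical (config, seed) yields
  bit-identical snapshots and byte-identical pipeline output files.

## Problem sizes

Recovery studies use the study-scale problem sizes: cohesion at ~150–450
pooled pairs over three synthetic embryos, shape/orientation at 5,000 cells
per region, spindles at 5,000 events, filopodia at ≥2,000 lengths, and the
isotropic baselines at 100,000 directions. The full test suite and the
acceptance script each complete in a few minutes on one CPU.

## What passing tests do and do not show

The generator reproduces the *statistical structure* of labelled-cell
ensembles: counts, shape/orientation mixtures, cohesion/density scales,
tissue dimensions and displacement ordering. It does not reproduce image
noise, segmentation error, cell–cell contact geometry, mechanical coupling,
or biological variability between embryos beyond seeded sampling. Parameter
recovery therefore validates the estimators and the pipeline plumbing — that
the implemented statistics measure what they claim at realistic sample sizes
— not the biological fidelity of the generative model.

## Known limitations

- Homogeneous-tube placement cannot reconcile printed counts, dimensions and
  NN scales (see Density groups); absolute density medians are
  boundary-biased upward.
- Physical sections count cells spanning a cut on both sides; centroid
  sectioning never does. Counts are therefore exact by construction.
- The graft substream intervals and contralateral fractions are coarse
  categorical encodings of reported distributions, sufficient for ordering
  and presence/absence properties only.
- Whether pooled-across-embryos or per-embryo means are the right ANOVA unit
  is left to the caller; the pipeline pools.
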