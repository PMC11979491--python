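# Methods

## Grid geometry

The brain-grid is a fixed partition of a template-space (RAS, mm) bounding
box — default x ∈ [−72, 72], y ∈ [−108, 72], z ∈ [−60, 84], enclosing the
MNI brain — into 48 axis-aligned cells by 3 mediolateral, 2 anteroposterior
and 3 dorsoventral planes. The historical grid places these planes on
anatomical landmarks; published descriptions do not give their millimetre
coordinates, so the default here is a reproducible fractional stand-in: the
midline plane is fixed at x = 0 with symmetric lateral planes at half the
hemispheric width, and the y and z axes are split into equal thirds and
quarters. Explicit plane coordinates can be supplied in the config when a
landmarked grid is available; every downstream computation is unchanged.

Assignment is half-open along the label direction. All three label indices
(A right→left, C anterior→posterior, S superior→inferior) increase as the
coordinate decreases, and each cell owns its higher-coordinate edge, so
every interior point belongs to exactly one cell and the exact midline
x = 0 falls on the left-medial (A3) side. Consequences worth knowing:

* the 48 boxes tile the bounding box exactly — summed cell volumes equal
  the box volume to machine precision;
* voxelization assigns each voxel *centre* to one cell, so per-cell overlap
  volumes sum exactly to the mask volume whenever all voxel centres lie in
  the box; centres outside it are dropped;
* mirror symmetry (A1↔A4, A2↔A3) holds for symmetric lateral planes except
  for points lying exactly on a plane, which is a measure-zero set but can
  matter for voxel lattices deliberately aligned with the planes.

All geometry runs through the volume affine in mm, never raw indices, so
anisotropic 2D-acquired masks (e.g. 0.45×0.45×5 mm) and 1 mm isotropic
volumes are handled identically.

## Involvement and its threshold

A cell is involved when its overlap volume exceeds `threshold_ml`. The
default is 0 mL (any overlap counts): the most permissive reading, and the
only one that needs no extra assumption. The threshold is exposed as a
sensitivity knob; involvement is monotone non-increasing in it, which the
test suite checks as a property.

## Statistics

* **2×2 measures.** OR = ad/bc and RR = [a/(a+b)]/[c/(c+d)] with log-scale
  Wald 95% intervals. Tables with a zero cell are returned as flagged
  non-estimable rather than continuity-corrected; correction methods change
  answers silently and are out of scope.
* **Logistic fits** are maximum likelihood via Newton/IRLS (statsmodels)
  with tolerance 1e-8. Complete or quasi-complete separation is detected as
  an optimizer separation error or a coefficient magnitude beyond 15 on the
  log-odds scale (odds ratios beyond e^15 carry no epidemiological
  meaning); separated fits are flagged and their coefficients withheld.
  Penalised (Firth-style) estimation was deliberately not made the default:
  transparency over silent shrinkage.
* **Per-cell scan.** One univariate logistic fit per cell; cells with fewer
  than `min_involved` involved (or uninvolved) patients are excluded with a
  stated reason — with the default `min_involved = 1` this excludes exactly
  the never-involved cells, the only defensible data-driven reading of a
  scan that covers fewer than 48 cells. p-values are nominal by design;
  Benjamini–Hochberg adjustment is available behind a flag.
* **Stepwise model.** Forward selection with conditional removal, the
  convention of the major commercial statistics package lineage: entry by
  Rao score test (the score of the current coefficients vanishes at the
  MLE, so the statistic reduces to U²·[I⁻¹]₍new,new₎), removal by
  likelihood-ratio test, defaults p_enter = 0.05 ≤ p_remove = 0.10.
  Confounders are forced into the design; candidates collinear with the
  current design are skipped and logged. Ties break on smallest entry
  p-value, then lexicographic name, making the procedure deterministic for
  a given input. The step log is part of the result.
* **Subgroups** rerun the identical scan on a diagnosis/grade stratum and
  refuse strata below 10 patients (configurable): below that, Wald
  machinery is not worth printing.

### Wald calibration at small n

Wald p-values from 2×2-sized strata are *conservative* at very small n
(with 20 patients the per-cell tests essentially never reach p < 0.05).
The permutation-null calibration property is therefore checked at n = 120
restricted to well-populated cells, where the asymptotics the test relies
on actually hold; at smaller n the scan still runs but its p-values should
be read as conservative.

## Occurrence maps

Group maps are voxelwise means of binary masks on a reference lattice
(default 2 mm isotropic over the grid bounding box; 1 mm is a config
change). Masks on other lattices are resampled nearest-neighbour (affine
composition + order-0 map_coordinates), preserving binarity; no smoothing
is applied. Two exact invariants are tested: conservation (map integral ×
N = summed mask volumes) and group decomposition (pooled map = N-weighted
average of group maps). Frequency tables aggregate at cell level, which is
the documented default for grid-style figures; voxel-level peaks are also
available (`peak_occurrence`, ties broken by lowest cell code).

## Tract overlap

Tract masks are inputs; no tractography is performed. The default
vocabulary is the 8 bundles IFOF, CST, UF, aSLF, pSLF, AF, FAT, Ci, and the
package ships a deterministic synthetic toy atlas (8 capsule-shaped tubes
with loosely plausible left-hemisphere courses) so tests and demos need no
external template; it is labelled synthetic everywhere and is not an
anatomical reference. Profiles report mean/max occurrence within the tract
and the occupied fraction; the mean statistic is linear under N-weighted
map averaging, which is tested.

## Synthetic cohorts

The generator draws, per patient: sex (male fraction 58/93), lognormal
tumour volume (ln-mean 3.8, ln-sd 0.8 mL, capped at 190 mL ⇒ mean ≈ 60 mL),
border type (diffuse with probability 54/83), a seed cell from a spatial
density decaying from a left fronto-insular focus (−35, 5, 5) with 40 mm
scale (gliomas cluster fronto-insularly), and an age from N(42, 12²)
clipped to 20–74.

**Shape model.** A compact axis-aligned ellipsoid core (half the target
volume, axis ratios 1.2–2.6) plus infiltrative satellite lobes (22% of
target volume each, centred 1.4–2.6 core radii along random directions):
diffuse-border tumours grow 6 lobes, sharp-border tumours 2. Pure
ellipsoids saturate around 4 involved cells regardless of plausible volume;
the lobed model reproduces the sublobar spread of infiltrative tumours.
These parameters were calibrated once so that, at large n, the median
involved-cell count is 8, mean realised volume ≈ 62 mL, and diffuse/sharp
mean counts ≈ 9/6, then frozen as the package defaults.

**Outcome model.** `logit P(seizure) = β0 + Σ_c β_c I_c + β_sex·male`, with
I_c the *realised* involvement of the generated mask — the same family the
scan fits, so recovery is a valid oracle. Defaults: β_sex = ln 3.6, cell
effects ln 8.8 for A4C2S3 and ln 0.3 for A3C1S1, and β0 solved (Brent) so
the sex-mixture marginal prevalence is 75%. The solver ignores cell
effects; with the default seeding a minority of patients involve an effect
cell, so the realised prevalence sits within a few points of the target
(the all-effects-zero case is exact and tested at 3 binomial SEs).

**Randomness.** One root seed; per-patient substreams via
`SeedSequence.spawn`, so cohorts are bit-for-bit reproducible and adding
draw sites for one patient cannot shift another.

**What the generator does not emulate:** registration error (masks are
generated directly in template space), non-ellipsoidal growth along specific
white-matter geometry, volume- or age-dependent seizure effects (available
only by configuring cell effects), and missing clinical fields. Passing
recovery tests therefore demonstrate the *statistical* pipeline under a
correctly specified spatial-logistic model, not robustness to real-world
registration or segmentation noise.

## Problem sizes in the test suite

Deliberate choices, balancing Monte-Carlo resolution against desk-scale
runs: recovery of a planted OR = 4 effect uses 100 replicates at n = 200 on
a 24³ lattice (CI coverage ≥ 90%); the permutation null uses 200 label
permutations at n = 120; stepwise entry-rate calibration uses 200
replicates at n = 300 with 5 noise candidates; generator faithfulness is
checked at n = 1000 within 3 Monte-Carlo SEs. Fixture trees are capped at
20 patients on a 32³ lattice.

## Known limitations

* Default grid planes are fractional, not anatomically landmarked; analyses
  meant to be compared with landmark-based grids must supply plane
  coordinates.
* Wald intervals everywhere; profile-likelihood intervals are not yet
  implemented (the flag is reserved).
* Laterality derivation counts any crossing voxel as bilateral involvement
  with no minimum-volume rule.
* The stepwise procedure can, like its commercial ancestor, oscillate for
  pathological inputs; a step cap (default 100) bounds it and the step log
  exposes any such behaviour.
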