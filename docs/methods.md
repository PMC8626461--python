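# Methods

`marrowmap` quantifies where disseminated tumour cells (DTCs) sit relative
to the bone-marrow vasculature in 3D fluorescence volumes, and how that
vasculature is remodelled.  Because the microscopy data such analyses are
run on are not generally redistributable, the package pairs every
measurement stage with a synthetic-marrow generator that knows the ground
truth, so each stage is tested as a parameter-recovery problem.

## Coordinate and intensity conventions

Volumes are `(nz, ny, nx)` arrays with anisotropic physical spacing
`(sz, sy, sx)` in µm; voxel index `i` along an axis sits at physical
position `i·spacing` (origin at the centre of voxel 0).  All reported
distances, lengths and areas are µm-based.  Channel intensities are
arbitrary units: instrument scales vary between detectors and unmixing
settings, so nothing downstream assumes absolute calibration.

## Synthetic marrow generator

The generator emulates a metaphyseal marrow field of view as acquired by
cleared-tissue confocal imaging:

- **Grid**: default 256×256×64 voxels at (2, 1, 1) µm — a ~100 µm-deep
  stack with typical z-undersampling, which forces every measurement stage
  to honour physical spacing.
- **Vessel network**: arterioles (radius ≈ 8 µm) enter the volume, run
  roughly axially as tortuous polylines (bounded perpendicular jitter of
  waypoints), and branch into type H capillaries (≈ 6 µm) which feed type L
  sinusoids (≈ 12 µm).  Vessels are capsule unions of spheres along the
  centerline — the simplest geometry that supports a radius, an open lumen
  (default 50% of the radius), continuity across branch points, and
  closed-form oracles (cross-section πr², lateral area 2πrL).  Where
  subtypes overlap, a voxel takes the subtype of the nearest centerline
  sample.  The default network (3 arterioles, branch factor 2, type H
  segments ≈ 90 µm) makes the 10 µm shell of type H vessels occupy ≈ 4% of
  admissible marrow — matching the chance proximity a uniform null model
  measures in real metaphyseal stacks — and the whole-vasculature shell
  ≈ 15–20%.
- **Bone**: a cortical plate on one volume face plus trabecular spurs in a
  configurable metaphyseal band.  Bone content is deliberately modest so
  that endosteal shells stay below the DTC bone-proximity level being
  emulated.
- **Intensity model**: class-conditional channel means (arterial: CD31 200 /
  EMCN ≈ background; type H: 200/200; type L: 60/60 over background 5) plus
  Gaussian noise (sd 10) and optional Gaussian blur (default 0 µm).  The
  means are synthetic conventions, not instrument calibrations; they are
  chosen so 3-class Otsu separates the populations cleanly at noise up to
  ~20% of the class separation.  Blur defaults to off so that the noiseless
  configuration renders exact class means; enabling it (µm-valued sigma)
  studies gate robustness to boundary mixing.
- **Sprouts**: Poisson-distributed anchors along type H / type L segments
  (arterioles are spared by default), with Gaussian lengths (8 ± 2 µm,
  truncated at 1 µm) and thin radius (1.5 µm), rendered as part of the
  parent vessel.
- **DTCs**: spheres of radius 5 µm (10 µm diameter spot convention).  The
  placement mix assigns deterministic integer counts (largest-remainder
  rounding) to classes — perivascular, endosteal ("near bone"), type-H-
  adjacent, each meaning "centre within the 10 µm shell of that structure,
  uniform over the shell" — with the remainder uniform over admissible
  marrow (everything outside vessels and bone).  Spots keep a minimum
  centre separation (12 µm default) by rejection sampling: clustered cells
  are annotated as single spots, and spot detection is specified for
  non-overlapping objects.  Sub-voxel jitter falls back to the voxel centre
  when it would push a constructive spot out of its shell.

What the generator does **not** emulate: realistic PSFs or depth-dependent
attenuation, vessel calibre variation along a segment, haemodynamics,
marrow cellularity, or growth-plate anatomy.  Passing recovery tests on
this phantom therefore demonstrates that the measurement pipeline is
unbiased under known geometry and noise — not that it is robust to every
artefact of real microscopy.

## Vessel phenotyping

Voxels are gated in joint CD31–EMCN intensity space: arterial =
CD31-high/EMCN-negative, type H = CD31-high/EMCN-high, type L =
low-positive in both, background below a CD31 presence threshold.  The
original protocol draws these gates by hand; here the default is
reproducible 3-class Otsu per channel (CD31 over all voxels; EMCN over
CD31-present voxels), with a manual override that passes thresholds through
verbatim.  Degenerate inputs (fewer than three distinct levels, or a
unimodal smoothed log-histogram) raise an error advising manual gates; an
adversarial near-unimodal histogram can evade this check, which is a known
limitation.  Voxels falling between hand-gate quadrants (CD31-high with
intermediate EMCN, or CD31-low with negative/high EMCN) are assigned to the
nearest class centroid in per-channel-normalized intensity space; the
centroids are the means of the unambiguously gated populations.

Connected components are 26-connected per subtype; components below
500 µm³ merge into an adjacent kept component of another subtype (a
misgated speck inside a continuous vessel belongs to that vessel) or are
dropped if isolated.

## Spot detection and curation

Single-scale Laplacian-of-Gaussian detection at σ = d/(2√3) for expected
diameter d = 10 µm, with per-axis σ in voxels (anisotropy-corrected), local
maxima over a 0.7 d neighbourhood (so near-touching spots keep separate
peaks), an intensity floor, and duplicate suppression within d/2.  Two
cells closer than ~d/2 merge into one detection; a fitted radius above
1.5× the expected radius flags `is_cluster`.  Curation removes detections
centred in bone or vessel lumens or below a quality cutoff, logging a
reason per removal — an automated surrogate for manual review of optical
sections, with the rule set config-exposed because published curation
criteria are rarely stated.

## Spatial niche statistics

- **Distance fields**: exact Euclidean distance transform with anisotropic
  sampling; spot distances are trilinear interpolations of the field at
  the spot centre.  Distances are centre-to-structure by default (a
  `subtract_radius` flag gives surface-referenced distances), matching how
  spot-to-surface distances are read off imaging software.
- **Proximity statistic**: fraction of spots within a threshold (default
  10 µm) of a structure, aggregated per volume; group summaries are mean ±
  s.e.m. across volumes (the biological replicate is the mouse/stack, not
  the spot).
- **Null model**: DTC-sized spots placed uniformly over admissible marrow
  (vessel interiors incl. lumens and bone excluded — regions where DTCs
  are never annotated), refusing to run unless all vessel subtypes and
  bone are present in the volume, so chance proximity is neither over- nor
  under-estimated on unrepresentative stacks.  Default size
  max(10 × nDTC, 1000); `null_convergence_check` re-draws the model at
  0.25–2× across seeds and reports the smallest n whose across-seed s.d.
  falls below 0.5 percentage points.
- **Tests**: two-sample two-sided Kolmogorov–Smirnov with D evaluated
  exactly on the pooled sample and the asymptotic Kolmogorov p at
  effective n = n₁n₂/(n₁+n₂); unpaired two-tailed t tests (pooled-variance
  Student by default, Welch by flag) on per-volume means.  Zero-variance
  groups are guarded (p = 1 for equal means, p → 0 otherwise, flagged).
  No multiple-testing correction is applied; p values are per-comparison
  and marked as such in outputs.  Caliper tumour volume is width²·length/2.

## Morphometry

- **Vessel length** is the longest geodesic path through the 3D thinning
  skeleton (26-neighbour graph, physical edge weights, weighted double-
  sweep) — a reproducible surrogate for manual measurement points, and the
  documented denominator of both surface-over-length and sprouts-per-100 µm.
  Components whose main path does not exceed twice their maximal local
  radius are flagged degenerate (blobs have no meaningful length).  A known
  edge case: topological thinning can erase exactly axis-symmetric tubes
  with even voxel cross-sections (an upstream thinning artefact); such
  components come back flagged degenerate rather than silently wrong.  Real
  (tortuous) vessels are unaffected.
- **Surface area**: marching-cubes mesh of the mask at the 0.5 level after
  1 µm Gaussian smoothing (tames staircase overestimation; sigma
  config-exposed), summed triangle area.  For an isolated voxel the 0.5
  level set is the inscribed octahedron (~30% of the cuboid face sum);
  meaningful areas require components several voxels across.
- **Sprouts**: terminal skeleton branches whose tip-side run of nodes with
  local radius below 2 µm is at least 2 µm long.  The sprout length is that
  thin run — the protrusion beyond the vessel wall — because the raw
  anchor-to-tip geodesic would include one wall radius.  Both thresholds are
  config-exposed ("thin" has no published numeric definition) and reported
  in outputs.  Sprouts are counted in full 3D, not per transversal section.
- **Lumen area**: at 10 equidistant main-path nodes (excluding 5 µm around
  branch anchors and path ends), the lumen mask is sampled on the plane
  perpendicular to the centerline tangent at half-voxel resolution; the
  area is the in-plane region connected to the centerline point.  Collapsed
  or solid vessels record 0.  On data without a generator-truth lumen, a
  hole-fill of the vessel wall supplies the lumen mask.
- **Vessel volume fraction** (intralesional density): |vessel ∩ region| /
  |region| by voxel count.

## Reproduction protocol (scripts/acceptance.py)

The published proximity percentages are measurements on unreleased
microscopy data, so the reproducible counterpart is calibrated parameter
recovery.  If a fraction f of spots is constructively placed in a
structure's 10 µm shell and the rest uniformly, the expected measured
fraction is f + (1−f)·u, where u is the chance level.  For each seed, u is
estimated from the placement process itself (starting at the geometric
shell volume fraction and refined by two fixed-point iterations over
calibration placements, because the hard-core separation makes uniform
spots slightly avoid crowded shells), then f = (target − u)/(1 − u) is
fixed **before** any measurement.  The pipeline — tumour-channel rendering,
LoG detection, curation, distance transform, proximity fraction — then
recovers the target without access to it.  Vascular and bone proximities
are measured against the generator's annotated surfaces; type H proximity
is measured against the CD31/EMCN-gated classification, mirroring how each
structure is defined in the imaging protocol.  The null-model target
calibrates the type-H radius by bisection until the type-H 10 µm shell
occupies the target fraction of admissible marrow (verified by the
geometric oracle), then measures 50 000 uniform random spots per seed.

Problem sizes: 20 seeds × 256×256×64 voxels × ~500 DTCs for the recovery
targets, 10 seeds × 50 000 spots for the null model.  The pytest acceptance
suite runs the same protocols at 3 seeds and ~96–128-scale grids; the
statistical checks (binomial 99% CI coverage, exact oracle agreement,
5 ± 2% type-I calibration) are identical.

## Numerical choices and degenerate inputs

Centerline rasterization samples at half the minimum spacing; sub-voxel
spot jitter is uniform within the voxel cell; EDT interpolation is
trilinear with nearest-edge extension; KS p values are clamped to (0, 1];
skeleton graphs reduced to their largest connected piece when thinning
fragments; marching-cubes meshes are computed on padded masks so surfaces
close at volume borders.  Morphometry outputs are invariant under grid
translation and axis permutation up to the orientation dependence of
thinning and meshing (a few voxels of tip handling, ~1e-4 relative area).

## Known limitations

Intensity units are arbitrary; gates derived on one volume do not transfer
to another instrument.  The sphere-capsule vessel model has no calibre
taper or elliptic cross-sections, so surface estimates on real vessels
carry meshing bias the phantom cannot reveal.  Sprout recovery degrades
when anchors are closer than the skeletonization can separate (~2 µm).
Uniformity of the null model is exact over voxel centres; sub-voxel jitter
introduces O(spacing²) curvature bias near structure boundaries, well below
the 0.5-percentage-point tolerance used in verification.
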