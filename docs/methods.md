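# Methods

This note documents the models, numerical choices, and limitations behind
`slfcmap`, in the spirit of a statistics package's model documentation.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The analysis model

The package analyzes per-animal 3D optical-density (OD) volumes from
autoradiographic CBF mapping in a 2×2 between-subjects design:
treatment ∈ {WAS, sham} × colorectal distension ∈ {0, 60 mmHg}, with
roughly 9–10 animals per cell. All group statistics are classical
equal-variance linear-model statistics computed independently per voxel:

- **CRD contrast** — pooled two-sample t of the 60-mmHg vs 0-mmHg
  subgroup within one treatment, df = n₁ + n₂ − 2. Positive t = CBF
  increase (activation).
- **WAS × CRD interaction** — the cell-means contrast
  (WAS60 − WAS0) − (sham60 − sham0) divided by its standard error from
  pooled within-cell variance, df = N − 4. This equals the
  interaction-coefficient t of a dummy-coded saturated OLS fit, which is
  how the test suite cross-checks it.
- **Seed functional connectivity** — across-animal Pearson r between
  voxel OD and the seed ROI's mean OD within one 60-mmHg subgroup,
  mapped to t = r√(df/(1−r²)), df = n − 2, sign retained. No nuisance
  covariates are modelled.

Voxels with zero variance are reported as undefined (NaN) and counted,
never silently zeroed. Swapping group labels negates the t map exactly;
these identities are enforced by oracle tests against per-voxel
`scipy.stats` computations.

### Thresholding

Inference is deliberately uncorrected-voxel-p + cluster extent, mirroring
the classical small-animal SPM recipe: one-sided p < .05 per direction
(activation and deactivation thresholded separately and never merged),
6-connectivity (face adjacency; 18/26 configurable), components below the
extent threshold discarded. No random-field or permutation correction is
offered — that is a scope decision, not an omission.

**Extent scaling.** The reference criterion is 100 contiguous voxels on a
full-scale reconstruction grid (taken as 400 × 57 × 300 voxels of
40 × 300 × 40 µm). Desk-scale grids are 100–200× smaller, where
volume-proportional scaling degenerates to 1 voxel and the extent
criterion loses its role of suppressing isolated noise voxels. The scaled
extent is therefore floored: at 5 voxels for unsmoothed maps, and, for
smoothed maps, at the voxel count spanning the same number of smoothness
resels the full-scale criterion spans (100 voxels ≈ 11.1 resels of
in-plane 3×3-voxel smoothing; with the default anisotropic kernel this
floor is ≈236 voxels). The scaling factor and floor are logged on every
run and both reference values are arguments of
`mapping.scale_extent`.

## 2. The synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes, so that every downstream stage has a recovery test with known
ground truth:

    OD(v) = baseline(v) + subgroup effect(region(v))
          + FC latent component(region(v)) + ε(v),  ε ~ N(0, noise_sd²) i.i.d.

- **Baseline** — `global_mean` (default 100 OD units) inside brain
  parcels, `background_fraction × global_mean` (default 0.35) outside, so
  the 70 %-of-mean mask has real background to remove, as film background
  does.
- **Group effects** — per region per design cell, a constant OD offset.
- **Seed coupling** — one latent z ~ N(0,1) per animal. The seed region
  receives `latent_sd·z`; a region with coupling ρ receives
  `latent_sd·(ρz + √(1−ρ²)z_r)` with z_r independent per region and
  animal. The across-animal correlation between seed and region means is
  therefore ρ in expectation — the planted FC sign and magnitude are
  analytically known, not merely simulated. Couplings may differ by
  treatment (the demo plants ρ = −0.9 under sham, 0 under WAS).
- **Defaults** — `noise_sd = 0.5`, `latent_sd = 1.0`, n = 10 per
  subgroup. The source experiments report no OD noise magnitudes or
  inter-animal variances, so these are free parameters chosen to put the
  planted regimes (≥1.5 within-group SD effects, |ρ| = 0.9 couplings) in
  a realistic moderate-power regime at n = 10, not estimates of any real
  study. With these defaults the voxel-level correlation induced by a
  ρ = 0.9 coupling is attenuated to ρ·latent_sd/√(latent_sd²+noise_sd²)
  ≈ 0.80 by voxel noise — the region-mean correlation remains 0.9.
- **Atlas** — box-shaped connected parcels tiled with one-voxel
  background margins and seeded jitter; unilateral (right-hemisphere)
  names; contralateral connectivity is represented in the SC table's
  laterality column, not as mirrored parcels.
- **Grid** — a scaled-down stand-in (default 32 × 16 × 32) for the
  full 57-section reconstruction. The physical voxel anisotropy
  (40 µm in-plane, 300 µm section spacing) is preserved so that
  anisotropic smoothing decisions are actually exercised. Replicate
  counts in tests and the acceptance script (50 null replicates, 100
  recovery replicates) and these grid sizes are the package's chosen
  study conditions for desk-scale reproduction.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: film/digitization artifacts, spatially
correlated physiological noise, heteroscedasticity across regions,
partial-volume effects at parcel borders, imperfect registration in the
common-space cohorts (registration is exercised separately on synthetic
slice stacks), and any real anatomy in the atlas.

## 3. EMG / visceromotor response

The filter realization behind "lowcut filtered at 20 Hz" is a zero-phase
4th-order Butterworth high-pass (`sosfiltfilt`), chosen because zero-phase
filtering keeps AUC windows phase-neutral; the realization is
configurable via the corner argument. AUC is trapezoidal on the sample
grid, windows are inclusive of both endpoint samples (so a constant-1
rectified trace gives exactly 20 unit·s per 20-s window). "Normalized by
the baseline" is read as the ratio raw/baseline — consistent with the
later percent-of-control scaling — with subtraction available as
`mode="subtract"` since the wording alone does not fix the convention. A
zero baseline AUC flags the epoch and reports the ratio as undefined
rather than raising. The default distension template is two series of
20-s phasic distensions at 10/20/40/60 mmHg with 4-min interstimulus
intervals; repeats per pressure are averaged in the tidy output table.
Group ANOVAs on the resulting per-animal tables are left to
general-purpose statistics tooling.

## 4. Volume pipeline numerics

- **Rigid slice registration** — objective: normalized cross-correlation;
  search: 1°-step rotation grid over ±10° with per-angle sub-pixel
  translation from phase correlation, then bounded scalar refinement of
  the angle (0.02° tolerance). Final resampling is nearest-neighbour in a
  *single* combined resampling step (rotation and shift composed into one
  affine) — sequential rotate-then-shift resampling doubles interpolation
  error. Transforms snap to identity below 0.05°/0.05 px so an aligned
  stack reconstructs bit-identically. A best-pose correlation below 0.3
  triggers a low-confidence warning (structureless inputs). The
  similarity metric is this package's choice; classical section-alignment
  tools do not publish theirs.
- **Fill value** — resampling fills with the median border intensity
  (film background), not the minimum, which biases the objective on
  signed or offset intensity scales.
- **Affine normalization** — 12 parameters (3 translations, rotations,
  log-scales, shears), centre-anchored, optimized in two Powell stages
  (rigid+scale, then all 12) on negative NCC with trilinear resampling.
  Failure modes are explicit: an iteration-cap hit or a final correlation
  below 0.1 (no usable overlap) raises a convergence error carrying the
  final objective.
- **Smoothing** — the in-plane FWHM is 3 × the in-plane voxel dimension
  (σ = FWHM/2√(2 ln 2) ≈ 1.27 voxels); the 300-µm section spacing makes a
  physically isotropic kernel degenerate, so the section axis gets a
  one-voxel-σ kernel instead; both are configurable. Boundaries are
  reflective; a centred impulse conserves total OD to 1e-6.
- **Masking** — threshold at 0.70 × the grand mean over the *full grid*
  (single-pass convention; brain-only means would require the mask being
  computed). Masks are computed after smoothing, before statistics, and
  combined across animals by intersection for group maps. An
  all-nonpositive volume yields an empty mask with a warning.

## 5. Connectome and SLFC decisions

- **Strength vocabulary** — collated databases use ~10 qualitative
  strength words; the linear 1–7 encoding is standard but the exact
  word-to-number table is not published, so `connectome.STRENGTH_WORDS`
  ships an explicit, editable mapping ("very strong"=1 … "very weak"=7,
  "present"=4, plus 'fibers of passage') as a documented convention.
- **Filtering** — strength-7 ('very weak'), 'fibers of passage', and
  contralateral reports are removed before graph construction
  (cross-hemispheric connectivity is out of scope). Filtering is
  idempotent and order-preserving.
- **Aggregation** — multiple reports on one directed pair collapse to one
  edge; the strongest (minimum) code wins by default, median is available.
  Aggregation is order-independent.
- **Region matching** — exact string match only. FC regions absent from
  the SC nomenclature are reported as *unresolved*, never silently
  dropped; silent nomenclature merging is the main error source in
  connectome work.
- **Intersection semantics** — both networks are binarized first;
  direction comes only from SC, sign only from FC; strengths and peak
  statistics are annotations. Every functionally connected region is
  classified exactly once: SLFC edge, FC-without-SC, or unresolved.
  Structural neighbours without FC are omitted. Within one region,
  overlap by clusters of both signs resolves to the larger overlap with a
  warning — region-granularity reporting has no principled resolution for
  mixed signs.
- **No causal claims** — the output is a signed, directed intersection;
  effective-connectivity modelling and global graph metrics are
  non-goals.

## 6. The demonstration workflow

`pipeline.run_demo` wires the stages end to end on one synthetic cohort:
planted seed activation of 2.0 OD in the 60-mmHg cells (≈1.8 within-group
SD at the seed, whose variance is √(latent_sd²+noise_sd²) because the FC
latent rides on it), sham-negative/WAS-absent seed–amygdala-analog
coupling, smoothing, intersection masking, both CRD contrasts, the
interaction, per-treatment seed FC (seed ROI = PrL region ∩ its positive
activation clusters, with an explicit logged fallback to the full region),
SC generation with a planted afferent amygdala→seed edge, filtering,
intersection, and the between-condition change table
(unchanged / sign-flip / lost / gained per partner region). Every written
file carries `config_hash` (SHA-256 of the canonical config JSON) and the
RNG seed; all stage seeds derive from one `SeedSequence`, so a fixed seed
reproduces the bundle byte for byte. The out-of-scope nonlinear
(DCT-basis) spatial normalization step is intentionally absent: synthetic
cohorts are generated in a common space, so affine normalization suffices
to exercise the pipeline; the omission is a documented scope boundary,
not an approximation claim.

## 7. Known limitations

- Affine normalization can reach a local optimum for initial
  misalignments far beyond its basin (≫10° rotations); it has no
  multi-start stage.
- Cluster-level inference is descriptive: only the voxel-level α is
  calibrated; the extent criterion's family-wise properties are not
  quantified (by design, matching the source recipe).
- Region-level FC calls inherit the single-test behaviour of n ≈ 10
  correlation: a region with a region-wide latent component has ≈2α
  probability of a false sign call, which bounds the end-to-end motif
  recovery rate below 100 %.
- The EMG model is additive broadband noise; it does not model motor-unit
  waveforms, so burst *detection* beyond rectified AUC is out of scope.
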