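# Methods

## Model

Cortical function is represented on a pair of spherical icosahedral meshes
(one per hemisphere, nominal radius 100 mm; an order-k subdivision has
10·4ᵏ + 2 vertices, coarse meshes being index prefixes of fine ones). The
working assumption of hyperalignment is that, after surface registration,
two brains agree at coarse spatial scale but differ at fine scale by
*local orthogonal rotations of vertex space*: within a small neighborhood,
one subject's response patterns are (approximately) a rotation/reflection
of another's.

### Connectivity profiles

For each hemisphere, every cortical vertex (seed) is correlated with a
fixed whole-brain set of connectivity targets, giving a seeds × targets
matrix. Targets are either searchlight averages on a coarse prefix grid
(each coarse vertex receives the mean time course of the fine vertices
within an averaging radius) or, in FULL mode, every cortical vertex's own
time course. Runs are z-scored independently (population variance,
divisor n) before concatenation; the profile rows are then standardized to
zero mean, unit variance per seed. Degenerate (constant) seeds or targets
contribute correlation 0 with a warning rather than NaN, keeping the
downstream linear algebra total.

### Searchlight Procrustes alignment

For every 15 mm geodesic searchlight (closed ball, great-circle distance on
the nominal sphere), the source subject's profile rows A and the target's
rows B over the searchlight's vertices are matched by the orthogonal
Procrustes solution R = UVᵀ from the SVD of BAᵀ — reflections allowed, no
isotropic scaling (scale is irrelevant because transformed data are
re-z-scored). The searchlight rotations are *summed* into the (S × S)
blocks of an initially zero sparse hemisphere matrix with no count
normalization; the per-vertex scale this introduces is absorbed by run-wise
z-scoring after application, which makes self-alignment exactly
correlation-preserving. Transforms are pairwise and directional: each
source brain is projected straight into the index subject's space, and no
common model space is ever constructed.

Response hyperalignment (RHA) is the identical machinery with
(vertices × timepoints) response patterns in place of profiles; it is only
defined when both subjects watched the same stimulus, which the code
enforces by comparing run lengths.

### Coarse-to-fine iteration

Dense targets on merely anatomically aligned data are uninformative, so
the iterative schedule starts coarse and refines. At each step the working
(progressively transformed) source movie yields fresh profiles, which are
aligned to the *untransformed* target subject's profiles; the new
transforms are applied to the working data before the next step. The
full-resolution schedule is six steps — three at the order-3 grid
(642 targets/hemisphere before masking, 13 mm averaging), two at order 4
(2562, 7 mm), one FULL — with 15 mm alignment searchlights throughout. The
synthetic default is the same design two subdivision octaves down, three
steps (order-1 grid / 55 mm, order-2 / 27 mm, FULL), preserving the
averaging-radius ≈ grid-spacing ratio of the full-scale schedule.
Composition of a chain is the ordered application with interleaved
z-scoring; `collapse_chain` provides the single matrix product for
inspection only and is documented as approximate for exactly that reason.

### Topography prediction and evaluation

Category-selective topographies are unthresholded per-run OLS t maps for
the contrast "target category vs. all other categories" (weights +1 and
−1/(C−1); zero-sum), using boxcars convolved with a canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s, undershoot
ratio 6, 32 s kernel, peak normalized to 1; 10× oversampled convolution),
an intercept, and Legendre drifts up to order 2 per run. A scrambled
control category is modeled as an ordinary category and included in the
baseline by default (configurable per design). Predictions project each
source subject's localizer runs through the source→target chain, fit the
GLM in target space, and average t maps with equal weight over runs and
sources; an alternative mode pushes each source's pre-computed t maps
through the chain's matrices directly (mean-centered over cortex before
each multiplication, no z-scoring — there is no run dimension), which
agrees closely with the canonical mode. Identity chains give the
anatomical-alignment (AA) baseline.

Scoring: whole-map Pearson correlation of predicted vs. own maps over
cortical vertices; Cronbach's alpha across the k localizer runs,
α = k/(k−1)·(1 − Σᵢ Var(mapᵢ)/Var(Σᵢ mapᵢ)) with population variances over
vertices, as the reliability ceiling; the same two statistics within 15 mm
searchlights (locally degenerate centers yield NaN, never zero, so
histograms can exclude them explicitly); fine-connectome similarity per
searchlight as the correlation of two vectorized (members × targets)
profile blocks; and method contrasts as paired two-sided t tests on
Fisher-z-transformed correlations with Bonferroni adjustment (the paired
t test is our choice; |r| is clipped to 1−10⁻¹² before atanh).

## Synthetic cohort: what it emulates, and what not

The generator plants exactly the structure the model assumes, making it a
documented favorable-case simulator:

- **Template.** n_latents = 40 latent loading maps, each a sum of 8
  spherical Gaussian bumps (width 10 mm) on random cortical vertices, rows
  normalized so every vertex's noise-free movie course has unit variance.
  Category tuning maps are drawn *in the span of the loadings*
  (tuning = loadings · w, w ~ N(0, I)): category selectivity is part of the
  same functional architecture the movie drives, which is precisely why
  movie-derived transforms can transfer to localizer contrasts. Tuning maps
  are standardized over cortex.
- **Misalignment.** Each hemisphere is partitioned into patches by nearest
  order-2 coarse-grid center (~28 mm across); each subject gets one random
  orthogonal block per patch, drawn Haar-uniform on the complement of the
  patch-constant vector (R·1 = 1). Patch means — coarse-scale topography —
  are preserved exactly while fine patterns are scrambled. Fully Haar
  blocks (`preserve_patch_means=False`) also destroy coarse correspondence,
  and then no coarse-target first step can get a purchase; the
  mean-preserving restriction encodes the "anatomy aligns coarse structure"
  premise the method rests on.
- **Movies.** Latent courses are unit-variance AR(1) series (coefficient
  0.3) drawn per *movie*, shared by all subjects watching it and
  independent across movies A and B — different movies share spatial
  (connectivity) structure but nothing temporal. Subject data are the
  rotated template signal plus white noise (movie σ = 1.0, i.e. 1:1
  signal-to-noise in variance), 300 timepoints in 3 runs, TR 2 s.
- **Localizers.** 4 runs; each run presents 2 blocks × 5 categories
  (faces, bodies, scenes, objects, scrambled), 18 s blocks, 4 s gaps, 12 s
  lead-in/out, randomized order; signal = tuning-weighted convolved
  boxcars, rotated, plus white noise σ = 50. Because t-statistic noise is
  ~1 regardless of σ, this σ places per-run map reliability where block
  localizers actually live: Cronbach's alpha ≈ 0.90–0.94 and peak |t| ≈ 8
  across the 4-run average.
- **Medial wall.** A 20° polar cap per hemisphere stands in for the
  non-cortical wall (~3% of vertices masked).
- **Seeding.** Every stream derives from
  (master_seed, CRC-32 of "subject|condition|run"), so any array is
  reproducible in isolation and regeneration from the manifest is bitwise.

Not emulated: hemodynamic nonlinearity and spatial noise correlation, head
motion, scanner drift and physiological confounds, inter-subject variation
in mesh geometry (all subjects share the template mesh, as after fsaverage
resampling), smooth (non-orthogonal) topographic warps, and misalignment
that crosses patch boundaries. Passing tests therefore show the pipeline
is *correct under its own model class* — rotations it can express, with
coarse correspondence intact — not that real cortices satisfy that model;
on real data the attainable prediction accuracy is an empirical question
bounded by the localizer's reliability.

## Numerical choices

- Great-circle distance on the nominal sphere (not graph shortest path);
  real registration spheres are rescaled to radius 100 mm on import so mm
  radii behave as on a real cortex. Closed-ball membership; ties at the
  radius included. 0-based vertex indices; hemispheres are disjoint meshes
  (no cross-hemisphere searchlights) and target grids concatenate both,
  left first.
- Population (divisor-n) variance throughout; scale cancels in every
  correlation.
- SVD sign/tie handling: any valid singular decomposition is accepted;
  tests assert optimality and orthogonality, not entrywise uniqueness, for
  degenerate spectra.
- GLM degenerate vertices: residual variance at or below 10⁻¹² of the mean
  square signal (data in the model span — e.g. noise-free simulations)
  yields a signed sentinel t of ±10⁶ with a warning, never an exception;
  masked vertices carry NaN and are excluded from all statistics.
- Whole-map correlation on a degenerate map raises (a flat whole-brain map
  is a pipeline bug); searchlight-local degeneracy returns NaN (flat local
  neighborhoods are expected).

## Design decisions taken where the design was open

- Pearson profiles are computed on run-wise z-scored, concatenated series;
  with full-length correlation the result equals relying on the
  correlation's internal centering, and the run-wise convention removes
  run-level offsets.
- Movie data are re-z-scored between iterative steps (required anyway to
  absorb the block-sum scale).
- Cross-movie pairs are aligned directly, with no within-dataset
  pre-alignment.
- The alignment searchlight radius stays 15 mm at every iterative step.
- The Fisher-z comparison uses a paired two-sided t test.

## Problem sizes

The packaged study conditions are desk-scale: order-3 meshes
(642 vertices/hemisphere, 1284 total), 10 subjects, 2 × 300-timepoint
movies, 4 localizer runs. The complete experiment — 90 directed pairs ×
2 hemispheres × 3 iterative steps for within-movie CHA, the same again
cross-movie, RHA, and all predictions — runs in a few minutes on one CPU
core. The full-resolution schedule (order-5 meshes, 10,242
vertices/hemisphere) is implemented by the same code paths and constants
but is intended for real GIFTI data.

## Known limitations

- The orthogonal hypothesis class cannot express smooth warps or
  expansion/compression of cortical territories; it approximates them at
  searchlight scale.
- Block summation without count normalization weights densely covered
  vertices more heavily; the subsequent z-scoring removes per-vertex scale
  but not relative within-searchlight weighting.
- Cronbach's alpha assumes (essentially) parallel runs; strong run-order
  effects would bias the ceiling.
- The contrast-map prediction mode is a linear shortcut: it commutes the
  GLM with the transform and is exact only up to the interleaved
  normalizations, hence "quite similar", not identical, to the canonical
  mode.
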