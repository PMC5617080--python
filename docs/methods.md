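# Methods

This note documents the models behind `graftdcs`, the defaults and why
they were chosen, what the synthetic phantom does and does not emulate,
and the numerical decisions a user auditing results should know about.

## Phantom model

The phantom is a 3-D block in µm coordinates: `z` is the cutting axis,
`y` maps to image rows with *dorsal* = smaller row index, `x` to
columns with the grafted hemisphere at small `x`. Regions are
axis-aligned primitives: two mirrored striatal ellipsoids (semi-axes
1000 × 1200 × 1500 µm, ~7.5 mm³ each), a corpus-callosum slab dorsal to
both, and an ellipsoidal graft core concentric with the lesioned
striatum (default semi-axes 550 × 550 × 690 µm → 0.875 mm³, matching
the ~0.9 mm³ scale of sham-stimulated grafts; the anodal-like injected
effect scales the semi-axes by 1.164, i.e. volume × 1.58).

**Fiber field.** TH-fiber stain fraction outside the core is

    f(p) = A · (exp(−d/λ_eff) − exp(−d_max/λ)) / (1 − exp(−d_max/λ)),

clipped at 0, where `d` is the ellipsoidal distance from the core
surface (normalized radius minus one, scaled by the geometric-mean
semi-axis), `A = 0.75` the peak stain fraction, `λ = 350 µm` the decay
length and `d_max = 300 µm` a hard reach beyond which the halo
vanishes (compact support keeps noise-free thresholded areas finite).
The dorsal bias β ≥ 0 multiplies the decay length dorsally of the core
centre, `λ_eff = (1+β)·λ`, which extends both the stain mass and the
thresholded extent dorsally — an amplitude-only bias would leave the
noise-free thresholded support symmetric and make the dorsoventral
ratio blind to β. The intact striatum carries a uniform stain fraction
(0.45) chosen so the sham relative fiber density lands near the ~60%
scale typical of partial reinnervation; the corpus callosum and the
core interior carry zero fiber stain.

A caveat that matters when configuring groups: once `(1+β)·d_max`
exceeds the room between the core surface and the striatal boundary,
the halo saturates against the boundary and the dorsoventral ratio
compresses toward the dorsal/ventral striatal volume ratio. The
default group reaches (sham 300 µm, cathodal 330 µm, anodal 420 µm)
keep the *ventral* shell inside the striatum; the anodal dorsal shell
deliberately saturates, which is what produces its dorsally biased
ratio.

**Cells.** TH-ir somata are spheres of diameter `D = 12 µm` (a typical
grafted dopaminergic soma; no measured value was available, so `D` is
an explicit parameter everywhere) placed at ellipsoidal radius skewed
toward the core border, with a bounded outward excursion so that every
cell stays inside the core dilated by the 50 µm shell. A sphere leaves
a disc profile on every section slab it intersects — the over-counting
the Abercrombie correction removes.

**Rendering.** Brightfield DAB convention: intensity = background (220)
− 200 × stain fraction + N(0, σ) noise (σ = 3 by default), quantized to
8 or 16 bits; the field is sampled at the slab mid-plane. Stain levels
are ordered so a plain intensity threshold separates the tissue
classes: fibers ≤ 0.75 < core neuropil 0.7–0.75 band < somata at 1.0
(soma pixels land near intensity 20, the profile detector's default
cut is 50). ROI label masks are rendered at the slab mid-plane; the
graft-core label takes precedence over the striatum label and loaders
re-add core pixels to the striatal mask.

**Ground truth.** Core volume is analytic (`4πabc/3`). Fiber volume
above the stain threshold, the dorsal/ventral thresholded-volume ratio
and the dorsal/ventral stain-mass ratio are integrated on a 20 µm grid
(15 µm in the test fixtures) over the lesioned striatum. The D/V truth
used for validation is the thresholded-volume ratio because that is the
quantity the pixel-count estimator measures; the mass ratio is recorded
alongside.

**What the phantom does not emulate** — and therefore what passing
tests do not establish about real data: optics (PSF, uneven
illumination, stain deconvolution), tissue deformation and registration
error, manual-outlining variability, non-ellipsoidal anatomy, fiber
anisotropy, and cell clustering/overlap beyond random border placement.
The validation certifies the estimators, not the microscope.

## Behavioral generator

Baselines are N(12, 3²) net ipsilateral turns/min, resampled above the
4 turns/min inclusion threshold. Improvement at week 5 is
`a + b·IFD + ε`, `ε ~ N(0, σ)`; week 2 realizes half of it plus noise.
The raw coupling (used in the slope-recovery validation) takes the
reinnervation score as given; the pipeline defaults standardize the
score within the cohort first (`a = 10`, `b = 2.5`, `σ = 1.5`) so that
the behavioral effect is independent of the score's arbitrary units and
the full-recovery frequency (week-5 rate ≤ 0) falls in the observed
~25–75% range across groups. BDNF tables draw an interhemispheric ratio
per animal (sham ≈ 99%, anodal ≈ 120%).

## Quantification defaults

| parameter | default | rationale |
| --- | --- | --- |
| section thickness T | 40 µm | standard freezing-microtome thickness |
| sampling gap | 120 µm | 1-in-4 sampling; spacing h = 160 µm |
| pixel size | 5.16 µm/px | typical slide-scanner resolution at this magnification |
| OD threshold θ | reference mean + 3·SD | transfers across noise levels; a fixed θ is configurable |
| comparison at θ | strictly above | "pixels above threshold" is a strict inequality |
| Abercrombie D | 12 µm | see cells above; configurable everywhere |
| soma intensity cut | 50 | midway between soma (~20) and core neuropil (~80) rendering levels |
| profile search dilation | 10 px (~50 µm) | covers the border shell where somata sit |

Sampling-geometry metadata is authoritative: volumes and count scaling
use whatever `h = T + gap` the dataset declares. (Free-floating "one in
six" series of 40 µm sections would imply h = 240 µm; the 40 + 120 =
160 µm default reflects the declared spacing of the modelled study —
the two statements are inconsistent at source, and the pipeline simply
follows the metadata.)

Aggregation decisions the field leaves open, fixed here and recorded in
every report: relative fiber density pools positive pixels across
sections before dividing (rather than averaging per-section ratios);
integrated fiber density multiplies the *summed* fiber area (mm²) by
the pooled relative density as a fraction, so only relative comparisons
are meaningful; the dorsoventral centre is the area-weighted core
centroid row pooled over sections (a per-section mode exists behind a
flag), and pixels exactly on the centre row split 50/50, removing a
tie-break asymmetry.

## Statistics

Two-sample comparisons are gated by a Kolmogorov–Smirnov normality test
whose reference normal uses sample-estimated parameters; p values
therefore come from the Lilliefors null distribution (the naive KS null
would almost never reject). Non-normal routes go to the Mann–Whitney U
test, exact by enumeration whenever `n_x·n_y ≤ 400` and tie-free,
otherwise the tie-corrected normal approximation. The mixed
repeated-measures ANOVA (between GROUP, within TIME) is univariate with
sphericity assumed; the Greenhouse–Geisser ε is computed and reported
but not applied, and post hoc tests are per-group paired t of each
later timepoint against baseline, uncorrected by design. On
zero-variance inputs where the library implementation fails, a
first-principles split-plot sum-of-squares fallback reports F = 0,
p = 1 for zero effects over zero error rather than NaN. Regression is
OLS with intercept; group membership is coded sham = 0, anodal = 1,
cathodal = 2 (the coding is embedded in the report), and standardized
coefficients are `b·sd(x)/sd(y)`. The BDNF contrast defaults to an
upper-tailed Welch t (directed hypothesis, unequal variances); both
tails are available because the directionality convention differs
between analyses of this design.

Group allocation balances baseline rotation: a descending serpentine
deal (ties shuffled by seed), then exact re-partition for small
cohorts (≤ 200,000 candidate balanced partitions) or greedy
size-preserving swaps for larger ones. The exact branch makes the
group-mean gap provably minimal for the cohort sizes this pipeline
targets.

## Numerical notes and limitations

* Frustum summation adds no end caps beyond the first and last section,
  so reconstructed volumes underestimate slightly (≈ 0.2% for a 1 mm
  sphere at h = 50 µm, more for coarser sampling); the error shrinks
  monotonically with h.
* `N = n·T/(T+D)` is unbiased only if profiles from spheres straddling
  slab boundaries are counted on every slab they touch; the profile
  detector counts connected components per section independently, which
  matches this convention. Touching somata merge into one component —
  at the default densities this biases counts by a few percent
  downward.
* Zero-intensity pixels are clamped to 1 before the OD log; OD is
  clipped at 0, so tissue brighter than the reference carries no
  signal.
* Validation problem sizes: the end-to-end ordering check runs 100
  seeded cohorts of 11 animals on half-scale phantoms at 10.32 µm/px
  (10 sections of 146 × 223 px per animal); calibration checks use
  1000 replicates per test. Full-scale single-animal quantification
  (20 sections of 582 × 892 px) runs in a few seconds.
* A single run is reproducible bit-for-bit from (config, seed); every
  report embeds the resolved configuration and a content hash.
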