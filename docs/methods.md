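# Methods

## Scope and model of the data

`angioscreen` quantifies self-organized microvascular networks growing in
the tumor compartment of microfluidic chip cultures, and analyzes
plate-based drug screens built on such chips. Three readout families are
handled: per-chip viability (a single fluorescence value), per-chip analyte
concentrations (a cytokine/chemokine panel measured in the supernatant),
and the 15 morphometric descriptors computed from a vessel-marker
(e.g. CD31) fluorescence image of each chip.

The image model is: a bright, branching vessel network of mixed calibers on
a slowly varying background with additive read noise and occasional small
debris ("specks"), inside a tumor compartment whose center contains a
circular region (the glass hole of the graft plate) that serves as the
reference area for vessel densities.

## Image measurement pipeline

1. **Background subtraction** — classic rolling-ball: the background is the
   surface traced by a ball of radius *r* rolled under the intensity
   landscape, implemented with scikit-image's exact rolling ball. Default
   radius 50 px, chosen to exceed the widest expected vessel (~8 px here,
   ~20 px in full-resolution confocal exports) by well over 2×, so vessels
   are preserved while illumination gradients are removed. For radii ≥ 16 px
   the estimate is computed on a 4× downscaled copy and upsampled (the same
   shortcut the ImageJ implementation takes); the background is additionally
   capped at the image so the subtraction stays non-negative. The classic
   ball is used throughout; the sliding-paraboloid variant is not
   implemented.
2. **Segmentation** — the default backend thresholds the preprocessed image
   with Otsu's method computed inside the tumor compartment. This replaces
   the trainable pixel classifier used in interactive workflows with a
   deterministic, parameter-free default; the backend slot accepts any
   callable that returns either a binary vessel mask or a ready 3-class
   grid, so a trained classifier can be plugged in for real data.
3. **Thick/thin split** — per-pixel vessel caliber is estimated as
   2·EDT − 1 at the nearest skeleton pixel, where EDT is the Euclidean
   distance to background. The −1 is a pixel-center correction that makes a
   bar of odd integer width *w* measure exactly *w*; without it a 3-px-wide
   vessel measures 4 px and straddles the default cutoff. Pixels with
   caliber ≥ 4 px (configurable) are "thick". The split partitions the
   binary mask exactly, so thick + thin = total area always.
4. **Cleanup** — everything outside the compartment is zeroed and connected
   components (8-connectivity, classes merged) smaller than 50 px
   (configurable) are dropped. The operation is idempotent.
5. **Skeleton graph** — the mask union is thinned to a 1-px,
   topology-preserving skeleton. Skeleton pixels with ≥ 3 8-neighbors are
   junction pixels; 8-adjacent junction pixels merge into one junction node
   so an X-crossing counts once. Degree-1 pixels are endpoints; remaining
   degree-2 pixels form edge paths. Edge length is geometric (axial step 1,
   diagonal √2). Endpoint-terminated edges shorter than 3 px (configurable)
   are pruned as thinning artifacts, including any leftover single-pixel
   protrusion in the junction cluster they attached to (removed only when
   topologically simple). Closed loops with no node are represented as a
   self-loop on one bookkeeping node and contribute length but no junctions.
6. **Descriptors** — 15 per chip: convex-hull (explant) area;
   thick/thin/total vessel area; the three densities (area ÷ center-circle
   area); junction count; branching index (junctions ÷ total area); total
   and average branch length; average width (total area ÷ total length);
   thick:total area ratio; inside:outside ratios of total and thick area
   relative to the center circle. Degenerate ratios (zero outside-area on a
   non-empty mask) are reported missing (NaN) and flagged rather than
   infinite; an empty mask yields all zeros with a flag; if total length is
   0, average width is 0. Units are pixels; a µm/px factor, if provided, is
   applied only at output time.

Numerical conventions: coordinates are (row, col), 0-based, y-down;
8-connectivity everywhere; averages of branch length are per-branch within
a chip.

## Screen statistics

* **Vehicle normalization** — each chip is expressed as 100 × raw ÷ mean of
  the vehicle-control (DMSO) chips on the same plate. This removes any
  per-plate multiplicative factor exactly, so scripted viability multipliers
  are recovered to machine precision in noise-free simulation.
* **Replicate reproducibility** — Pearson r between first and second
  replicate values per plate × treatment condition.
* **Group comparisons** — Shapiro–Wilk on each group at α = 0.05 gates the
  path: all-gaussian → one-way ANOVA with Tukey HSD post-hoc; otherwise
  Kruskal–Wallis with Dunn's post-hoc z tests (tie-corrected). Post-hoc
  p-values are then Bonferroni-adjusted across the pairwise family — Tukey
  p-values are already familywise, so the extra Bonferroni is deliberately
  conservative, matching the published workflow this pipeline mirrors. A
  zero-variance group on the parametric path falls back to the
  nonparametric path with a warning.
* **Analyte tests** — per analyte × treatment, two-sided unpaired Wilcoxon
  rank-sum vs control (exact null for small tie-free samples, otherwise
  normal approximation with mid-ranks and tie correction), adjusted with
  Benjamini–Hochberg across the full analyte × treatment family by default
  (per-analyte families are available). "Wilcoxon" is read as the unpaired
  rank-sum test because the compared groups are independent chips.
* **Welch's t** — unequal-variance t with Satterthwaite degrees of freedom,
  for two-group comparisons of supernatant markers.
* **Embedding** — descriptors are standardized per column (flagged/missing
  and constant columns dropped), then PCA (deterministic sign convention:
  the largest-magnitude loading of each component is positive) or t-SNE
  (explicit seed required; perplexity defaults to min(30, n/4) and must be
  < n/3).
* **Significance stars** — **** < 0.0001, *** < 0.001, ** < 0.01, * < 0.05,
  on adjusted p-values.
* **Exclusions** — no automatic outlier removal; an explicit exclusion list
  in the configuration is the only mechanism.

## Synthetic data generator

The generator exists so that every stage above can be validated against
exact ground truth; it is first-class, tested code.

**Vascular networks.** A border-seeded persistent random walk with
Bernoulli branching: trunk walkers start on the frame border pointing
inward, advance a fixed step (4 px) with Gaussian angular jitter
(sd = (1 − persistence) × 1.2 rad, persistence 0.9), and branch with
probability 0.02 per step at ±55°, with a 4-step cooldown between branch
events so junctions stay resolvable. A walker whose stroke is about to
touch an earlier vessel either fuses into it — the tip snaps onto the
target's centerline, creating an anastomosis junction — when the approach
is steeper than 30°, or, for near-parallel encounters, backs off and stops
without a junction (parallel merges are not representable as a point
junction, and letting strokes graze creates skeleton artifacts that have no
ground-truth counterpart). Branches shorter than 14 px are discarded along
with their branch-point records unless they carry surviving children.
Stroke widths are drawn uniformly from (5, 8) px for thick and (1.5, 3.5) px
for thin vessels; the gap around the 4-px cutoff is deliberate, because the
rasterized band width is a step function of the nominal width and sampling
inside [3.5, 5) would make nominal and measured caliber classes disagree by
construction. Every branch event, fusion, cancellation and stub-drop is
written to an event log from which the junction count can be independently
replayed; the truth object stores exact polylines, junction coordinates,
total arc length, and (after rasterization) pixel-exact per-class areas.

**Rasterization.** Each polyline is stroked with half-width (w − 1)/2
(floored at 0.5 px so hairline strokes stay 8-connected on diagonals),
giving a horizontal stroke of odd nominal width exactly w rows plus round
end caps. Thin branches are painted before thick ones, so thick wins ties.

**Corruption.** Clean raster + background field (planar ramp by default, or
Gaussian blobs) + Gaussian read noise (σ = 30) + small bright debris blobs
(10 specks of 3–8 px), rejection-placed so they touch neither vessels nor
each other — each speck is one off-vessel connected component that the
cleanup stage is expected to remove. Deterministic given its seed.

**Screens.** Donors × treatments × replicate chips with plates nested in
donors, mirroring the graft-plate layout the package targets: 2 chips per
treatment per plate, 6 vehicle chips per plate, 2 plates per donor. Each
readout is multiplicative — baseline × donor effect × plate effect ×
treatment multiplier × lognormal chip noise (donor sd 0.25, plate sd 0.10,
replicate CV 0.10) — so everything stays positive and vehicle normalization
is exact in the noise-free limit. The default analyte panel is the 13-plex
chemokine/cytokine set plus IL-6; descriptor baselines are plausible
pixel-unit values for a 1024² chip image.

What the generator does **not** emulate: out-of-focus light and PSF blur,
uneven staining along a vessel, lumenized 3-D structure projected to 2-D,
touching-but-distinct vessel crossings at shallow angles, plate-position
(edge) effects, and donor-specific treatment response heterogeneity.
Passing the recovery tests therefore shows the measurement chain is correct
and robust to background, noise and debris — not that the default
segmentation backend matches a trained classifier on real stainings.

## Validation experiments and problem sizes

Validation runs on 512 × 512 frames with a 150-px center circle (the
default chip geometry is 1024² with a 300-px circle; the glass-hole radius
is not standardized and must be configured for real data). The suite
measures: analytic shapes (a 100 × 5 bar, a plus-sign); 50 networks with
≥ 20 branches, clean and corrupted; 200 all-null screens for BH
calibration; 1000 null replicates of 5 groups × n = 8 for the family-wise
error of the gated procedure; 100 screens with a scripted anti-angiogenic
treatment (density, length and junction descriptors halved; n = 10 treated
vs 30 vehicle) for power; 20 screens for PCA separation (silhouette).
Statistical calibration of the rank-sum p-values is checked under an iid
null (donor and plate effects at zero): with random effects on, the
balanced stratification makes the pooled test conservative, which the
flag-rate experiment confirms, but uniformity of raw p-values holds only in
the iid case.

## Known limitations and deliberate departures

* 90° rotations leave all area- and count-based descriptors exactly
  invariant, but skeleton-derived lengths can shift by ~0.1–0.5% because
  the thinning algorithm is not perfectly rotation-equivariant; tests
  assert near-equality rather than bit-identity for those.
* The thick/thin caliber criterion of the original trained classifier is
  unrecoverable; the width-based surrogate is a documented replacement.
* Truth total length counts full centerlines, including the ~half-width
  segment where a child emerges from inside its parent stroke; the skeleton
  cannot see that buried part, which contributes most of the small negative
  bias (~2–4%) in measured total length.
* Albumin-positive areas from an external segmentation enter the statistics
  layer as a plain per-chip scalar column; no CNN segmentation is provided.
* No mixed-effects modeling of donor heterogeneity and no dose–response
  fitting; comparisons pool chips across donors per treatment (the pooling
  rule is configurable in spirit via explicit group construction).
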