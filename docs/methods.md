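# Methods

## Scope and model

`mitoscreen` quantifies live and fixed high-content fluorescence assays of
mitochondrial biology in cultured neurons: organelle segmentation on maximum
projections, per-cell mitochondrial morphometrics, a time-lapse mitophagy
assay based on complete mitochondrion–lysosome colocalization, fixed-stain
validations (LC3/Tomm20 colocalization, per-cell Tomm20 content), marker and
puncta positivity, and ATP partitioning between oxidative phosphorylation
(OXPHOS) and glycolysis from inhibitor plates. Because matched public image
data for this assay family are scarce, the package ships a first-class
synthetic scene generator with exact ground truth so that every stage is
verifiable at desk scale.

## The mitophagy assay

A mitophagy event on one frame is a mitochondrion whose binarised
max-projection mask lies entirely inside a single lysosome label:

    overlap(m) = max_L |m ∩ L| / |m|,   event ⇔ overlap(m) ≥ θ,  θ = 1 by default

* The threshold θ is configurable because strict pixel equality is fragile
  on real, noisy boundaries; θ = 1 is the default and is what all shipped
  analyses use.
* Containment is scored against a *single* lysosome label by default.
  Whether the original screening implementation required one lysosome or the
  lysosome-class union is not knowable; both are implemented
  (`containment_mode="single" | "union"`). On connected-component label maps
  the difference only appears when a mitochondrion straddles two touching
  lysosomes.
* Each frame is scored independently: the assay reports per-time-point
  cross-sectional fractions *m* = (engulfed mitochondria)/(mitochondria) per
  cell, not a cumulative flux, so no object tracking is attempted. Frames
  are 18 min apart by default.
* Cells with zero mitochondria are excluded from *m* (logged), never counted
  as zero.

## Segmentation

All quantification runs on per-frame maximum projections over z (never
per-plane). The stack is deliberately classical:

1. **Nuclei** — Gaussian smoothing (σ = 1.5 px), Otsu threshold with a
   robust floor (background median + 6 MAD) so blank images yield empty
   maps, minimum area 40 px, distance-transform watershed to split touching
   nuclei.
2. **Cells** — seeded watershed growing each nucleus over a cytoplasmic
   intensity proxy (smoothed sum of the mitochondria and lysosome channels).
   The foreground threshold is the lowest multi-Otsu split computed in log
   intensity: the log transform compresses the bright organelle mode, which
   otherwise drags the threshold above the dim cytoplasm. Cells touching
   the field border are flagged and excluded from per-cell statistics by
   default (truncated morphology biases shape metrics).
3. **Organelles** — white top-hat background subtraction (disk radius 8 px,
   larger than any organelle) inside cell regions, Otsu on the in-cell
   histogram, minimum object area 3 px. Labels are clipped to cell regions
   and assigned to cells by majority overlap.
4. **Spots / markers** — local-maximum detection above a robust in-cell
   threshold; marker positivity is mean cell intensity above k× the
   background median (k = 3), floored at background + 6 MAD so a
   zero-background image does not declare every cell positive.

No thresholding or size parameters of the original (proprietary) analysis
are published; all values here are package defaults, exposed in
`SegmentationConfig`, and not claimed to match any commercial software.

## Morphometrics

* **Roundness** R = P²/(4πA) with the Crofton perimeter (circle = 1;
  spiky/elongated > 1). Some platforms report the opposite orientation of
  this scale; `convention="inverse"` returns 1/R. Printed roundness and
  elongation values from instrument-specific formulas are not reproduced
  numerically — the formulas are unpublished and their units unknowable.
* **Elongation** E = major/minor axis of the second-moment ellipse.
* **Interconnectivity** I = mean mitochondrial area/perimeter in µm (the
  ImageJ mitochondrial-morphology macro convention; disc of radius r →
  r/2). Lower I means a more fragmented network. Absolute magnitudes depend
  on optics and pixel size and are therefore validated by closed forms and
  monotonicity (fragmenting a fixed area always lowers I), not against
  printed instrument values.
* Intensity readouts (TMRM → membrane-potential proxy; redox probe →
  mitochondrial ROS proxy; Tomm20 → mitochondrial content) are
  background-subtracted by the median intensity of non-cell pixels; per-cell
  values are means (or integrals, for Tomm20) over in-mitochondria pixels.

## ATP partitioning

With condition means U (untreated), O (oligomycin), D (2-deoxyglucose) and
B (both inhibitors), untreated set to 100 %:

    %OXPHOS = 100(U−O)/U,  %glycolysis = 100(U−D)/U,  %residual = 100·B/U

Condition means are arithmetic well means (no outlier rejection by default;
a robust-median option exists). The partition is scale-invariant. The three
percentages need not sum to 100 — the deviation is flagged, never
corrected — and negative inhibition is reported as a negative percentage
with a warning because it is diagnostically meaningful. The metabolic
switch day is the first timepoint at which %OXPHOS exceeds %glycolysis.

## Statistics

Two-way fixed-effects ANOVA (genotype × timepoint) via OLS with
within-timepoint genotype contrasts adjusted by Sidak (1−(1−p)^k) or a
studentized-range (Tukey) family; the choice is a run-level configuration
because published reports of this assay family use both. Time-lapse comparisons
use a mixed ANOVA (time within subject, genotype between). The unit of
replication is the differentiation round: per-cell values are averaged per
round before testing, matching the biological n and avoiding
pseudoreplication.

## Synthetic scenes

The generator emulates the study conditions rather than arbitrary images:

* **Defaults**: 50 cells per field, ~20 mitochondria per cell (Poisson,
  truncated only at the geometric packing limit), 4 constitutive lysosomes
  per cell, basal engulfment probability 0.09 per mitochondrion per frame
  (the day-27 control value; the mutant condition uses 0.025 and induced
  plateaus use 0.3/0.1), 10 frames at 18 min, 7 z-planes, 0.3 µm pixels,
  16-bit output.
* **Cells** are smoothed star-convex polygons (random low-order harmonics)
  whitened by their exact polygon second-moment matrix and rescaled, so the
  second-moment elongation equals the requested ratio (verified ≤ 10 %
  error, typically < 1 %); spike amplitude grows monotonically with the
  requested boundary roundness.
* **Engulfment** is an independent Bernoulli draw per mitochondrion per
  frame (reversible between frames, i.e. lysosomal turnover), so the
  cross-sectional engulfed fraction equals the engulfment probability at
  every frame. In an engulfed frame a lysosome envelops the mitochondrion
  in place (concentric, radius = mitochondrion radius + 3 px); this is
  geometrically equivalent to relocating the mitochondrion into a lysosome
  and keeps any engulfment count feasible. Ground-truth per-cell fractions
  are exact by construction.
* **Rendering**: objects are crisp binary masks times intensity (no PSF
  blur), spread over z with a Gaussian focus profile whose peak weight is 1
  at each cell's focal plane — hence a max projection recovers the in-focus
  image exactly and a noise-free render round-trips to the ground-truth
  masks. Poisson shot noise (gain 0.1 photons per intensity unit) and
  Gaussian read noise (SD 40) are applied afterwards. A faint cytoplasmic
  background (8 % of mitochondrial intensity) in the mitochondria channel
  plays the role of the cytosolic dye signal that real cell segmentation
  relies on.
* **RNG discipline**: one integer seed per scene, split into geometry,
  engulfment and noise sub-streams, so geometry is bit-stable when only the
  noise model changes and reruns are bit-identical.
* **ATP plates** draw wells from a Gamma distribution with the requested
  condition mean and CV (positive-valued; CV = 0 gives exact means).

What the generator does **not** model — and hence what passing tests do not
show about real data: point-spread blur and chromatic shifts, photobleaching
and stage drift, neurite arbors and touching cells, partial organelle
overlap in z, intensity gradients across the field, and mitochondrial shape
heterogeneity (all organelles are discs). Recovery results demonstrate that
the measurement chain is unbiased under the modelled conditions, not that
segmentation of real neurons is error-free.

## Problem sizes and numerical choices

Recovery experiments use 3 replicate scenes of 50 cells × ~20 mitochondria
× 10 frames (≈30 000 Bernoulli draws per condition), which puts two
binomial standard errors at ≈0.003 around a rate of 0.09 — tight enough to
expose a ~4 % relative detection bias. Single-frame scenes are used where
time plays no role (counts, intensities). Event containment uses an
epsilon of 1e-12 on the overlap fraction to absorb float division. Otsu
thresholds are always floored by median + 6 MAD of the relevant background
so degenerate/blank inputs fail soft (empty maps) rather than hallucinating
objects.

## Known limitations

* The organelle detector assumes blob-like organelles well separated at the
  rendered scale; heavily networked mitochondria in real images would merge
  into single labels and lower counts (and raise I, consistently with its
  definition).
* `%OXPHOS + %glycolysis + %residual` routinely exceeds 100 in real plates
  (inhibitor synergy); the package reports and flags rather than
  renormalises.
* The mixed ANOVA assumes equal frame grids across groups and ≥ 2 subjects
  per group; unbalanced time grids are rejected rather than interpolated.
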