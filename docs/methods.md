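# Methods

This note documents the models, parameters and numerical choices behind
`dabquant`, and what the synthetic-data validation does and does not show
about real histology.

## Optical density and stain separation

Brightfield pixels are converted to optical density per channel as
OD = −log₁₀((I+1)/(I₀+1)), clipped at zero, with white reference I₀ = 255
by default.  The +1 offset guards saturated pixels (I = 0) against
infinities.  Stain separation is Ruifrok–Johnston colour deconvolution:
per-pixel OD 3-vectors are projected through the inverse of a 3×3 unit
stain matrix and negative projections are clipped.  The default vectors are
the classic hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778) directions; the residual third vector is completed
per channel as √max(0, 1 − h² − d²) and normalized, which keeps it
non-negative (a plain cross product does not).  Vectors are configurable;
stain-vector *estimation* from images is out of scope.

Coordinates are fixed project-wide: 0-based pixel indices, x right, y down;
pixel (i, j) covers [j, j+1)×[i, i+1) with center (j+0.5, i+0.5); polygon
membership is decided by the pixel center (even-odd rule, boundary points
excluded).  All windowed image operations pad borders symmetrically
(edge-mirrored).

## Superpixel H-score

SLIC superpixels are grid-seeded at spacing s = diameter/pixel-size and
iteratively reassigned in a 2s×2s window per center under the distance

    D = sqrt(d_int² + compactness² · (d_spatial/s)²),

where d_int is in OD units.  Defaults: diameter 10 µm, compactness 0.25,
10 iterations, connectivity enforcement on (orphan fragments merge into the
adjacent label sharing the longest border).  The labels partition the ROI
exactly.  The superpixel statistic is the arithmetic mean OD of member
pixels.  Classification uses lower-inclusive bins
(negative < t_weak ≤ weak < t_moderate ≤ moderate < t_strong ≤ strong), a
deterministic tie rule pinned by test.  The intensity thresholds are
mandatory experiment-wide configuration — they must be identical for every
image of both cohorts of one experiment; `thresholds_from_quantiles` sets
them from pooled control-pixel OD quantiles when no externally chosen
values exist.  The generator's scenes are built against (0.15, 0.35, 0.65)
OD.

H = (SP_W·100 + SP_M·200 + SP_H·300)/SP_T ranges over [0, 300]; SP_T = 0 is
an error (undefined score), distinct from a valid score of 0.

A caveat pinned down during validation: the H-score is a *count* fraction
over superpixels, while scene ground truth is an *area* fraction.  On
high-contrast scenes SLIC superpixels covering stained patches end up
slightly larger than background ones, so count fractions track area
fractions only when stained structures span several superpixel diameters.
The generator therefore builds diffuse patches ≳4 superpixel diameters
across (≤6000 µm², scaled down on small tiles), and the closure test uses a
192 µm tile (~360 superpixels) so that a ±2-point-per-class tolerance is
resolvable at all.

## Stain-load arms

**Pixel classifier** (microglial load): a 50-tree random forest over a
per-pixel feature stack — raw DAB OD, Gaussian-smoothed OD at radii
(0.5, 1) µm, local standard deviation at radius 1 µm (radii are physical
and converted via the pixel size; sub-pixel radii are rejected).  Training
samples up to 5000 pixels per class from positive/negative polygon
annotations, seed-deterministically; both annotation labels are mandatory.
The study-level trainer annotates a rendered training tile up to 1 px
inside the patch boundary and from 2 px outside it, so partially-smoothed
edge pixels are represented in training — without this the classifier
systematically erodes object edges and underestimates load.

**Phansalkar threshold** (astrocytic load): t = μ(1 + p·e^(−qμ) + k(σ/r−1))
with the common published constants k=0.25, r=0.5, p=2, q=10 and a disk
window of radius 15 px by default (the originating tool publishes no
parameters; all are configuration).  The formula assumes bright objects, so
the OD channel is min-max normalized (stain-positive = high), never
inverted.  μ and σ use the exact disk-window mean/SD (direct correlation,
not an approximation), so the mask is bit-identical to a per-pixel
evaluation of the formula.

Load = 100·|mask ∧ ROI|/|ROI| percent; content outside the ROI never
affects it.

## Soma counting

The seven-step chain, in pinned order: (1) linear min-max rescale of the
ROI's OD to 8-bit; (2) CLAHE local contrast normalization (tile 64 px;
clip expressed in the originating tool's convention, default 2.0, mapped to
skimage's [0,1] fraction as clip/100; 0 disables the step); (3) IsoData
auto-threshold (Otsu optional), stain = bright = foreground; (4) binary
closing, 3×3 square; (5) binary erosion, 3×3 square — the step that strips
thin ramified processes; (6) 3×3 median despeckle; (7) 8-connected
labeling with the inclusive area cut-off, default 8 µm² (a component of
exactly 8 µm² is retained).  Structuring-element radius 0 and median window
1 mean "skip", used by fixtures that pin the cut-off boundary without
morphological area change.  Densities are count / ROI area in mm².

Morphology interacts with resolution: at 0.25 µm/px a 20 µm² soma survives
closing–erosion–despeckle comfortably above the cut-off, while at 1 µm/px
the same soma erodes below it.  Fixtures and defaults assume scans at
0.25–0.5 µm/px (a 40× scan is ~0.25 µm/px).

## Statistics

* Hemisphere check: two-sided Wilcoxon signed-rank on (left − right) per
  mouse; zero differences dropped before ranking; exact null for tie-free
  n ≤ 25 (scipy), own 2ⁿ mid-rank enumeration for tied n ≤ 16, normal
  approximation with continuity correction beyond.  All-zero differences
  return p = 1 with a warning.  The reported statistic is W⁺.  Mice missing
  a hemisphere are dropped and logged; < 3 usable pairs flags the result
  underpowered (p still computed).
* Bilateral averaging: hemispheres are averaged per (mouse, region,
  metric), with an `n_sides` provenance column; idempotent.
* Group comparison: two-sided Mann–Whitney U, exact by complete enumeration
  of all C(n1+n2, n1) labelings of the pooled mid-ranks when n1+n2 ≤ 16
  (ties handled by permuting the observed values), asymptotic with tie
  correction otherwise; p = min(1, 2·min(P(U≤u), P(U≥u))).  Both routes are
  implemented; the choice is recorded in every result (`method`).
* Normalization for reporting: values ×100 / control mean; the control
  group's normalized mean is exactly 100.  Rank tests are scale-invariant,
  so normalization never changes p (tested).
* Outliers: two-sided Grubbs at α = 0.05 by default, at most one flag per
  invocation, every exclusion logged — never silent.  The test choice is
  configuration; Grubbs is the package's choice where tooling conventions
  vary.
* Stars: * p<0.05, ** p<0.01, *** p<0.005, **** p<0.0005, else "ns" —
  note the unusual 0.005/0.0005 upper tiers, kept deliberately; boundaries
  are strict inequalities (p = 0.05 is "ns").
* No multiple-testing correction by default (per-region p-values are
  reported uncorrected, matching the reporting convention the pipeline
  reproduces); `holm_adjust` is available when a correction is wanted.
* Sidedness: two-sided throughout — both increases and decreases are
  starred.

## Synthetic data: what it emulates, and what it does not

Scenes are synthesized in OD space along the DAB vector and converted to
RGB via the Beer–Lambert inverse, which makes the deconvolution round trip
exact by construction (float images; 8-bit quantization only on TIFF
export, adding ~2×10⁻³ OD of rounding).  Element types: flat diffuse disks
at class-representative ODs (0.04 / 0.25 / 0.50 / 0.90), compact
tangle-like blobs, ramified cells (disk soma + 3–6 one-pixel random-walk
processes at lower OD — the erosion step's intended victim), and star
cells (fine radiating branches).  Background OD is 0.02 ± 0.005, safely
below the weak threshold.  Pixel size defaults to 0.25 µm/px, consistent
with a 40× scan.

Cohorts: per mouse, metric values are baseline × group-and-region effect
multiplier × unit-mean log-normal factors at the configured between-mouse
(default 25%) and within-mouse/hemisphere (default 0) coefficients of
variation — strictly positive and CV-parameterized, which is why
log-normal was chosen.  Baselines: H-score 60, microglial load 16%,
astrocytic load 12%, soma density 150/mm².  Group sizes follow the
two-group design the statistics layer targets (e.g. 10 treated vs 6
control).  Slices per mouse is exposed as a parameter rather than fixed.
Everything is bit-reproducible from (spec, seed); derived per-scene seeds
stay below 2³¹.

What passing on synthetic data does **not** show: scenes have no tissue
texture, no slide artifacts (folds, bubbles), no counterstain variation,
no stain colocalization and no hemisphere asymmetries; stained structures
are flat-OD geometric shapes.  Recovery within ±2 percentage points here
demonstrates the pipeline's correctness and calibration on resolvable,
well-separated staining — not robustness to real-slide variability.

## Study runs

A run is reproducible from (config, seed) alone: the report embeds a
config fingerprint and hashes deterministically.  Blinding is structural —
the quantification stage receives pixels and ROI masks only; group labels
join the measure table at the statistics stage.  Every exclusion (outlier,
missing hemisphere, missing ROI) is written to the report.  `render=False`
feeds the generator's ground-truth metric values directly to the
statistics layer; it exists for many-replicate power and type-I-error
studies (hundreds of cohorts), where rendering every scene would add
nothing but runtime.  Validation sizes used by the test suite: 60–768 px
tiles, 200 simulated cohorts for effect-recovery rates, 30 studies for
regional specificity, 100 for the type-I check.

## Known limitations

* SLIC compactness is expressed in OD units; very high-contrast scenes
  with structures ≲2 superpixel diameters across bias count fractions
  relative to area fractions (see above).
* The pixel classifier is a deliberately small, seed-deterministic forest;
  it is not a substitute for interactive annotation on real tissue.
* No whole-slide pyramidal formats; tiles and ROIs must fit in memory.
* No watershed separation of touching somata and no skeleton/morphology
  analysis of glia; astrocytes are quantified as load only.
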